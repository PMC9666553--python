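"""Derived quantities: bacterial concentration, crystal mass, efficiency.

From the per-position binary masks this module computes

* bacterial surface coverage, count and concentration — the count is the
  coverage divided by the 4 um^2 footprint of a single rod (4 um x 1 um),
  the concentration divides the count by the local pore volume at the full
  chip depth;
* per-crystal records — each connected component is summarized by its
  moment-equivalent ellipse; the equivalent diameter D is the mean of the
  minor and major axes, the volume assumes a sphere of diameter D, and the
  mass uses the density of calcite (2.71 g/cm^3).  Total position mass is
  the sum over records;
* the theoretical precipitable mass M_CaCO3 * c_Ca * Q * dt delivered by the
  cementation solution over dt, and the local chemical efficiency: measured
  mass over the theoretical mass apportioned to the position by its
  pore-volume share;
* replicate aggregation as mean and mean absolute deviation per position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "CALCITE_DENSITY_G_PER_UM3",
    "MOLAR_MASS_CACO3_G_PER_MOL",
    "MOLAR_MASS_CA_G_PER_MOL",
    "BACTERIUM_FOOTPRINT_UM2",
    "FlowConfig",
    "CrystalRecord",
    "BacterialStats",
    "PositionQuant",
    "bacterial_stats",
    "crystal_records",
    "position_mass",
    "theoretical_mass",
    "local_efficiency",
    "aggregate_replicates",
]

#: Density of calcite, 2.71 g/cm^3 expressed per um^3.
CALCITE_DENSITY_G_PER_UM3 = 2.71e-12
MOLAR_MASS_CACO3_G_PER_MOL = 100.09
MOLAR_MASS_CA_G_PER_MOL = 40.08
#: Plan-view footprint of one rod (4 um length x 1 um width).
BACTERIUM_FOOTPRINT_UM2 = 4.0


@dataclass(frozen=True)
class FlowConfig:
    """Flow and chemistry constants of the injection experiment."""

    q_ul_per_s: float = 0.018
    c_ca_mol_per_l: float = 1.0
    m_ca_g_per_mol: float = MOLAR_MASS_CA_G_PER_MOL
    m_caco3_g_per_mol: float = MOLAR_MASS_CACO3_G_PER_MOL
    pv_tot_ul: float = 74.0
    length_um: float = 990_000.0
    width_um: float = 3_000.0
    depth_um: float = 50.0
    porosity: float = 0.5
    rho_w_kg_per_m3: float = 998.0
    mu_w_pa_s: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in (
            "q_ul_per_s",
            "c_ca_mol_per_l",
            "m_ca_g_per_mol",
            "m_caco3_g_per_mol",
            "pv_tot_ul",
            "length_um",
            "width_um",
            "depth_um",
            "porosity",
            "rho_w_kg_per_m3",
            "mu_w_pa_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def c_ca_g_per_l(self) -> float:
        """Calcium mass concentration C_Ca = c_Ca * M_Ca (g/L)."""
        return self.c_ca_mol_per_l * self.m_ca_g_per_mol

    @property
    def cross_section_m2(self) -> float:
        return (self.width_um * 1e-6) * (self.depth_um * 1e-6)


@dataclass(frozen=True)
class CrystalRecord:
    """One detected mineral (single crystal or aggregate)."""

    centroid_um: tuple[float, float]
    minor_um: float
    major_um: float
    area_px: int

    def __post_init__(self) -> None:
        if self.minor_um > self.major_um + 1e-9:
            raise ValueError("minor axis must not exceed major axis")

    @property
    def equivalent_diameter_um(self) -> float:
        """D = (minor + major) / 2."""
        return 0.5 * (self.minor_um + self.major_um)

    @property
    def volume_um3(self) -> float:
        """Sphere volume (4/3) pi (D/2)^3 — applied to aggregates as well."""
        return (4.0 / 3.0) * math.pi * (self.equivalent_diameter_um / 2.0) ** 3

    @property
    def mass_g(self) -> float:
        return CALCITE_DENSITY_G_PER_UM3 * self.volume_um3


@dataclass(frozen=True)
class BacterialStats:
    coverage_um2: float
    count: float
    concentration_per_ml: float


@dataclass(frozen=True)
class PositionQuant:
    """Derived quantities for one sampled position."""

    position: int
    x_mm: float
    bacteria: BacterialStats
    crystals: tuple[CrystalRecord, ...]
    pore_volume_ul: float
    mass_g: float
    efficiency_pct: float

    @property
    def n_crystals(self) -> int:
        return len(self.crystals)

    @property
    def mean_diameter_um(self) -> float:
        if not self.crystals:
            return 0.0
        return float(np.mean([c.equivalent_diameter_um for c in self.crystals]))


def bacterial_stats(
    bacteria_mask: np.ndarray,
    grain_mask: np.ndarray,
    pixel_size_um: float,
    depth_um: float,
) -> BacterialStats:
    """Surface coverage, cell count and concentration from the bacteria mask.

    count = coverage / 4 um^2; concentration divides by the pore volume of
    the field (pore pixel area x chip depth).
    """
    bact = np.asarray(bacteria_mask, dtype=bool)
    grain = np.asarray(grain_mask, dtype=bool)
    if bact.shape != grain.shape:
        raise ValueError("bacteria and grain masks must share a shape")
    if pixel_size_um <= 0 or depth_um <= 0:
        raise ValueError("pixel size and depth must be positive")
    pore_px = grain.size - int(grain.sum())
    if pore_px == 0:
        raise ValueError("field has zero pore area")
    coverage = float(bact.sum()) * pixel_size_um**2
    count = coverage / BACTERIUM_FOOTPRINT_UM2
    pore_volume_ml = pore_px * pixel_size_um**2 * depth_um * 1e-12  # um^3 -> mL
    return BacterialStats(
        coverage_um2=coverage,
        count=count,
        concentration_per_ml=count / pore_volume_ml,
    )


def crystal_records(crystal_mask: np.ndarray, pixel_size_um: float) -> list[CrystalRecord]:
    """Summarize each connected component of the crystal mask.

    Minor/major axes are the moment-equivalent ellipse axes of the component
    (same second moments as the pixel region), converted to microns.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    labels = measure.label(np.asarray(crystal_mask, dtype=bool))
    records: list[CrystalRecord] = []
    for region in measure.regionprops(labels):
        minor = region.axis_minor_length * pixel_size_um
        major = region.axis_major_length * pixel_size_um
        cy, cx = region.centroid
        records.append(
            CrystalRecord(
                centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                minor_um=float(minor),
                major_um=float(major),
                area_px=int(region.area),
            )
        )
    return records


def position_mass(records: Iterable[CrystalRecord]) -> float:
    """Total CaCO3 mass at a position (g): density x sum of sphere volumes."""
    return float(sum(r.mass_g for r in records))


def theoretical_mass(config: FlowConfig, dt_s: float) -> float:
    """Theoretical precipitable mass (g) delivered over ``dt_s`` seconds.

    M_CaCO3 (g/mol) x c_Ca (mol/L) x Q (L/s) x dt (s), assuming complete
    conversion of the injected calcium.
    """
    if dt_s < 0:
        raise ValueError("dt must be non-negative")
    q_l_per_s = config.q_ul_per_s * 1e-6
    return config.m_caco3_g_per_mol * config.c_ca_mol_per_l * q_l_per_s * dt_s


def local_efficiency(
    mass_g: float,
    pv_local_ul: float,
    pv_tot_ul: float,
    m_theor_g: float,
) -> float:
    """Local chemical efficiency E (%) of calcium-to-calcite conversion.

    The theoretical mass is apportioned to the position by its pore-volume
    share: E = 100 * m / (m_theor * PV_l / PV_TOT).  Values above 100% are
    possible when precipitation concentrates locally; they are reported
    with a warning rather than clipped.
    """
    if pv_local_ul <= 0 or pv_tot_ul <= 0 or m_theor_g <= 0:
        raise ValueError("pore volumes and theoretical mass must be positive")
    eff = 100.0 * mass_g / (m_theor_g * pv_local_ul / pv_tot_ul)
    if eff > 100.0:
        warnings.warn(
            f"local efficiency {eff:.1f}% exceeds 100% "
            "(locally concentrated precipitation)",
            stacklevel=2,
        )
    return eff


def aggregate_replicates(values: Sequence[Sequence[float]] | np.ndarray):
    """Mean and mean absolute deviation across replicates, per position.

    ``values`` has shape (n_replicates, n_positions); returns ``(mean, mad)``
    arrays of length n_positions, with ``mad = mean(|x_i - mean|)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_replicates requires at least one replicate")
    if arr.ndim == 1:
        arr = arr[None, :]
    mean = arr.mean(axis=0)
    mad = np.abs(arr - mean).mean(axis=0)
    return mean, mad
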