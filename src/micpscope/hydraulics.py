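"""Flow-side calculations: seepage velocity, Reynolds number, permeability.

Intrinsic permeability follows Darcy's law for incompressible creeping flow
through the channel,

    k = Q mu L / (A (p1 - p2)),

with Q the imposed flow rate (m^3/s), mu the water viscosity (Pa s), L the
channel length (m), A = W x H the cross-section (m^2) and p1, p2 the inlet
and outlet pressures.  Sensor pressures arrive in mbar and are converted to
Pa.  Pressure-difference series are smoothed with a Savitzky–Golay filter
before the per-sample permeability is evaluated inside imposed-flow phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .quantify import FlowConfig

__all__ = [
    "MBAR_TO_PA",
    "PressureSeries",
    "PermeabilityTrace",
    "seepage_velocity",
    "reynolds",
    "savgol_smooth",
    "permeability",
    "permeability_trace",
]

MBAR_TO_PA = 100.0


@dataclass(frozen=True)
class PressureSeries:
    """Timestamped inlet/outlet sensor pressures with flow-phase windows.

    ``flow_phases`` lists ``(t_start, t_end)`` seconds of imposed flow; the
    boundaries come from the injection schedule, not from the data.
    """

    time_s: np.ndarray
    p1_mbar: np.ndarray
    p2_mbar: np.ndarray
    flow_phases: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p1 = np.asarray(self.p1_mbar, dtype=float)
        p2 = np.asarray(self.p2_mbar, dtype=float)
        if not (len(t) == len(p1) == len(p2)):
            raise ValueError("time, p1 and p2 must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "p1_mbar", p1)
        object.__setattr__(self, "p2_mbar", p2)
        object.__setattr__(
            self,
            "flow_phases",
            tuple((float(a), float(b)) for a, b in self.flow_phases),
        )

    def flow_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.time_s), dtype=bool)
        for a, b in self.flow_phases:
            mask |= (self.time_s >= a) & (self.time_s <= b)
        return mask


@dataclass(frozen=True)
class PermeabilityTrace:
    """Per-sample permeability within flow phases and its reduction."""

    time_s: np.ndarray
    dp_pa_smooth: np.ndarray
    k_m2: np.ndarray
    reduction_pct: np.ndarray

    @property
    def final_reduction_pct(self) -> float:
        return float(self.reduction_pct[-1])


def seepage_velocity(
    q_ul_per_s: float,
    width_um: float,
    depth_um: float,
    porosity: float,
) -> float:
    """Seepage (pore) velocity in mm/s: Q / (W H n)."""
    if q_ul_per_s < 0:
        raise ValueError("flow rate must be non-negative")
    if width_um <= 0 or depth_um <= 0 or not 0 < porosity <= 1:
        raise ValueError("require positive cross-section and porosity in (0, 1]")
    area_mm2 = (width_um * 1e-3) * (depth_um * 1e-3)
    return q_ul_per_s / (area_mm2 * porosity)  # uL/s = mm^3/s


def reynolds(
    rho_kg_per_m3: float,
    throat_m: float,
    velocity_m_per_s: float,
    mu_pa_s: float,
) -> float:
    """Pore-scale Reynolds number rho * lambda * u / mu (dimensionless)."""
    if rho_kg_per_m3 <= 0 or throat_m <= 0 or mu_pa_s <= 0:
        raise ValueError("density, throat size and viscosity must be positive")
    if velocity_m_per_s < 0:
        raise ValueError("velocity must be non-negative")
    return rho_kg_per_m3 * throat_m * velocity_m_per_s / mu_pa_s


def savgol_smooth(
    series: Sequence[float] | np.ndarray,
    window_length: int = 51,
    poly_order: int = 3,
) -> np.ndarray:
    """Savitzky–Golay smoothing (local least-squares polynomial fits).

    Endpoints are handled by polynomial fits on the truncated windows
    (``mode='interp'``), so polynomials up to ``poly_order`` are reproduced
    exactly everywhere.
    """
    y = np.asarray(series, dtype=float)
    if window_length % 2 == 0 or window_length <= poly_order:
        raise ValueError("window_length must be odd and greater than poly_order")
    if len(y) < window_length:
        raise ValueError(
            f"series length {len(y)} shorter than window {window_length}"
        )
    return savgol_filter(y, window_length, poly_order, mode="interp")


def permeability(
    q_m3_per_s: float,
    mu_pa_s: float,
    length_m: float,
    area_m2: float,
    p1_mbar: float,
    p2_mbar: float,
) -> float:
    """Intrinsic permeability k (m^2) from Darcy's law; pressures in mbar."""
    if q_m3_per_s <= 0 or mu_pa_s <= 0 or length_m <= 0 or area_m2 <= 0:
        raise ValueError("Q, mu, L and A must be positive")
    dp_pa = (p1_mbar - p2_mbar) * MBAR_TO_PA
    if dp_pa <= 0:
        raise ValueError("p1 must exceed p2 (no-flow or reversed gradient)")
    return q_m3_per_s * mu_pa_s * length_m / (area_m2 * dp_pa)


def permeability_trace(
    series: PressureSeries,
    config: FlowConfig,
    sg_window: int = 51,
    sg_order: int = 3,
    effective_length_um: float | None = None,
) -> PermeabilityTrace:
    """Permeability evolution during imposed-flow phases.

    The pressure difference is converted to Pa and Savitzky–Golay smoothed
    within each flow phase (phases shorter than ``sg_window`` use the largest
    feasible odd window), then Darcy's law is applied per sample.  The
    reduction is relative to the first flow-phase sample,
    ``100 (k0 - k) / k0``.  ``effective_length_um`` overrides the channel
    length between the pressure taps; the default uses the full length, as
    the headline permeability numbers do.
    """
    mask = series.flow_mask()
    if not mask.any():
        raise ValueError("series contains no imposed-flow samples")
    dp_pa = (series.p1_mbar - series.p2_mbar) * MBAR_TO_PA
    smooth = np.array(dp_pa, dtype=float)
    for a, b in series.flow_phases:
        sel = (series.time_s >= a) & (series.time_s <= b)
        n = int(sel.sum())
        if n == 0:
            continue
        win = min(sg_window, n if n % 2 == 1 else n - 1)
        if win > sg_order:
            smooth[sel] = savgol_filter(dp_pa[sel], win, sg_order, mode="interp")
    length_m = (effective_length_um or config.length_um) * 1e-6
    q_m3 = config.q_ul_per_s * 1e-9
    with np.errstate(divide="ignore"):
        k = np.where(
            mask & (smooth > 0),
            q_m3 * config.mu_w_pa_s * length_m / (config.cross_section_m2 * smooth),
            np.nan,
        )
    valid = np.flatnonzero(mask & np.isfinite(k))
    if valid.size == 0:
        raise ValueError("no valid positive pressure differences in flow phases")
    k0 = k[valid[0]]
    reduction = 100.0 * (k0 - k) / k0
    return PermeabilityTrace(
        time_s=series.time_s[valid],
        dp_pa_smooth=smooth[valid],
        k_m2=k[valid],
        reduction_pct=reduction[valid],
    )
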