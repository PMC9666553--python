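"""Construction and interrogation of microfluidic chip pore geometries.

Two chip families are supported, both at the same target porosity:

* a *homogeneous* medium — a square lattice of identical cylindrical grains
  with a single pore-throat size (nearest-neighbour surface gap), and
* a *heterogeneous* medium — an irregular, non-overlapping packing of
  cylindrical grains whose nearest-neighbour gaps span a prescribed range
  with a prescribed mean.

All coordinates are continuous microns with the origin at the inlet-side
top-left corner of the channel; ``x`` runs along the flow direction (channel
length ``L``) and ``y`` across the channel width ``W``.  Rasters are indexed
row-major with row ↔ ``y`` and column ↔ ``x``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "ChipDesign",
    "GrainMask",
    "ThroatStats",
    "make_homogeneous_design",
    "make_heterogeneous_design",
    "rasterize",
    "pore_throat_stats",
    "pore_volume",
]


@dataclass(frozen=True)
class ChipDesign:
    """Vector description of cylindrical grains in a rectangular channel.

    Parameters
    ----------
    length_um, width_um, depth_um
        Channel dimensions L, W, H in microns.
    porosity
        Target areal porosity n (pore area fraction).
    grains
        ``(N, 3)`` float array of ``(cx, cy, r)`` in microns.
    kind
        ``"homogeneous"`` or ``"heterogeneous"``.
    seed
        Seed used for randomized packings, ``None`` for deterministic layouts.
    """

    length_um: float
    width_um: float
    depth_um: float
    porosity: float
    grains: np.ndarray
    kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grains, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "grains", g)

    @property
    def grain_area_um2(self) -> float:
        return float(np.pi * np.sum(self.grains[:, 2] ** 2))

    @property
    def areal_porosity(self) -> float:
        """Porosity of the full channel computed from the grain disks."""
        return 1.0 - self.grain_area_um2 / (self.length_um * self.width_um)

    def to_json(self) -> str:
        payload = {
            "length_um": self.length_um,
            "width_um": self.width_um,
            "depth_um": self.depth_um,
            "porosity": self.porosity,
            "kind": self.kind,
            "seed": self.seed,
            "grains": self.grains.tolist(),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ChipDesign":
        d = json.loads(text)
        return cls(
            length_um=d["length_um"],
            width_um=d["width_um"],
            depth_um=d["depth_um"],
            porosity=d["porosity"],
            grains=np.asarray(d["grains"], dtype=float),
            kind=d["kind"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class GrainMask:
    """Binary grain raster for a rectangular field of a chip.

    ``raster`` is boolean with foreground = grain; ``origin_um`` is the
    ``(x, y)`` offset of the field within the channel.
    """

    raster: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def grain_fraction(self) -> float:
        return float(self.raster.mean())

    @property
    def porosity(self) -> float:
        return 1.0 - self.grain_fraction


@dataclass(frozen=True)
class ThroatStats:
    """Summary of per-grain nearest-neighbour surface gaps (microns)."""

    min_um: float
    max_um: float
    mean_um: float


def _lattice_geometry(throat_um: float, porosity: float) -> tuple[float, float]:
    """Solve pitch and diameter of a square lattice from throat + porosity.

    For a square lattice with pitch p and grain diameter d the areal porosity
    is ``n = 1 - pi d^2 / (4 p^2)`` and the throat is ``p - d``.  Both
    constraints together fix ``d = throat / (c - 1)`` with
    ``c = sqrt(pi / (4 (1 - n)))``; the solution only exists (positive gap and
    non-overlapping grains) for ``n > 1 - pi/4``.
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    if throat_um <= 0:
        raise ValueError(f"throat must be positive, got {throat_um}")
    c = math.sqrt(math.pi / (4.0 * (1.0 - porosity)))
    if c <= 1.0:
        raise ValueError(
            f"infeasible porosity {porosity}: a square lattice with a positive "
            f"pore throat requires porosity > 1 - pi/4 ≈ {1 - math.pi / 4:.4f}"
        )
    diameter = throat_um / (c - 1.0)
    pitch = c * diameter
    return pitch, diameter


def make_homogeneous_design(
    throat_um: float,
    porosity: float,
    length_um: float = 990_000.0,
    width_um: float = 3_000.0,
    depth_um: float = 50.0,
) -> ChipDesign:
    """Square lattice of identical grains with a given throat and porosity.

    The unit-cell porosity equals the target exactly by construction; the
    channel-averaged porosity differs only by the partial margins left at the
    channel edges (the lattice is centred in the channel).
    """
    pitch, diameter = _lattice_geometry(throat_um, porosity)
    r = diameter / 2.0
    nx = int(math.floor((length_um - diameter) / pitch)) + 1
    ny = int(math.floor((width_um - diameter) / pitch)) + 1
    if nx < 1 or ny < 1:
        raise ValueError("channel too small to hold a single grain")
    x0 = (length_um - ((nx - 1) * pitch)) / 2.0
    y0 = (width_um - ((ny - 1) * pitch)) / 2.0
    xs = x0 + pitch * np.arange(nx)
    ys = y0 + pitch * np.arange(ny)
    cx, cy = np.meshgrid(xs, ys, indexing="ij")
    grains = np.column_stack([cx.ravel(), cy.ravel(), np.full(cx.size, r)])
    return ChipDesign(
        length_um=length_um,
        width_um=width_um,
        depth_um=depth_um,
        porosity=porosity,
        grains=grains,
        kind="homogeneous",
        seed=None,
    )


def make_heterogeneous_design(
    throat_min_um: float,
    throat_max_um: float,
    throat_mean_um: float,
    porosity: float,
    length_um: float,
    width_um: float,
    seed: int,
    depth_um: float = 50.0,
    max_attempts: int = 1_000_000,
) -> ChipDesign:
    """Irregular non-overlapping grain packing with prescribed gap statistics.

    Grains are added by random sequential addition: each new grain is placed
    at a drawn surface gap from a randomly chosen existing grain (the anchor)
    and accepted only if it lies fully inside the channel and keeps a gap of
    at least ``max(throat_min_um, 0.8 × drawn gap)`` to every existing grain.
    Placement stops once the target porosity is reached.  The gap draw is a
    Gamma variate shifted to ``throat_min_um``; its shape/scale and the grain
    radius distribution are fixed so that at 0.5 porosity the per-grain
    nearest-neighbour gaps land on the requested (min, mean, max) envelope.

    Deterministic for a given ``seed``.
    """
    if not throat_min_um < throat_mean_um < throat_max_um:
        raise ValueError(
            "require throat_min < throat_mean < throat_max, got "
            f"({throat_min_um}, {throat_mean_um}, {throat_max_um})"
        )
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    rng = np.random.default_rng(seed)
    area_target = (1.0 - porosity) * length_um * width_um

    # Radius distribution and gap draw calibrated together: the mean
    # nearest-neighbour gap at fixed porosity scales with the grain radius
    # (gap ≈ 0.24 r at n = 0.5), so the radius median is tied to the target
    # mean gap.  Gamma(3, ·) keeps the draw's mode away from throat_min so
    # the realised gap distribution is not piled up at the minimum.
    r_med = 300.0 * (throat_mean_um / 70.0)
    r_sigma = 0.25
    r_lo, r_hi = r_med / 3.0, min(1.5 * r_med, width_um / 3.0)
    gap_shape = 3.0
    gap_scale = (throat_mean_um - throat_min_um) / 1.5
    floor_frac = 0.8

    def draw_radius() -> float:
        return float(np.clip(r_med * math.exp(r_sigma * rng.standard_normal()), r_lo, r_hi))

    cx: list[float] = []
    cy: list[float] = []
    rr: list[float] = []
    area = 0.0

    # First grain: random position comfortably inside the channel.
    r0 = draw_radius()
    cx.append(float(rng.uniform(r0, length_um - r0)))
    cy.append(float(rng.uniform(r0, width_um - r0)))
    rr.append(r0)
    area += math.pi * r0 * r0

    attempts = 0
    while area < area_target and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(len(rr)))
        r_new = draw_radius()
        gap = throat_min_um + float(rng.gamma(gap_shape, gap_scale))
        if gap > throat_max_um:
            continue
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        d = rr[i] + gap + r_new
        x = cx[i] + d * math.cos(theta)
        y = cy[i] + d * math.sin(theta)
        if not (r_new <= x <= length_um - r_new and r_new <= y <= width_um - r_new):
            continue
        dx = np.asarray(cx) - x
        dy = np.asarray(cy) - y
        gaps = np.hypot(dx, dy) - np.asarray(rr) - r_new
        if gaps.min() < max(throat_min_um, floor_frac * gap) - 1e-9:
            continue
        cx.append(x)
        cy.append(y)
        rr.append(r_new)
        area += math.pi * r_new * r_new

    achieved = 1.0 - area / (length_um * width_um)
    if area < area_target:
        raise RuntimeError(
            f"heterogeneous packing did not converge within {max_attempts} "
            f"placement attempts; achieved porosity {achieved:.3f} "
            f"(target {porosity})"
        )
    grains = np.column_stack([cx, cy, rr])
    return ChipDesign(
        length_um=length_um,
        width_um=width_um,
        depth_um=depth_um,
        porosity=porosity,
        grains=grains,
        kind="heterogeneous",
        seed=seed,
    )


def rasterize(
    design: ChipDesign,
    field_um: Sequence[float],
    pixel_size_um: float,
) -> GrainMask:
    """Rasterize the grains covering a rectangular field of the chip.

    ``field_um`` is ``(x0, y0, extent_x, extent_y)`` in microns and must lie
    inside the channel.  A pixel is grain iff its centre lies inside a grain
    disk (point sampling, no anti-aliasing), so masks are exactly
    reproducible.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    x0, y0, ex, ey = (float(v) for v in field_um)
    if ex <= 0 or ey <= 0:
        raise ValueError("field extents must be positive")
    if x0 < 0 or y0 < 0 or x0 + ex > design.length_um + 1e-6 or y0 + ey > design.width_um + 1e-6:
        raise ValueError("field lies outside the channel rectangle")
    n_cols = max(1, int(round(ex / pixel_size_um)))
    n_rows = max(1, int(round(ey / pixel_size_um)))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    ps = pixel_size_um
    for gx, gy, r in design.grains:
        if gx + r < x0 or gx - r > x0 + ex or gy + r < y0 or gy - r > y0 + ey:
            continue
        # pixel-centre coordinates: x = x0 + (col + 0.5) ps, y = y0 + (row + 0.5) ps
        c_lo = max(0, int(math.floor((gx - r - x0) / ps - 0.5)))
        c_hi = min(n_cols, int(math.ceil((gx + r - x0) / ps + 0.5)))
        r_lo = max(0, int(math.floor((gy - r - y0) / ps - 0.5)))
        r_hi = min(n_rows, int(math.ceil((gy + r - y0) / ps + 0.5)))
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        yy = y0 + (np.arange(r_lo, r_hi) + 0.5) * ps - gy
        xx = x0 + (np.arange(c_lo, c_hi) + 0.5) * ps - gx
        mask[r_lo:r_hi, c_lo:c_hi] |= (
            yy[:, None] ** 2 + xx[None, :] ** 2 <= r * r
        )
    return GrainMask(raster=mask, pixel_size_um=pixel_size_um, origin_um=(x0, y0))


def _nearest_gap_per_grain(grains: np.ndarray) -> np.ndarray:
    """Per-grain nearest-neighbour surface gap, microns.

    Neighbours come from a Delaunay triangulation of the grain centres; each
    grain's gap is the minimum ``center distance - r_i - r_j`` over its
    neighbours.  For fewer than 4 grains (or degenerate center sets) all
    pairs are used.
    """
    n = len(grains)
    centers = grains[:, :2]
    radii = grains[:, 2]
    pairs: set[tuple[int, int]] = set()
    use_all_pairs = n < 4
    if not use_all_pairs:
        try:
            tri = Delaunay(centers)
        except QhullError:
            use_all_pairs = True
        else:
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        pairs.add((i, j))
    if use_all_pairs:
        pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
    best = np.full(n, np.inf)
    for i, j in pairs:
        gap = float(np.hypot(*(centers[i] - centers[j])) - radii[i] - radii[j])
        best[i] = min(best[i], gap)
        best[j] = min(best[j], gap)
    return best


def pore_throat_stats(design: ChipDesign) -> ThroatStats:
    """Min / max / mean of per-grain nearest-neighbour surface gaps."""
    if len(design.grains) < 2:
        raise ValueError("pore_throat_stats requires at least 2 grains")
    gaps = _nearest_gap_per_grain(design.grains)
    gaps = gaps[np.isfinite(gaps)]
    return ThroatStats(
        min_um=float(gaps.min()),
        max_um=float(gaps.max()),
        mean_um=float(gaps.mean()),
    )


def pore_volume(
    design_or_mask: ChipDesign | GrainMask,
    depth_um: float | None = None,
) -> float:
    """Pore volume in microliters: (total area − grain area) × depth.

    For a :class:`ChipDesign` the grain area is the analytic disk area over
    the whole channel and ``depth_um`` defaults to the design depth; for a
    :class:`GrainMask` it is the foreground pixel area of the covered field
    and ``depth_um`` is required.
    """
    if isinstance(design_or_mask, ChipDesign):
        h = design_or_mask.depth_um if depth_um is None else depth_um
        if h <= 0:
            raise ValueError("depth must be positive")
        pore_area = design_or_mask.length_um * design_or_mask.width_um - design_or_mask.grain_area_um2
    elif isinstance(design_or_mask, GrainMask):
        if depth_um is None:
            raise ValueError("depth_um is required for a GrainMask")
        if depth_um <= 0:
            raise ValueError("depth must be positive")
        h = depth_um
        ps2 = design_or_mask.pixel_size_um ** 2
        pore_area = (design_or_mask.raster.size - int(design_or_mask.raster.sum())) * ps2
    else:
        raise TypeError(f"unsupported type {type(design_or_mask)!r}")
    return pore_area * h * 1e-9  # um^3 -> uL
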