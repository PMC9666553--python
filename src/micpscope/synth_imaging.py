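"""Synthetic ground-truth scenes and two-modality microscopy rendering.

The forward model evolves a scene of settled rod-shaped bacteria and growing
CaCO3 crystals on a chip design, then renders co-registered brightfield and
phase-contrast rasters with additive Gaussian noise and a low-order
illumination gradient.  Because the scene geometry is known exactly, the
segmentation and quantification stages can be tested against ground truth
without any experimental data.

Conventions
-----------
* Times are hours from the start of cementation-solution injection.
* Crystal nucleation begins 1 h after injection start and crystals follow a
  logistic diameter-growth law that is ~80% complete 3 h after onset and
  saturated by ~12 h.
* Brightfield: bright background, dark grain and crystal outlines, faint
  bacteria.  Phase contrast: dark background, bacteria slightly brighter,
  crystals bright.
* Rendered outlines are drawn as an annulus *inside* the true shape
  boundary, so a fill of the detected outline reproduces the ground-truth
  shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chip_geometry import ChipDesign, rasterize

__all__ = [
    "Bacterium",
    "Crystal",
    "SceneState",
    "ImagePair",
    "GrowthParams",
    "NoiseParams",
    "RenderLevels",
    "BRIGHTFIELD_LEVELS",
    "PHASE_CONTRAST_LEVELS",
    "seed_bacteria",
    "evolve_scene",
    "render_brightfield",
    "render_phase_contrast",
    "render_pair",
    "ground_truth",
    "growth_fraction",
]

# Label values of the per-pixel phase map.
LABEL_PORE, LABEL_BACTERIA, LABEL_CRYSTAL, LABEL_GRAIN = 0, 1, 2, 3


@dataclass(frozen=True)
class Bacterium:
    """A settled rod: capsule of given length/width centred at ``center_um``."""

    center_um: tuple[float, float]
    length_um: float
    width_um: float = 1.0
    orientation_rad: float = 0.0


@dataclass(frozen=True)
class Crystal:
    """A growing crystal (single or merged aggregate), elliptical in plan view.

    The current axes follow the shared logistic growth law: the equivalent
    diameter at time ``t`` is ``final_diameter_um * growth_fraction(t -
    nucleation_time_h)`` and the minor/major split is fixed by ``aspect``
    (minor/major ratio).
    """

    center_um: tuple[float, float]
    nucleation_time_h: float
    final_diameter_um: float
    aspect: float = 1.0
    orientation_rad: float = 0.0

    def axes_um(self, t_h: float) -> tuple[float, float]:
        """(minor, major) full axes at time ``t_h``; (0, 0) before nucleation."""
        d = self.final_diameter_um * growth_fraction(t_h - self.nucleation_time_h)
        major = 2.0 * d / (1.0 + self.aspect)
        return self.aspect * major, major

    def equivalent_diameter_um(self, t_h: float) -> float:
        minor, major = self.axes_um(t_h)
        return 0.5 * (minor + major)

    def area_um2(self, t_h: float) -> float:
        minor, major = self.axes_um(t_h)
        return math.pi * minor * major / 4.0


@dataclass(frozen=True)
class SceneState:
    """Ground truth at one time point for one field of the chip."""

    t_h: float
    design: ChipDesign
    field_um: tuple[float, float, float, float]
    bacteria: tuple[Bacterium, ...] = ()
    crystals: tuple[Crystal, ...] = ()

    def total_crystal_area_um2(self) -> float:
        return sum(c.area_um2(self.t_h) for c in self.crystals)


@dataclass(frozen=True)
class ImagePair:
    """Co-registered brightfield + phase-contrast rasters for one position/time."""

    brightfield: np.ndarray
    phase_contrast: np.ndarray
    pixel_size_um: float
    position: int = 1
    t_h: float = 0.0

    def __post_init__(self) -> None:
        if self.brightfield.shape != self.phase_contrast.shape:
            raise ValueError("brightfield and phase contrast rasters must share a shape")


@dataclass(frozen=True)
class GrowthParams:
    """Nucleation and growth defaults for the synthetic crystal population.

    Nucleation is a Poisson process over the window
    [nucleation_start_h, nucleation_stop_h] with intensity
    ``nucleation_rate_per_cell_h × (number of bacteria)`` — cells act as
    nucleation sites, so the count scales with the bacterial load.  Final
    equivalent diameters are drawn from a clipped normal whose default mean
    sits inside the observed 17–46 um envelope.
    """

    nucleation_start_h: float = 1.0
    nucleation_stop_h: float = 4.0
    nucleation_rate_per_cell_h: float = 2e-3
    final_diameter_mean_um: float = 30.0
    final_diameter_sd_um: float = 6.0
    final_diameter_min_um: float = 10.0
    final_diameter_max_um: float = 60.0
    aspect_min: float = 0.8
    aspect_max: float = 1.0
    grain_site_fraction: float = 0.5


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian pixel noise and a multiplicative linear illumination ramp."""

    sigma: float = 0.02
    gradient_amplitude: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class RenderLevels:
    background: float
    grain_interior: float
    grain_outline: float
    crystal_interior: float
    crystal_outline: float
    bacteria: float


BRIGHTFIELD_LEVELS = RenderLevels(
    background=0.90,
    grain_interior=0.75,
    grain_outline=0.20,
    crystal_interior=0.60,
    crystal_outline=0.20,
    bacteria=0.87,
)

PHASE_CONTRAST_LEVELS = RenderLevels(
    background=0.10,
    grain_interior=0.12,
    grain_outline=0.55,
    crystal_interior=0.80,
    crystal_outline=0.80,
    bacteria=0.30,
)

_GROWTH_TAU0 = 2.0  # h after nucleation: logistic midpoint
_GROWTH_SCALE = 0.7  # h: logistic steepness


def growth_fraction(tau_h: float) -> float:
    """Fraction of final diameter reached ``tau_h`` hours after nucleation.

    Baseline-subtracted logistic: 0 at nucleation, ~0.80 after 3 h (i.e. at
    t = 4 h for a crystal nucleated at 1 h), >0.999 after 11 h.
    """
    if tau_h <= 0.0:
        return 0.0
    g0 = 1.0 / (1.0 + math.exp(_GROWTH_TAU0 / _GROWTH_SCALE))
    g = 1.0 / (1.0 + math.exp(-(tau_h - _GROWTH_TAU0) / _GROWTH_SCALE))
    return (g - g0) / (1.0 - g0)


def _pore_sampler(design: ChipDesign, field_um, rng, margin: float = 0.0):
    """Rejection sampler for points in the pore space of a field."""
    x0, y0, ex, ey = field_um
    grains = design.grains

    def sample() -> tuple[float, float]:
        for _ in range(10_000):
            x = x0 + rng.uniform(0.0, ex)
            y = y0 + rng.uniform(0.0, ey)
            d2 = (grains[:, 0] - x) ** 2 + (grains[:, 1] - y) ** 2
            if len(grains) == 0 or np.all(d2 > (grains[:, 2] + margin) ** 2):
                return float(x), float(y)
        raise RuntimeError("field has (effectively) no pore space to sample")

    return sample


def _field_pore_volume_ul(design: ChipDesign, field_um, depth_um: float) -> float:
    """Pore volume of a field in uL, from a 1 um/px rasterization."""
    mask = rasterize(design, field_um, pixel_size_um=1.0)
    pore_px = mask.raster.size - int(mask.raster.sum())
    return pore_px * 1.0 * depth_um * 1e-9


def seed_bacteria(
    design: ChipDesign,
    concentration_per_ml: float,
    field_um: Sequence[float],
    seed: int,
) -> SceneState:
    """Uniformly seed settled rods into the pore space of a field at t = 0.

    The rod count is ``round(concentration × pore volume of the field)`` at
    the full chip depth; rod lengths are uniform on [2, 4] um, width 1 um,
    orientation uniform.
    """
    if concentration_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    field_um = tuple(float(v) for v in field_um)
    rng = np.random.default_rng(seed)
    pv_ul = _field_pore_volume_ul(design, field_um, design.depth_um)
    n = int(round(concentration_per_ml * pv_ul * 1e-3))  # uL -> mL
    if n > 0 and pv_ul <= 0:
        raise ValueError("field has zero pore space but positive concentration")
    if n == 0:
        return SceneState(t_h=0.0, design=design, field_um=field_um)
    sample = _pore_sampler(design, field_um, rng)
    bacteria = tuple(
        Bacterium(
            center_um=sample(),
            length_um=float(rng.uniform(2.0, 4.0)),
            width_um=1.0,
            orientation_rad=float(rng.uniform(0.0, 2.0 * math.pi)),
        )
        for _ in range(n)
    )
    return SceneState(t_h=0.0, design=design, field_um=field_um, bacteria=bacteria)


def _merge_pair(a: Crystal, b: Crystal, t_h: float) -> Crystal:
    """Merge two overlapping crystals into one aggregate record.

    The merged ellipse comes from the area-weighted union second moments of
    the two member ellipses, rescaled to conserve total area; it continues
    growing on the earlier member's growth curve.
    """

    def cov(c: Crystal) -> tuple[np.ndarray, float, np.ndarray]:
        minor, major = c.axes_um(t_h)
        sa, sb = major / 2.0, minor / 2.0
        ct, st = math.cos(c.orientation_rad), math.sin(c.orientation_rad)
        rot = np.array([[ct, -st], [st, ct]])
        # uniform ellipse second moments: diag(a^2/4, b^2/4) in principal axes
        s = rot @ np.diag([sa * sa / 4.0, sb * sb / 4.0]) @ rot.T
        area = math.pi * sa * sb
        return s, area, np.asarray(c.center_um, dtype=float)

    s1, a1, c1 = cov(a)
    s2, a2, c2 = cov(b)
    area = a1 + a2
    center = (a1 * c1 + a2 * c2) / area
    d1, d2 = c1 - center, c2 - center
    s = (a1 * (s1 + np.outer(d1, d1)) + a2 * (s2 + np.outer(d2, d2))) / area
    evals, evecs = np.linalg.eigh(s)
    evals = np.maximum(evals, 1e-12)
    semi = 2.0 * np.sqrt(evals)  # semi-axes; evals ascending
    scale = math.sqrt(area / (math.pi * semi[0] * semi[1]))
    semi *= scale
    minor_now, major_now = 2.0 * semi[0], 2.0 * semi[1]
    orient = math.atan2(evecs[1, 1], evecs[0, 1])
    t_nuc = min(a.nucleation_time_h, b.nucleation_time_h)
    g = growth_fraction(t_h - t_nuc)
    d_now = 0.5 * (minor_now + major_now)
    final_d = d_now / g if g > 0 else max(a.final_diameter_um, b.final_diameter_um)
    return Crystal(
        center_um=(float(center[0]), float(center[1])),
        nucleation_time_h=t_nuc,
        final_diameter_um=final_d,
        aspect=float(minor_now / major_now),
        orientation_rad=orient,
    )


def _merge_overlaps(crystals: list[Crystal], t_h: float) -> list[Crystal]:
    """Merge crystals whose equivalent-circle footprints overlap at ``t_h``."""
    merged = list(crystals)
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                ci, cj = merged[i], merged[j]
                di = ci.equivalent_diameter_um(t_h)
                dj = cj.equivalent_diameter_um(t_h)
                if di <= 0 or dj <= 0:
                    continue
                dist = math.hypot(
                    ci.center_um[0] - cj.center_um[0],
                    ci.center_um[1] - cj.center_um[1],
                )
                if dist < 0.5 * (di + dj):
                    merged[i] = _merge_pair(ci, cj, t_h)
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    return merged


def evolve_scene(
    scene: SceneState,
    t_target_h: float,
    growth: GrowthParams | None = None,
    seed: int = 0,
) -> SceneState:
    """Advance the scene to ``t_target_h``: nucleate, grow and merge crystals.

    Nucleation sites sit either on grain perimeters or on the pore floor
    (glass slide), where settled cells reside.  Crystal area is monotonically
    non-decreasing across successive calls.
    """
    growth = growth or GrowthParams()
    if t_target_h < scene.t_h:
        raise ValueError("t_target must be >= current scene time")
    if growth.nucleation_rate_per_cell_h < 0:
        raise ValueError("nucleation rate must be non-negative")
    rng = np.random.default_rng(seed)
    lo = max(scene.t_h, growth.nucleation_start_h)
    hi = min(t_target_h, growth.nucleation_stop_h)
    new: list[Crystal] = []
    if hi > lo and scene.bacteria:
        lam = growth.nucleation_rate_per_cell_h * len(scene.bacteria) * (hi - lo)
        n_new = int(rng.poisson(lam))
        if n_new:
            sample_pore = _pore_sampler(scene.design, scene.field_um, rng, margin=2.0)
            x0, y0, ex, ey = scene.field_um
            grains = scene.design.grains
            in_field = grains[
                (grains[:, 0] > x0 - 400) & (grains[:, 0] < x0 + ex + 400)
                & (grains[:, 1] > y0 - 400) & (grains[:, 1] < y0 + ey + 400)
            ]
            for _ in range(n_new):
                t_nuc = float(rng.uniform(lo, hi))
                d_final = float(
                    np.clip(
                        rng.normal(growth.final_diameter_mean_um, growth.final_diameter_sd_um),
                        growth.final_diameter_min_um,
                        growth.final_diameter_max_um,
                    )
                )
                center = None
                if len(in_field) and rng.random() < growth.grain_site_fraction:
                    # grown from the pillar surface into the pore: centre offset
                    # so the full-grown crystal is tangent to the pillar
                    for _ in range(50):
                        gx, gy, gr = in_field[int(rng.integers(len(in_field)))]
                        th = float(rng.uniform(0.0, 2.0 * math.pi))
                        off = gr + d_final / 2.0
                        cx = gx + off * math.cos(th)
                        cy = gy + off * math.sin(th)
                        if not (x0 <= cx <= x0 + ex and y0 <= cy <= y0 + ey):
                            continue
                        d2 = (grains[:, 0] - cx) ** 2 + (grains[:, 1] - cy) ** 2
                        if np.all(d2 > grains[:, 2] ** 2):
                            center = (float(cx), float(cy))
                            break
                if center is None:
                    center = sample_pore()
                new.append(
                    Crystal(
                        center_um=center,
                        nucleation_time_h=t_nuc,
                        final_diameter_um=d_final,
                        aspect=float(rng.uniform(growth.aspect_min, growth.aspect_max)),
                        orientation_rad=float(rng.uniform(0.0, math.pi)),
                    )
                )
    crystals = _merge_overlaps(list(scene.crystals) + new, t_target_h)
    return replace(scene, t_h=float(t_target_h), crystals=tuple(crystals))


# ---------------------------------------------------------------------------
# Rasterization of scene geometry


def _grid(field_um, pixel_size_um):
    x0, y0, ex, ey = field_um
    n_cols = max(1, int(round(ex / pixel_size_um)))
    n_rows = max(1, int(round(ey / pixel_size_um)))
    return n_rows, n_cols


def _paint_disk(mask, field_um, ps, cx, cy, r_out, r_in=0.0):
    """Set pixels with r_in < dist <= r_out from (cx, cy) to True."""
    x0, y0, _, _ = field_um
    n_rows, n_cols = mask.shape
    c_lo = max(0, int((cx - r_out - x0) / ps) - 1)
    c_hi = min(n_cols, int((cx + r_out - x0) / ps) + 2)
    r_lo = max(0, int((cy - r_out - y0) / ps) - 1)
    r_hi = min(n_rows, int((cy + r_out - y0) / ps) + 2)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    yy = y0 + (np.arange(r_lo, r_hi) + 0.5) * ps - cy
    xx = x0 + (np.arange(c_lo, c_hi) + 0.5) * ps - cx
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    sel = d2 <= r_out * r_out
    if r_in > 0:
        sel &= d2 > r_in * r_in
    mask[r_lo:r_hi, c_lo:c_hi] |= sel


def _paint_ellipse(mask, field_um, ps, crystal: Crystal, t_h, shrink_um=0.0):
    """Set pixels inside the crystal ellipse (optionally shrunk) to True."""
    minor, major = crystal.axes_um(t_h)
    sa, sb = major / 2.0 - shrink_um, minor / 2.0 - shrink_um
    if sa <= 0 or sb <= 0:
        return
    cx, cy = crystal.center_um
    x0, y0, _, _ = field_um
    n_rows, n_cols = mask.shape
    rmax = max(sa, sb)
    c_lo = max(0, int((cx - rmax - x0) / ps) - 1)
    c_hi = min(n_cols, int((cx + rmax - x0) / ps) + 2)
    r_lo = max(0, int((cy - rmax - y0) / ps) - 1)
    r_hi = min(n_rows, int((cy + rmax - y0) / ps) + 2)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    yy = y0 + (np.arange(r_lo, r_hi) + 0.5) * ps - cy
    xx = x0 + (np.arange(c_lo, c_hi) + 0.5) * ps - cx
    ct, st = math.cos(crystal.orientation_rad), math.sin(crystal.orientation_rad)
    xr = ct * xx[None, :] + st * yy[:, None]
    yr = -st * xx[None, :] + ct * yy[:, None]
    mask[r_lo:r_hi, c_lo:c_hi] |= (xr / sa) ** 2 + (yr / sb) ** 2 <= 1.0


def _paint_capsule(mask, field_um, ps, bact: Bacterium):
    """Set pixels inside the rod capsule to True."""
    cx, cy = bact.center_um
    half = max(bact.length_um / 2.0 - bact.width_um / 2.0, 0.0)
    w2 = bact.width_um / 2.0
    ux, uy = math.cos(bact.orientation_rad), math.sin(bact.orientation_rad)
    x0, y0, _, _ = field_um
    n_rows, n_cols = mask.shape
    rmax = half + w2
    c_lo = max(0, int((cx - rmax - x0) / ps) - 1)
    c_hi = min(n_cols, int((cx + rmax - x0) / ps) + 2)
    r_lo = max(0, int((cy - rmax - y0) / ps) - 1)
    r_hi = min(n_rows, int((cy + rmax - y0) / ps) + 2)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    yy = y0 + (np.arange(r_lo, r_hi) + 0.5) * ps - cy
    xx = x0 + (np.arange(c_lo, c_hi) + 0.5) * ps - cx
    # distance to the capsule spine segment
    t = np.clip(xx[None, :] * ux + yy[:, None] * uy, -half, half)
    dx = xx[None, :] - t * ux
    dy = yy[:, None] - t * uy
    mask[r_lo:r_hi, c_lo:c_hi] |= dx * dx + dy * dy <= w2 * w2


def _scene_masks(scene: SceneState, pixel_size_um: float, outline_um: float = 1.2):
    """Rasterize scene geometry into per-phase masks.

    Returns (grain_interior, grain_outline, crystal_interior, crystal_outline,
    bacteria); outlines are annuli just inside the true shape boundary.
    """
    shape = _grid(scene.field_um, pixel_size_um)
    g_int = np.zeros(shape, dtype=bool)
    g_out = np.zeros(shape, dtype=bool)
    c_int = np.zeros(shape, dtype=bool)
    c_out = np.zeros(shape, dtype=bool)
    bact = np.zeros(shape, dtype=bool)
    ps = pixel_size_um
    x0, y0, ex, ey = scene.field_um
    for gx, gy, r in scene.design.grains:
        if gx + r < x0 or gx - r > x0 + ex or gy + r < y0 or gy - r > y0 + ey:
            continue
        _paint_disk(g_int, scene.field_um, ps, gx, gy, max(r - outline_um, 0.0))
        _paint_disk(g_out, scene.field_um, ps, gx, gy, r, max(r - outline_um, 0.0))
    for c in scene.crystals:
        if c.equivalent_diameter_um(scene.t_h) <= 0:
            continue
        _paint_ellipse(c_int, scene.field_um, ps, c, scene.t_h, shrink_um=outline_um)
        full = np.zeros(shape, dtype=bool)
        _paint_ellipse(full, scene.field_um, ps, c, scene.t_h)
        c_out |= full & ~c_int
    for b in scene.bacteria:
        _paint_capsule(bact, scene.field_um, ps, b)
    return g_int, g_out, c_int, c_out, bact


def _apply_nuisance(img: np.ndarray, noise: NoiseParams) -> np.ndarray:
    if noise.gradient_amplitude:
        n_rows, n_cols = img.shape
        ramp = 1.0 + noise.gradient_amplitude * (
            np.linspace(-0.5, 0.5, n_cols)[None, :]
            + 0.3 * np.linspace(-0.5, 0.5, n_rows)[:, None]
        )
        img = img * ramp
    if noise.sigma:
        rng = np.random.default_rng(noise.seed)
        img = img + rng.normal(0.0, noise.sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _render(scene, pixel_size_um, levels: RenderLevels, noise: NoiseParams) -> np.ndarray:
    g_int, g_out, c_int, c_out, bact = _scene_masks(scene, pixel_size_um)
    img = np.full(_grid(scene.field_um, pixel_size_um), levels.background, dtype=float)
    # precedence bottom-up: bacteria < crystal < grain
    img[bact] = levels.bacteria
    img[c_int] = levels.crystal_interior
    img[c_out] = levels.crystal_outline
    img[g_int] = levels.grain_interior
    img[g_out] = levels.grain_outline
    return _apply_nuisance(img, noise)


def render_brightfield(
    scene: SceneState,
    pixel_size_um: float = 0.29,
    noise: NoiseParams | None = None,
) -> np.ndarray:
    """Brightfield render: bright background, dark grain/crystal outlines."""
    return _render(scene, pixel_size_um, BRIGHTFIELD_LEVELS, noise or NoiseParams())


def render_phase_contrast(
    scene: SceneState,
    pixel_size_um: float = 0.29,
    noise: NoiseParams | None = None,
) -> np.ndarray:
    """Phase-contrast render: dark background, brighter bacteria, bright crystals."""
    return _render(scene, pixel_size_um, PHASE_CONTRAST_LEVELS, noise or NoiseParams())


def render_pair(
    scene: SceneState,
    pixel_size_um: float = 0.29,
    noise: NoiseParams | None = None,
    position: int = 1,
) -> ImagePair:
    return ImagePair(
        brightfield=render_brightfield(scene, pixel_size_um, noise),
        phase_contrast=render_phase_contrast(scene, pixel_size_um, noise),
        pixel_size_um=pixel_size_um,
        position=position,
        t_h=scene.t_h,
    )


def ground_truth(scene: SceneState, pixel_size_um: float = 0.29) -> np.ndarray:
    """Per-pixel label raster {0 pore, 1 bacteria, 2 crystal, 3 grain}.

    Precedence grain > crystal > bacteria: a bacterium encapsulated in a
    crystal is labelled crystal.
    """
    g_int, g_out, c_int, c_out, bact = _scene_masks(scene, pixel_size_um)
    labels = np.zeros(_grid(scene.field_um, pixel_size_um), dtype=np.uint8)
    labels[bact] = LABEL_BACTERIA
    labels[c_int | c_out] = LABEL_CRYSTAL
    labels[g_int | g_out] = LABEL_GRAIN
    return labels
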