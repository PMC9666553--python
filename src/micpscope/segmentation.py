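"""Three-phase segmentation workflow for MICP microfluidics microscopy.

The workflow separates, per imaged position:

1. solid grains — from the brightfield image at t = 0 (dark pillar outlines
   on a bright background): adaptive binarization, area filtering of noise
   and bacteria, hole filling;
2. bacteria — from the phase-contrast image (bacteria slightly brighter than
   the dark background): adaptive binarization, grain removal, 10–900 px
   area filter;
3. CaCO3 crystals — from a later-time brightfield image (dark crystal
   outlines): adaptive binarization, morphological closing, hole filling,
   grain subtraction, and removal of residual thin pillar-outline arcs;

and composes the three binary masks into a single labelled phase map
{0 pore, 1 bacteria, 2 crystal, 3 grain}.

Adaptive threshold semantics
----------------------------
``adaptive_binarize`` thresholds against the local mean m(x) over a square
window.  With ``sensitivity`` s in [0, 1]:

* dark polarity:   foreground iff I(x) < m(x) · (0.5 + s)
* bright polarity: foreground iff I(x) > m(x) · (1.5 − s)

so for either polarity the foreground grows monotonically with s.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "extract_green_normalized",
    "adaptive_binarize",
    "segment_grains",
    "segment_bacteria",
    "segment_crystals",
    "compose_phase_map",
]

LABEL_PORE, LABEL_BACTERIA, LABEL_CRYSTAL, LABEL_GRAIN = 0, 1, 2, 3


def extract_green_normalized(image: np.ndarray) -> np.ndarray:
    """Green channel of an RGB image, normalized to [0, 1].

    8-bit images are divided by 255, 16-bit by 65535; float images are
    assumed to already be in [0, 1] and pass through.  Grayscale images skip
    the channel selection.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[2] < 3:
            raise ValueError(f"expected an RGB image, got shape {img.shape}")
        img = img[:, :, 1]
    elif img.ndim != 2:
        raise ValueError(f"expected a 2D or 3-channel image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    if np.issubdtype(img.dtype, np.floating):
        return img.astype(float)
    raise ValueError(f"unsupported image dtype {img.dtype}")


def default_window(shape: tuple[int, ...]) -> int:
    """Default local-mean window: ``2 * floor(min(H, W) / 16) + 1`` pixels."""
    return 2 * (min(shape[:2]) // 16) + 1


def adaptive_binarize(
    image: np.ndarray,
    sensitivity: float,
    polarity: str,
    window: int | None = None,
) -> np.ndarray:
    """Local-mean adaptive threshold with a [0, 1] sensitivity dial.

    Parameters
    ----------
    image
        Grayscale raster with values in [0, 1].
    sensitivity
        In [0, 1]; higher sensitivity marks more pixels as foreground.
    polarity
        ``"dark"`` to detect foreground darker than its neighbourhood,
        ``"bright"`` for brighter.
    window
        Odd square window for the local mean; defaults to
        :func:`default_window`.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("adaptive_binarize expects a 2D grayscale image")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError(f"sensitivity must be in [0, 1], got {sensitivity}")
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    win = default_window(img.shape) if window is None else int(window)
    if win < 1 or win % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {win}")
    if win > min(img.shape):
        raise ValueError(f"window {win} larger than image {img.shape}")
    local_mean = ndimage.uniform_filter(img, size=win, mode="reflect")
    if polarity == "dark":
        return img < local_mean * (0.5 + sensitivity)
    return img > local_mean * (1.5 - sensitivity)


def _fill_holes_border_aware(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed holes, including outlines cut open by the field border.

    A shape partially outside the field leaves an open outline that plain
    hole filling ignores; reflecting the mask across the border closes those
    outlines so their interiors fill too.
    """
    pad = min(mask.shape) // 2
    padded = np.pad(mask, pad, mode="reflect")
    return ndimage.binary_fill_holes(padded)[pad:-pad, pad:-pad]


def _filter_by_area(mask: np.ndarray, area_range_px) -> np.ndarray:
    lo, hi = area_range_px
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    areas = np.bincount(labels.ravel())
    keep = (areas >= lo) & (areas <= hi)
    keep[0] = False
    return keep[labels]


def segment_grains(
    brightfield_t0: np.ndarray,
    sensitivity: float = 0.45,
    area_range_px=(1000, np.inf),
    window: int | None = None,
) -> np.ndarray:
    """Grain mask from the t = 0 brightfield image.

    Binarize with dark polarity (pillar outlines are dark), discard connected
    components outside the grain-outline area range (noise specks, bacteria),
    then fill the enclosed pillar interiors.

    Raises ``ValueError`` if no component survives the area filter.  Grains
    only partially inside the field leave open outlines; filling reflects
    the mask across the border so those interiors fill as well.
    """
    outlines = adaptive_binarize(brightfield_t0, sensitivity, "dark", window)
    kept = _filter_by_area(outlines, area_range_px)
    if not kept.any():
        raise ValueError("no grains detected")
    return _fill_holes_border_aware(kept)


def segment_bacteria(
    phase_contrast: np.ndarray,
    grain_mask: np.ndarray,
    sensitivity: float = 0.15,
    area_range_px=(10, 900),
    window: int | None = None,
) -> np.ndarray:
    """Bacteria mask from a phase-contrast image.

    Binarize with bright polarity (bacteria are slightly brighter than the
    dark background), blank out the co-registered grain pixels, then keep
    only components whose pixel area lies within ``area_range_px``
    (default 10–900 px): smaller components are noise, larger ones are
    crystals or residual pillar outlines.
    """
    img = np.asarray(phase_contrast, dtype=float)
    if img.shape != grain_mask.shape:
        raise ValueError(
            f"phase contrast {img.shape} and grain mask {grain_mask.shape} differ"
        )
    fg = adaptive_binarize(img, sensitivity, "bright", window)
    fg &= ~grain_mask.astype(bool)
    return _filter_by_area(fg, area_range_px)


def segment_crystals(
    brightfield_t: np.ndarray,
    grain_mask: np.ndarray,
    sensitivity: float = 0.45,
    closing_radius: int = 2,
    thinness_cutoff: float = 0.25,
    min_area_px: int = 900,
    speckle_px: int = 8,
    window: int | None = None,
) -> np.ndarray:
    """Crystal mask from a later-time brightfield image.

    Binarize with dark polarity (crystal outlines are dark), drop noise
    speckles smaller than ``speckle_px`` so closing cannot weld them into
    crystal-sized blobs, close small outline gaps, fill the enclosed crystal
    bodies, remove the grains and their perimeters, and finally discard
    residual artifacts:

    * components smaller than ``min_area_px`` (bacteria that leak through
      the binarization — the bacteria area filter's upper bound is the
      natural floor for crystals), and
    * thin arc-like components with isoperimetric circularity
      ``4·pi·area / perimeter² < thinness_cutoff`` — leftover pillar
      outlines that survive grain subtraction when illumination drifts
      between t = 0 and t.

    The output is exactly disjoint from ``grain_mask``.
    """
    img = np.asarray(brightfield_t, dtype=float)
    grain = np.asarray(grain_mask, dtype=bool)
    if img.shape != grain.shape:
        raise ValueError(f"brightfield {img.shape} and grain mask {grain.shape} differ")
    fg = adaptive_binarize(img, sensitivity, "dark", window)
    if speckle_px > 0:
        labels_sp, n_sp = ndimage.label(fg)
        if n_sp:
            sizes = np.bincount(labels_sp.ravel())
            keep = sizes >= speckle_px
            keep[0] = False
            fg = keep[labels_sp]
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = _fill_holes_border_aware(fg)
    # remove grains and their perimeter halo (binarization + closing bleed)
    halo = morphology.dilation(grain, morphology.disk(max(closing_radius, 1)))
    fg &= ~halo
    labels = measure.label(fg)
    out = np.zeros_like(fg)
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        perim = region.perimeter
        if perim > 0 and 4.0 * np.pi * region.area / perim**2 < thinness_cutoff:
            continue
        out[labels == region.label] = True
    out &= ~grain
    return out


def compose_phase_map(
    grain_mask: np.ndarray,
    bacteria_mask: np.ndarray,
    crystal_mask: np.ndarray,
) -> np.ndarray:
    """Compose the three binary masks into one label raster.

    Precedence grain (3) > crystal (2) > bacteria (1) > pore (0); the labels
    partition the raster.
    """
    if not (grain_mask.shape == bacteria_mask.shape == crystal_mask.shape):
        raise ValueError("masks must share a shape")
    labels = np.zeros(grain_mask.shape, dtype=np.uint8)
    labels[np.asarray(bacteria_mask, dtype=bool)] = LABEL_BACTERIA
    labels[np.asarray(crystal_mask, dtype=bool)] = LABEL_CRYSTAL
    labels[np.asarray(grain_mask, dtype=bool)] = LABEL_GRAIN
    return labels
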