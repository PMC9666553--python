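"""Plot helpers: per-position profiles and phase-map display."""

from __future__ import annotations

import numpy as np
from matplotlib import colors
from matplotlib import pyplot as plt

__all__ = ["plot_profile", "plot_phase_map"]

# pore white, bacteria cyan, crystal red, grain black
_PHASE_CMAP = colors.ListedColormap(["white", "cyan", "red", "black"])


def plot_profile(x_mm, mean, mad=None, ylabel="", ax=None):
    """Profile along the chip: replicate mean with a mean-absolute-deviation band."""
    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x_mm, dtype=float)
    m = np.asarray(mean, dtype=float)
    ax.plot(x, m, "o-", ms=4)
    if mad is not None:
        mad = np.asarray(mad, dtype=float)
        ax.fill_between(x, m - mad, m + mad, alpha=0.3)
    ax.set_xlabel("distance from inlet (mm)")
    ax.set_ylabel(ylabel)
    return ax


def plot_phase_map(labels, ax=None):
    """Render a {0 pore, 1 bacteria, 2 crystal, 3 grain} label raster."""
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(labels, cmap=_PHASE_CMAP, vmin=0, vmax=3, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
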