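"""Shared fixtures: small chip designs and synthetic scenes.

Everything is generated at test time; fields are kept small (hundreds of
microns) so the rendered rasters stay in the megapixel range.
"""

from __future__ import annotations

import numpy as np
import pytest

from micpscope.chip_geometry import ChipDesign, make_homogeneous_design
from micpscope.synth_imaging import Bacterium, Crystal, SceneState

PIXEL_SIZE = 0.29


def aligned_field(design: ChipDesign, n_cells_x: int, n_cells_y: int):
    """A field spanning whole lattice unit cells, starting at a cell corner.

    Unit-cell alignment makes the field's analytic porosity equal the lattice
    target and keeps every covered grain fully inside the field.
    """
    g = design.grains
    xs = np.unique(np.round(g[:, 0], 6))
    ys = np.unique(np.round(g[:, 1], 6))
    pitch = float(xs[1] - xs[0])
    # start at the boundary between the first and second cell: the channel
    # margin can be narrower than half a cell, the interior never is
    x0 = float(xs[0]) + pitch / 2.0
    y0 = float(ys[0]) + pitch / 2.0
    return (x0, y0, n_cells_x * pitch, n_cells_y * pitch)


@pytest.fixture(scope="session")
def small_design() -> ChipDesign:
    """Homogeneous lattice with 20 um throats in a 2 x 1.2 mm channel.

    Pitch ~99 um, grain diameter ~79 um: large enough for realistic outline
    geometry at 0.29 um/px, small enough that a few unit cells fit in a
    sub-megapixel raster.
    """
    return make_homogeneous_design(
        throat_um=20.0, porosity=0.5, length_um=2_000.0, width_um=1_200.0, depth_um=50.0
    )


@pytest.fixture(scope="session")
def small_field(small_design):
    """Field of 5 x 4 unit cells of the small design (~495 x 396 um)."""
    return aligned_field(small_design, 5, 4)


@pytest.fixture(scope="session")
def empty_design() -> ChipDesign:
    """A grain-free channel (porosity 1): isolates bacteria/crystal stages."""
    return ChipDesign(
        length_um=1_000.0,
        width_um=800.0,
        depth_um=50.0,
        porosity=1.0,
        grains=np.empty((0, 3)),
        kind="homogeneous",
        seed=None,
    )


def make_crystal(center, diameter, aspect=1.0, orientation=0.0, t_nuc=1.0):
    """Crystal record fully grown to ``diameter`` by t >= 12 h."""
    return Crystal(
        center_um=center,
        nucleation_time_h=t_nuc,
        final_diameter_um=diameter,
        aspect=aspect,
        orientation_rad=orientation,
    )


@pytest.fixture(scope="session")
def crystal_scene(empty_design):
    """20 disjoint crystals on a grain-free chip at t = 12 h (fully grown)."""
    rng = np.random.default_rng(11)
    crystals = []
    for i in range(20):
        # 5 x 4 grid with jitter: spacing 180/160 um >> max diameter
        cx = 120.0 + (i % 5) * 180.0 + rng.uniform(-15, 15)
        cy = 120.0 + (i // 5) * 160.0 + rng.uniform(-15, 15)
        crystals.append(
            make_crystal(
                (cx, cy),
                diameter=float(rng.uniform(23.0, 46.0)),
                aspect=float(rng.uniform(0.8, 1.0)),
                orientation=float(rng.uniform(0, np.pi)),
            )
        )
    return SceneState(
        t_h=12.0,
        design=empty_design,
        field_um=(0.0, 0.0, 1_000.0, 800.0),
        crystals=tuple(crystals),
    )


@pytest.fixture(scope="session")
def rod_scene(empty_design):
    """50 well-separated rods on a grain-free chip at t = 0."""
    rng = np.random.default_rng(7)
    rods = []
    for i in range(50):
        cx = 60.0 + (i % 10) * 95.0 + rng.uniform(-10, 10)
        cy = 70.0 + (i // 10) * 140.0 + rng.uniform(-10, 10)
        rods.append(
            Bacterium(
                center_um=(cx, cy),
                length_um=float(rng.uniform(2.0, 4.0)),
                width_um=1.0,
                orientation_rad=float(rng.uniform(0, 2 * np.pi)),
            )
        )
    return SceneState(
        t_h=0.0,
        design=empty_design,
        field_um=(0.0, 0.0, 1_000.0, 800.0),
        bacteria=tuple(rods),
    )
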