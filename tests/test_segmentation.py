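"""Segmentation: adaptive thresholding and the three-phase workflow."""

import numpy as np
import pytest
from scipy import ndimage

from micpscope.chip_geometry import rasterize
from micpscope.segmentation import (
    adaptive_binarize,
    compose_phase_map,
    extract_green_normalized,
    segment_bacteria,
    segment_crystals,
    segment_grains,
)
from micpscope.synth_imaging import (
    Bacterium,
    NoiseParams,
    SceneState,
    ground_truth,
    render_brightfield,
    render_phase_contrast,
)

from conftest import make_crystal

NO_NOISE = NoiseParams(sigma=0.0, gradient_amplitude=0.0)
GRADIENT_ONLY = NoiseParams(sigma=0.0, gradient_amplitude=0.05)


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestGreenChannel:
    def test_rgb_pixel_takes_green_over_255(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (10, 200, 30)
        out = extract_green_normalized(img)
        assert out[0, 0] == pytest.approx(200 / 255)

    def test_black_image_maps_to_zero(self):
        assert not extract_green_normalized(np.zeros((4, 4, 3), dtype=np.uint8)).any()

    def test_grayscale_float_passthrough(self):
        img = np.random.default_rng(0).uniform(size=(5, 5))
        assert np.array_equal(extract_green_normalized(img), img)

    def test_unsupported_dtype_raises(self):
        with pytest.raises(ValueError, match="dtype"):
            extract_green_normalized(np.zeros((4, 4), dtype=np.int32))


class TestAdaptiveBinarize:
    def test_uniform_image_yields_empty_mask(self):
        img = np.full((64, 64), 0.6)
        assert not adaptive_binarize(img, 0.45, "dark").any()
        assert not adaptive_binarize(img, 0.45, "bright").any()

    def test_dark_disk_boundary_detected(self):
        yy, xx = np.mgrid[:128, :128]
        img = np.full((128, 128), 0.9)
        ring = np.abs(np.hypot(yy - 64, xx - 64) - 40) < 2
        img[ring] = 0.2
        mask = adaptive_binarize(img, 0.45, "dark")
        assert mask[ring].all()

    @pytest.mark.parametrize("polarity", ["dark", "bright"])
    def test_foreground_monotone_in_sensitivity(self, polarity):
        img = np.random.default_rng(2).uniform(size=(96, 96))
        counts = [
            adaptive_binarize(img, s, polarity).sum() for s in (0.1, 0.2, 0.35, 0.5, 0.8)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_window_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="window"):
            adaptive_binarize(np.zeros((16, 16)), 0.5, "dark", window=31)

    def test_invalid_sensitivity_raises(self):
        with pytest.raises(ValueError, match="sensitivity"):
            adaptive_binarize(np.zeros((16, 16)), 1.5, "dark")


@pytest.fixture(scope="module")
def lattice_scene(small_design, small_field):
    return SceneState(t_h=0.0, design=small_design, field_um=small_field)


@pytest.fixture(scope="module")
def lattice_truth(small_design, small_field):
    return rasterize(small_design, small_field, 0.29).raster


class TestSegmentGrains:
    def test_noise_free_grain_recovery(self, lattice_scene, lattice_truth):
        mask = segment_grains(render_brightfield(lattice_scene, 0.29, NO_NOISE))
        assert iou(mask, lattice_truth) >= 0.98

    def test_grain_count_unchanged_by_bacteria(self, lattice_scene, small_design):
        bf_plain = render_brightfield(lattice_scene, 0.29, NO_NOISE)
        # add rods at pore-space cell corners
        pitch = 2 * abs(lattice_scene.field_um[0] - small_design.grains[:, 0].min())
        x0, y0 = lattice_scene.field_um[:2]
        rods = tuple(
            Bacterium((x0 + i * pitch, y0 + j * pitch), 3.0, orientation_rad=0.7 * (i + j))
            for i in range(1, 4)
            for j in range(1, 3)
        )
        scene_rods = SceneState(
            t_h=0.0, design=small_design, field_um=lattice_scene.field_um, bacteria=rods
        )
        bf_rods = render_brightfield(scene_rods, 0.29, NO_NOISE)
        _, n_plain = ndimage.label(segment_grains(bf_plain))
        _, n_rods = ndimage.label(segment_grains(bf_rods))
        assert n_plain == n_rods

    def test_no_grains_raises(self):
        with pytest.raises(ValueError, match="no grains"):
            segment_grains(np.full((256, 256), 0.9))


class TestSegmentBacteria:
    def test_each_separated_rod_recovered(self, rod_scene):
        pc = render_phase_contrast(rod_scene, 0.29, NO_NOISE)
        grain = np.zeros(pc.shape, dtype=bool)
        mask = segment_bacteria(pc, grain)
        _, n = ndimage.label(mask)
        assert n == len(rod_scene.bacteria) == 50

    def test_area_filter_removes_specks_and_blobs(self):
        img = np.full((300, 300), 0.1)
        img[10:12, 10:12] = 0.3  # 4 px speck
        img[100:160, 100:160] = 0.8  # 3600 px crystal-like blob
        img[200:210, 200:214] = 0.3  # 140 px rod-cluster-sized
        mask = segment_bacteria(img, np.zeros_like(img, dtype=bool))
        _, n = ndimage.label(mask)
        assert n == 1
        assert mask[205, 205] and not mask[10, 10] and not mask[120, 120]

    def test_rod_on_grain_outline_clipped_to_pore(self, small_design, small_field):
        # pick the grain nearest the field centre so the rod is in view
        x0, y0, ex, ey = small_field
        g = small_design.grains
        idx = np.argmin((g[:, 0] - (x0 + ex / 2)) ** 2 + (g[:, 1] - (y0 + ey / 2)) ** 2)
        gx, gy, gr = g[idx]
        rod = Bacterium((gx + gr, gy), 4.0, 1.0, 0.0)  # straddles the boundary
        scene = SceneState(t_h=0.0, design=small_design, field_um=small_field,
                           bacteria=(rod,))
        pc = render_phase_contrast(scene, 0.29, NO_NOISE)
        grain = rasterize(small_design, small_field, 0.29).raster
        mask = segment_bacteria(pc, grain)
        assert mask.sum() > 0
        assert not (mask & grain).any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="grain mask"):
            segment_bacteria(np.zeros((64, 64)), np.zeros((32, 32), dtype=bool))


class TestSegmentCrystals:
    def test_disjoint_crystals_counted_and_sized(self, crystal_scene):
        bf = render_brightfield(crystal_scene, 0.29, NO_NOISE)
        grain = np.zeros(bf.shape, dtype=bool)
        mask = segment_crystals(bf, grain)
        labels, n = ndimage.label(mask)
        assert n == len(crystal_scene.crystals) == 20
        # greedy match by centroid: detected areas within 10% of truth
        truth_areas = {
            tuple(np.round(c.center_um)): c.area_um2(12.0) for c in crystal_scene.crystals
        }
        for region_label in range(1, n + 1):
            sel = labels == region_label
            area = sel.sum() * 0.29**2
            ys, xs = np.nonzero(sel)
            cx, cy = xs.mean() * 0.29, ys.mean() * 0.29
            nearest = min(
                truth_areas, key=lambda c: (c[0] - cx) ** 2 + (c[1] - cy) ** 2
            )
            assert area == pytest.approx(truth_areas[nearest], rel=0.10)

    def test_t0_image_has_no_crystals(self, lattice_scene):
        bf0 = render_brightfield(lattice_scene, 0.29, NO_NOISE)
        grain = segment_grains(bf0)
        assert not segment_crystals(bf0, grain).any()

    def test_residual_pillar_rings_removed(self, small_design, small_field):
        # imperfect grain mask (eroded) leaves ring remnants after subtraction;
        # the thinness rule must drop them without losing crystals
        pitch = 2 * abs(small_field[0] - small_design.grains[:, 0].min())
        x0, y0 = small_field[:2]
        scene = SceneState(
            t_h=12.0, design=small_design, field_um=small_field,
            crystals=(make_crystal((x0 + pitch, y0 + pitch), 30.0),
                      make_crystal((x0 + 3 * pitch, y0 + 2 * pitch), 35.0)),
        )
        bf = render_brightfield(scene, 0.29, GRADIENT_ONLY)
        grain_true = rasterize(small_design, small_field, 0.29).raster
        grain_eroded = ndimage.binary_erosion(grain_true, iterations=6)
        mask_clean = segment_crystals(bf, grain_true)
        mask_ringy = segment_crystals(bf, grain_eroded)
        _, n_clean = ndimage.label(mask_clean)
        _, n_ringy = ndimage.label(mask_ringy)
        assert n_clean == n_ringy == 2

    def test_output_disjoint_from_grain_mask(self, small_design, small_field):
        pitch = 2 * abs(small_field[0] - small_design.grains[:, 0].min())
        scene = SceneState(
            t_h=12.0, design=small_design, field_um=small_field,
            crystals=(make_crystal((small_field[0] + pitch, small_field[1] + pitch), 30.0),),
        )
        bf = render_brightfield(scene, 0.29, NoiseParams(0.02, 0.05, 4))
        grain = rasterize(small_design, small_field, 0.29).raster
        mask = segment_crystals(bf, grain)
        assert not (mask & grain).any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="grain mask"):
            segment_crystals(np.zeros((64, 64)), np.zeros((32, 32), dtype=bool))


class TestComposePhaseMap:
    def test_precedence_and_partition(self):
        shape = (8, 8)
        grain = np.zeros(shape, dtype=bool)
        bact = np.zeros(shape, dtype=bool)
        cryst = np.zeros(shape, dtype=bool)
        grain[0, 0] = bact[0, 0] = cryst[0, 0] = True  # grain wins
        bact[1, 1] = cryst[1, 1] = True  # crystal beats bacteria
        bact[2, 2] = True
        labels = compose_phase_map(grain, bact, cryst)
        assert labels[0, 0] == 3 and labels[1, 1] == 2 and labels[2, 2] == 1
        hist = np.bincount(labels.ravel(), minlength=4)
        assert hist.sum() == labels.size
        assert hist[0] == labels.size - 3

    def test_empty_masks_give_all_pore(self):
        z = np.zeros((4, 4), dtype=bool)
        assert not compose_phase_map(z, z, z).any()

    def test_shape_mismatch_raises(self):
        z = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="shape"):
            compose_phase_map(z, z, np.zeros((5, 5), dtype=bool))


class TestWorkflowIdempotence:
    def test_ideal_modality_images_recover_phase_map(self, small_design, small_field):
        """Noise-free renders of a mixed scene recover the ground-truth map."""
        pitch = 2 * abs(small_field[0] - small_design.grains[:, 0].min())
        x0, y0 = small_field[:2]
        scene = SceneState(
            t_h=12.0, design=small_design, field_um=small_field,
            bacteria=(Bacterium((x0 + 2 * pitch, y0 + pitch), 3.0, 1.0, 0.4),),
            crystals=(make_crystal((x0 + pitch, y0 + 2 * pitch), 30.0),),
        )
        truth = ground_truth(scene, 0.29)
        bf0 = render_brightfield(
            SceneState(t_h=0.0, design=small_design, field_um=small_field,
                       bacteria=scene.bacteria),
            0.29, NO_NOISE,
        )
        pc0 = render_phase_contrast(scene, 0.29, NO_NOISE)
        bft = render_brightfield(scene, 0.29, NO_NOISE)
        grain = segment_grains(bf0)
        bact = segment_bacteria(pc0, grain)
        cryst = segment_crystals(bft, grain)
        recovered = compose_phase_map(grain, bact, cryst)
        mismatch = (recovered != truth).mean()
        assert mismatch < 0.005  # boundary pixels only
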