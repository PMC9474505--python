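"""Voxel morphometry: volumes, contact areas, heights, tissue measures."""

import numpy as np
import pytest

from optomorph.morphometry import (
    cell_height,
    cell_volume,
    contact_area,
    longest_diameter,
    measure_cells,
    normalize_series,
    projected_area,
    thickness_measure,
)
from optomorph.stack import LabelVolume

V = 0.207


def prism(footprint=(20, 20), depth=48, pad=2):
    """Single-cell prism label volume with empty space below."""
    lab = np.zeros((depth + pad, footprint[0] + 4, footprint[1] + 4), np.int32)
    lab[:depth, 2 : 2 + footprint[0], 2 : 2 + footprint[1]] = 1
    return LabelVolume(lab, (V, V, V))


class TestCellBasics:
    def test_cube_volume_is_voxel_count_times_voxel_volume(self):
        lab = np.zeros((12, 12, 12), np.int32)
        lab[1:11, 1:11, 1:11] = 4
        vol = LabelVolume(lab, (V, V, V))
        assert cell_volume(vol, 4) == pytest.approx(1000 * V**3)

    def test_absent_label_raises(self):
        vol = prism()
        with pytest.raises(KeyError):
            cell_volume(vol, 99)
        with pytest.raises(KeyError):
            cell_height(vol, 99)

    def test_prism_height_spans_voxels(self):
        assert cell_height(prism(depth=48), 1) == pytest.approx(48 * V)

    def test_tilted_apical_surface_uses_mean_contact(self):
        """A staircase apical surface: height uses the mean contact z,
        verified against brute force over the contact voxels."""
        lab = np.zeros((30, 4, 10), np.int32)
        for col in range(10):
            top = col // 4  # 0,0,0,0,1,1,1,1,2,2
            lab[top:25, :, col] = 1
        vol = LabelVolume(lab, (V, V, V))
        # brute force: apical contact = topmost voxel per column
        tops = [col // 4 for col in range(10) for _ in range(4)]
        expected = (24 - np.mean(tops) + 1) * V
        assert cell_height(vol, 1) == pytest.approx(expected)

    def test_prism_contact_areas(self):
        vol = prism(footprint=(20, 20))
        assert contact_area(vol, 1, "apical") == pytest.approx(400 * V * V)
        assert contact_area(vol, 1, "basal") == pytest.approx(400 * V * V)

    def test_pointlike_apex_has_tiny_apical_area(self):
        lab = np.zeros((10, 9, 9), np.int32)
        lab[1:9, 2:7, 2:7] = 1
        lab[0, 4, 4] = 1  # single-voxel apex above the body
        vol = LabelVolume(lab, (V, V, V))
        # apex voxel + the body ring visible from above around it
        apex_only = contact_area(vol, 1, "apical")
        assert apex_only <= 25 * V * V

    def test_side_argument_validated(self):
        with pytest.raises(ValueError):
            contact_area(prism(), 1, "lateral")

    def test_contact_area_invariant_under_rotation(self, small_monolayer):
        gt = small_monolayer.rasterize_labels(0.207, 0.207)[0]
        rot = LabelVolume(np.rot90(gt.labels, axes=(1, 2)).copy(), gt.voxel_size)
        for lab_id in [1, 5, 9]:
            assert contact_area(gt, lab_id, "apical") == pytest.approx(
                contact_area(rot, lab_id, "apical")
            )


class TestMeasureAgainstGroundTruth:
    def test_ground_truth_raster_morphometry(self, monolayer_5x5):
        """On the isotropic ground-truth raster, measured (V, Aa, Ab, h)
        track the analytic table within voxelisation tolerance."""
        mono = monolayer_5x5
        gt = mono.rasterize_labels(0.207, 0.207)[0]
        df = measure_cells(gt).set_index("label")
        truth = mono.truth[mono.truth.frame == 0].set_index("label")
        for lab in truth.index:
            assert df.loc[lab, "volume_um3"] == pytest.approx(
                truth.loc[lab, "volume_um3"], rel=0.05
            )
            assert df.loc[lab, "apical_area_um2"] == pytest.approx(
                truth.loc[lab, "apical_area_um2"], rel=0.05
            )
            assert abs(df.loc[lab, "height_um"] - truth.loc[lab, "height_um"]) <= 0.207

    def test_linear_taper_consistency_of_measurements(self, monolayer_5x5):
        """Measured quantities satisfy |h - 2V/(Aa+Ab)| within 2 voxels."""
        gt = monolayer_5x5.rasterize_labels(0.207, 0.207)[0]
        df = measure_cells(gt)
        implied = 2 * df.volume_um3 / (df.apical_area_um2 + df.basal_area_um2)
        assert np.all(np.abs(df.height_um - implied) <= 2 * 0.207)

    def test_label_partition_conserves_tissue_volume(self, monolayer_5x5):
        gt = monolayer_5x5.rasterize_labels(0.207, 0.207)[0]
        df = measure_cells(gt)
        tissue = np.count_nonzero(gt.labels) * gt.voxel_volume
        assert df.volume_um3.sum() == pytest.approx(tissue, rel=1e-9)


class TestSeriesAndTissueMeasures:
    def test_normalize_series(self):
        assert np.allclose(normalize_series([10, 8, 9], 0), [1.0, 0.8, 0.9])
        assert np.allclose(normalize_series([5, 5, 5], 1), 1.0)
        with pytest.raises(ValueError):
            normalize_series([0, 1, 2], 0)

    def test_projected_area_of_disc(self):
        from skimage.draw import disk

        mask = np.zeros((300, 300), bool)
        rr, cc = disk((150, 150), 100)
        mask[rr, cc] = True
        area = projected_area(mask, pixel_size=0.5)
        assert area == pytest.approx(np.pi * 50.0**2, rel=0.03)

    def test_projected_area_empty_frame(self):
        assert projected_area(np.zeros((64, 64), bool), pixel_size=0.5) == 0.0

    def test_longest_diameter_circle_and_pixel(self):
        from skimage.draw import disk

        mask = np.zeros((200, 200), bool)
        rr, cc = disk((100, 100), 60)
        mask[rr, cc] = True
        assert longest_diameter(mask, 0.5) == pytest.approx(60.0, abs=0.5)
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert longest_diameter(single, 0.5) == pytest.approx(0.5)

    def test_longest_diameter_ellipse_against_brute_force(self):
        from skimage.draw import ellipse

        mask = np.zeros((300, 300), bool)
        rr, cc = ellipse(150, 150, 45, 135)
        mask[rr, cc] = True
        fast = longest_diameter(mask, 1.0)
        # brute force over all boundary-pixel pairs
        from scipy import ndimage

        boundary = mask & ~ndimage.binary_erosion(mask)
        pts = np.column_stack(np.nonzero(boundary)).astype(float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert fast == pytest.approx(d.max() + 1.0, abs=1e-9)
        assert fast == pytest.approx(2 * 135, abs=2.0)

    def test_thickness_parallel_bands(self):
        x = np.linspace(0, 100, 200)
        apical = np.column_stack([x, np.zeros_like(x)])
        basal = np.column_stack([x, np.full_like(x, 20.0)])
        t = thickness_measure(apical, basal, n_repeats=3, seed=0)
        assert t == pytest.approx(20.0, abs=0.2)
        t1 = thickness_measure(apical, basal, n_repeats=1, seed=4)
        assert t1 == pytest.approx(20.0, abs=0.2)

    def test_thickness_crossing_boundaries_rejected(self):
        a = np.array([[0.0, 0.0], [10.0, 10.0]])
        b = np.array([[0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValueError, match="cross"):
            thickness_measure(a, b)

    def test_thickened_epithelium_recovered(self):
        """A 14.3% thicker band is recovered within 2 percentage points."""
        theta = np.linspace(-0.6, 0.6, 400)
        r_ap, t0 = 100.0, 12.0
        apical = np.column_stack([r_ap * np.sin(theta), r_ap * (1 - np.cos(theta))])
        for factor in (1.0, 1.143):
            basal = np.column_stack(
                [(r_ap + t0 * factor) * np.sin(theta),
                 (r_ap + t0 * factor) * (1 - np.cos(theta)) - t0 * factor]
            )
            t = thickness_measure(apical, basal, n_repeats=3, seed=1)
            assert t / t0 == pytest.approx(factor, abs=0.02)
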