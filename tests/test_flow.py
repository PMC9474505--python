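"""Single-pass PIV and zonal radial reduction."""

import numpy as np
import pandas as pd
import pytest

from optomorph.flow import (
    VectorField,
    average_experiments,
    classify_zones,
    distance_profile,
    piv_single_pass,
    radial_component,
    tangential_component,
    zonal_series,
)
from optomorph.synthetic import generate_flow_field
from optomorph.tracking import StimulationROI

from conftest import speckle_texture


def brute_force_shift(a, b, max_shift=8):
    """Oracle: spatial cross-correlation by explicit search."""
    best, arg = -np.inf, (0, 0)
    a0 = a - a.mean()
    b0 = b - b.mean()
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(b0, -dy, axis=0), -dx, axis=1)
            score = float((a0 * shifted).sum())
            if score > best:
                best, arg = score, (dx, dy)
    return arg


class TestPIV:
    @pytest.mark.parametrize("shift", [(1, 0), (-2, 3), (5, -5), (0, -4)])
    def test_integer_translation_recovered(self, shift):
        dx, dy = shift
        tex = speckle_texture((192, 192), sigma=1.5, seed=10)
        moved = np.roll(np.roll(tex, dy, axis=0), dx, axis=1)
        f = piv_single_pass(tex, moved, window=64)
        assert f.valid.all()
        assert np.allclose(f.u, dx, atol=0.2)
        assert np.allclose(f.v, dy, atol=0.2)
        # brute-force correlation oracle on the central window
        wa = tex[64:128, 64:128]
        wb = moved[64:128, 64:128]
        assert brute_force_shift(wa, wb) == (dx, dy)

    def test_identical_frames_zero_field(self):
        tex = speckle_texture((128, 128), seed=3)
        f = piv_single_pass(tex, tex, window=64)
        assert np.allclose(f.u, 0) and np.allclose(f.v, 0)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            piv_single_pass(np.zeros((32, 32)), np.zeros((32, 32)), window=64)

    def test_uncorrelated_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(64, 64))
        b = rng.normal(size=(64, 64))
        f = piv_single_pass(a, b, window=64)
        assert not f.valid.any()

    def test_pixel_size_converts_to_microns(self):
        tex = speckle_texture((128, 128), seed=5)
        moved = np.roll(tex, 3, axis=1)
        f = piv_single_pass(tex, moved, window=64, pixel_size=0.5)
        assert np.allclose(f.u, 1.5, atol=0.1)


class TestComponents:
    def _field(self, u, v):
        x = np.array([10.0, 30.0])
        y = np.array([10.0, 30.0])
        return VectorField(x=x, y=y, u=np.full((2, 2), u), v=np.full((2, 2), v))

    def test_inward_unit_vectors_project_to_one(self):
        center = (50.0, 50.0)
        f = generate_flow_field(center, lambda d: 1.0, 10.0, (100.0, 100.0), 1)[0]
        assert np.allclose(radial_component(f, center), 1.0)
        assert np.allclose(tangential_component(f, center), 0.0, atol=1e-12)

    def test_decomposition_identity(self):
        f = self._field(0.3, -0.7)
        c = (17.0, 5.0)
        r = radial_component(f, c)
        t = tangential_component(f, c)
        assert np.allclose(r**2 + t**2, f.u**2 + f.v**2)

    def test_vector_at_center_contributes_zero(self):
        f = self._field(1.0, 1.0)
        r = radial_component(f, (10.0, 10.0))
        assert r[0, 0] == 0.0


class TestZones:
    ROI = StimulationROI(40.0, 60.0, 40.0, 60.0)

    def _grid_field(self):
        x = np.arange(2.5, 100.0, 5.0)
        y = np.arange(2.5, 100.0, 5.0)
        return VectorField(x=x, y=y, u=np.zeros((20, 20)), v=np.zeros((20, 20)))

    def test_zone_examples(self):
        f = self._grid_field()
        zones = classify_zones(f, self.ROI, adjacent_width=13.0)
        pos = f.positions
        centre_idx = np.unravel_index(np.argmin(np.linalg.norm(pos - [50, 50], axis=-1)), (20, 20))
        assert zones[centre_idx] == "stimulated"
        near_idx = np.unravel_index(np.argmin(np.linalg.norm(pos - [61, 50], axis=-1)), (20, 20))
        assert zones[near_idx] == "adjacent"
        assert zones[0, 0] == "outer"

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            classify_zones(self._grid_field(), self.ROI, adjacent_width=0.0)

    def test_constant_inward_accumulates_linearly(self):
        center = self.ROI.center
        fields = generate_flow_field(center, lambda d: 0.1, 5.0, (100.0, 100.0), 10)
        zones = classify_zones(fields[0], self.ROI, 13.0)
        df = zonal_series(fields, zones, center)
        last = df.groupby("zone").cumulative_um.last()
        assert np.allclose(last.to_numpy(), 1.0, atol=1e-9)

    def test_symmetric_in_out_schedule_cancels(self):
        center = self.ROI.center
        tp = np.concatenate([np.ones(5), -np.ones(5)])
        fields = generate_flow_field(center, lambda d: 0.2, 5.0, (100.0, 100.0), 10, tp)
        zones = classify_zones(fields[0], self.ROI, 13.0)
        df = zonal_series(fields, zones, center)
        peak = df.groupby("zone").cumulative_um.max()
        last = df.groupby("zone").cumulative_um.last()
        assert np.all(np.abs(last.to_numpy()) < 0.01 * np.abs(peak.to_numpy()))

    def test_linearity_in_the_field(self):
        center = self.ROI.center
        f1 = generate_flow_field(center, lambda d: 0.1, 5.0, (100.0, 100.0), 1)[0]
        f2 = generate_flow_field(center, lambda d: 0.05 * d / 50, 5.0, (100.0, 100.0), 1)[0]
        fsum = VectorField(x=f1.x, y=f1.y, u=f1.u + f2.u, v=f1.v + f2.v)
        zones = classify_zones(f1, self.ROI, 13.0)
        a = zonal_series([f1], zones, center).mean_radial_um.to_numpy()
        b = zonal_series([f2], zones, center).mean_radial_um.to_numpy()
        ab = zonal_series([fsum], zones, center).mean_radial_um.to_numpy()
        assert np.allclose(ab, a + b)

    def test_adjacent_peaked_profile_ordering(self):
        """Magnitude peaking just outside the ROI: adjacent accumulates
        the most, as generated."""
        roi = self.ROI
        center = roi.center

        def mag(d_center):
            d_edge = abs(d_center - 16.0)
            return 0.1 * max(0.0, 1.0 - d_edge / 30.0)

        fields = generate_flow_field(center, mag, 5.0, (100.0, 100.0), 5)
        zones = classify_zones(fields[0], roi, 10.0)
        last = zonal_series(fields, zones, center).groupby("zone").cumulative_um.last()
        assert last["adjacent"] > last["stimulated"]
        assert last["adjacent"] > last["outer"]


class TestDistanceProfile:
    ROI = StimulationROI(40.0, 60.0, 40.0, 60.0)

    def test_monotone_profile_recovered(self):
        fields = generate_flow_field(
            self.ROI.center, lambda d: 0.2 * max(0.0, 1.0 - d / 60.0), 4.0,
            (100.0, 100.0), 3,
        )
        prof = distance_profile(fields, self.ROI, bin_width=5.0)
        vals = prof.cumulative_radial_um.to_numpy()
        assert np.all(np.diff(vals[:6]) < 0)

    def test_zero_field_all_bins_zero(self):
        fields = generate_flow_field(self.ROI.center, lambda d: 0.0, 4.0, (100.0, 100.0), 2)
        prof = distance_profile(fields, self.ROI, bin_width=5.0)
        assert np.allclose(prof.cumulative_radial_um, 0.0)

    def test_single_bin_when_width_covers_field(self):
        fields = generate_flow_field(self.ROI.center, lambda d: 0.1, 4.0, (100.0, 100.0), 1)
        prof = distance_profile(fields, self.ROI, bin_width=500.0)
        assert len(prof) == 1


class TestAveraging:
    def _series(self, scale):
        fields = generate_flow_field((50.0, 50.0), lambda d: scale * 0.1, 10.0, (100.0, 100.0), 3)
        return fields

    def test_average_of_identical_is_itself(self):
        s = self._series(1.0)
        avg = average_experiments([s, s])
        assert np.allclose(avg[0].u, s[0].u)

    def test_average_of_opposite_fields_is_zero(self):
        avg = average_experiments([self._series(1.0), self._series(-1.0)])
        assert np.allclose(avg[0].u, 0) and np.allclose(avg[0].v, 0)

    def test_mismatched_frame_counts_rejected(self):
        with pytest.raises(ValueError):
            average_experiments([self._series(1.0), self._series(1.0)[:2]])

    def test_zonal_table_averaging(self):
        roi = StimulationROI(40.0, 60.0, 40.0, 60.0)
        fields = self._series(1.0)
        zones = classify_zones(fields[0], roi, 13.0)
        df = zonal_series(fields, zones, roi.center)
        avg = average_experiments([df, df])
        pd.testing.assert_frame_equal(avg, df)
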