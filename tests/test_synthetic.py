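"""Generator contracts: geometry, program kinetics, determinism, noise."""

import numpy as np
import pytest

from optomorph.synthetic import (
    ConstrictionProgram,
    SyntheticTissueSpec,
    generate_colony_profile,
    generate_flow_field,
    generate_junction_image,
    generate_monolayer,
    generate_translocation_series,
)
from optomorph.tracking import StimulationROI

from conftest import centered_roi


class TestMonolayerGroundTruth:
    def test_prism_case_heights_and_areas(self, small_monolayer):
        """taper = 1, no program: every cell is a prism of the tissue height."""
        tr = small_monolayer.truth
        assert np.allclose(tr.height_um, small_monolayer.spec.tissue_height)
        assert np.allclose(tr.apical_area_um2, tr.basal_area_um2)

    def test_linear_taper_identity_exact(self, constricted_timelapse):
        """h = 2V/(Aa+Ab) holds to machine precision for every generated cell."""
        mono, _, _ = constricted_timelapse
        tr = mono.truth
        lhs = tr.height_um
        rhs = 2 * tr.volume_um3 / (tr.apical_area_um2 + tr.basal_area_um2)
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_program_area_schedule_followed(self, constricted_timelapse):
        """Total stimulated apical area follows the programmed schedule."""
        mono, _, program = constricted_timelapse
        tr = mono.truth
        stim = tr[tr["class"] == "stimulated"]
        a0 = stim[stim.frame == 0].apical_area_um2.sum()
        for f, t in enumerate(mono.times):
            at = stim[stim.frame == f].apical_area_um2.sum()
            assert at / a0 == pytest.approx(program.area_factor(float(t)), abs=1e-6)

    def test_plateau_height_closed_form(self):
        """At the plateau, stimulated heights equal the closed form
        h0 (Aa0+Ab) / (g·Aa0 + Ab), cross-checked by numeric integration
        of the linear area profile."""
        spec = SyntheticTissueSpec(grid_shape=(5, 5), n_frames=2, frame_interval=500.0, seed=11)
        program = ConstrictionProgram(roi=centered_roi(spec), plateau_reduction=0.25, tau_on=5.0)
        mono = generate_monolayer(spec, program)
        tr = mono.truth
        stim = tr[tr["class"] == "stimulated"]
        f0 = stim[stim.frame == 0].set_index("label")
        f1 = stim[stim.frame == 1].set_index("label")
        h0 = spec.tissue_height
        for lab in f0.index:
            aa0, ab = f0.loc[lab, "apical_area_um2"], f0.loc[lab, "basal_area_um2"]
            aa1 = f1.loc[lab, "apical_area_um2"]
            expected = h0 * (aa0 + ab) / (aa1 + ab)
            assert f1.loc[lab, "height_um"] == pytest.approx(expected, rel=1e-9)
            # independent oracle: integrate the linear area profile numerically
            z = np.linspace(0, 1, 20001)
            area = aa1 + z * (ab - aa1)
            v_quad = np.trapezoid(area, z) * f1.loc[lab, "height_um"]
            assert v_quad == pytest.approx(f1.loc[lab, "volume_um3"], rel=1e-6)

    def test_volume_conserved_exactly_in_truth(self, constricted_timelapse):
        mono, _, _ = constricted_timelapse
        per_cell = mono.truth.groupby("label").volume_um3
        assert float(per_cell.std().max()) < 1e-9

    def test_voxelized_volume_constancy(self, constricted_timelapse):
        """On the isotropic raster, per-cell voxel volume drifts < 2%."""
        mono, _, _ = constricted_timelapse
        v = mono.spec.voxel_size_xy
        labs = mono.rasterize_labels(v, v)
        counts = []
        for lab in labs:
            c = np.bincount(lab.labels.ravel(), minlength=26)[1:26]
            counts.append(c * lab.voxel_volume)
        counts = np.array(counts)
        dev = np.abs(counts / counts.mean(axis=0) - 1.0)
        assert dev.max() < 0.02

    def test_determinism_and_noise_seed_independence(self):
        spec = SyntheticTissueSpec(grid_shape=(2, 2), n_frames=1, seed=5)
        a = generate_monolayer(spec)
        b = generate_monolayer(spec)
        assert np.array_equal(a.stacks[0].data, b.stacks[0].data)
        assert np.array_equal(a.labels[0].labels, b.labels[0].labels)
        # different noise stream: image changes, ground-truth labels do not
        spec_noise = SyntheticTissueSpec(grid_shape=(2, 2), n_frames=1, seed=5, noise_seed=999)
        c = generate_monolayer(spec_noise)
        assert not np.array_equal(a.stacks[0].data, c.stacks[0].data)
        assert np.array_equal(a.labels[0].labels, c.labels[0].labels)

    def test_roi_outside_field_rejected(self):
        spec = SyntheticTissueSpec(grid_shape=(2, 2), n_frames=1, seed=0)
        roi = StimulationROI(-5.0, 10.0, 0.0, 10.0)
        with pytest.raises(ValueError, match="outside"):
            generate_monolayer(spec, ConstrictionProgram(roi=roi))

    def test_invalid_program_parameters_rejected(self):
        spec = SyntheticTissueSpec(grid_shape=(2, 2), n_frames=1, seed=0)
        with pytest.raises(ValueError):
            ConstrictionProgram(roi=centered_roi(spec, size=5.0), plateau_reduction=1.0)
        with pytest.raises(ValueError):
            SyntheticTissueSpec(grid_shape=(0, 1))
        with pytest.raises(ValueError):
            SyntheticTissueSpec(taper=-1.0)


class TestFlowFieldGenerator:
    def test_uniform_inward_magnitude(self):
        fields = generate_flow_field((50.0, 50.0), lambda d: 1.0, 10.0, (100.0, 100.0), 1)
        f = fields[0]
        mag = np.hypot(f.u, f.v)
        assert np.allclose(mag, 1.0)
        from optomorph.flow import radial_component

        rad = radial_component(f, (50.0, 50.0))
        assert np.allclose(rad, 1.0)

    def test_zero_magnitude_gives_zero_field(self):
        f = generate_flow_field((50.0, 50.0), lambda d: 0.0, 10.0, (100.0, 100.0), 3)
        assert all(np.all(fi.u == 0) and np.all(fi.v == 0) for fi in f)

    def test_displacement_vanishes_beyond_support(self):
        """A profile decaying to zero at 60 µm leaves no motion farther out."""
        center = (80.0, 80.0)
        f = generate_flow_field(
            center, lambda d: max(0.0, 1.0 - d / 60.0), 8.0, (160.0, 160.0), 1
        )[0]
        pos = f.positions
        d = np.linalg.norm(pos - np.array(center), axis=-1)
        mag = np.hypot(f.u, f.v)
        assert np.all(mag[d > 60.0] == 0)
        assert np.all(mag[d < 55.0] > 0)


class TestColonyAndJunctionGenerators:
    def test_arc_curvature_definition(self):
        _, k = generate_colony_profile(100.0, 90.0, 8.0, (256, 256), 0.5)
        assert k == pytest.approx(0.01)
        _, k0 = generate_colony_profile(np.inf, 90.0, 8.0, (256, 256), 0.5)
        assert k0 == 0.0

    def test_radius_must_exceed_thickness(self):
        with pytest.raises(ValueError):
            generate_colony_profile(5.0, 90.0, 8.0, (64, 64), 0.5)

    def test_colony_determinism(self):
        a, _ = generate_colony_profile(100.0, 90.0, 8.0, (128, 128), 0.5, noise_sd=0.1, seed=3)
        b, _ = generate_colony_profile(100.0, 90.0, 8.0, (128, 128), 0.5, noise_sd=0.1, seed=3)
        assert np.array_equal(a, b)

    def test_junction_image_ratio_exact_before_noise(self):
        img, mask = generate_junction_image(1.75, junction_width=7)
        assert img[mask].mean() / img[~mask].mean() == pytest.approx(1.75)
        img1, mask1 = generate_junction_image(1.0)
        assert img1[mask1].mean() == pytest.approx(img1[~mask1].mean())

    def test_translocation_series_follows_exponentials(self):
        t = np.array([0.0, 30.0, 60.0, 70.0, 180.0, 223.3])
        y = generate_translocation_series(
            t, (60.0, 180.0), baseline=1.0, amplitude=0.75, tau_on=10.0, tau_off=43.3
        )
        assert y[0] == 1.0 and y[1] == 1.0
        assert y[3] == pytest.approx(1.0 + 0.75 * (1 - np.exp(-1.0)))
        amp_end = 0.75 * (1 - np.exp(-12.0))
        assert y[5] == pytest.approx(1.0 + amp_end * np.exp(-1.0))
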