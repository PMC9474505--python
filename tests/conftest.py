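"""Shared fixtures: small synthetic datasets reused across the suite.

Heavy fixtures are session-scoped so the monolayer is generated and
segmented once.
"""

from __future__ import annotations

import numpy as np
import pytest

from optomorph.segmentation import rescale_isotropic, segment_cells_3d
from optomorph.synthetic import ConstrictionProgram, SyntheticTissueSpec, generate_monolayer
from optomorph.tracking import StimulationROI


def centered_roi(spec: SyntheticTissueSpec, size: float = 26.5, t_start: float = 1.0):
    w, h = spec.field_size
    return StimulationROI(
        x_min=w / 2 - size / 2, x_max=w / 2 + size / 2,
        y_min=h / 2 - size / 2, y_max=h / 2 + size / 2,
        t_start=t_start,
    )


@pytest.fixture(scope="session")
def small_monolayer():
    """3×3 single-frame monolayer: quick segmentation/morphometry target."""
    spec = SyntheticTissueSpec(grid_shape=(3, 3), n_frames=1, seed=7)
    return generate_monolayer(spec)


@pytest.fixture(scope="session")
def small_segmentation(small_monolayer):
    """Isotropic stack and its watershed labels for the 3×3 monolayer."""
    iso = rescale_isotropic(small_monolayer.stacks[0])
    return iso, segment_cells_3d(iso)


@pytest.fixture(scope="session")
def monolayer_5x5():
    """5×5 single-frame monolayer at the standard imaging conditions."""
    spec = SyntheticTissueSpec(grid_shape=(5, 5), n_frames=1, seed=1)
    return generate_monolayer(spec)


@pytest.fixture(scope="session")
def constricted_timelapse():
    """5×5 monolayer with the standard constriction program, 4 frames.

    Frame 0 precedes stimulation; by the last frame (t = 75 min with
    tau_on = 10 min) the apical reduction has plateaued.
    """
    spec = SyntheticTissueSpec(grid_shape=(5, 5), n_frames=4, frame_interval=25.0, seed=3)
    roi = centered_roi(spec)
    program = ConstrictionProgram(roi=roi)
    return generate_monolayer(spec, program), roi, program


def match_to_truth(label_volume, truth_frame, gt_labels):
    """Map watershed labels onto ground-truth labels by maximum overlap."""
    from optomorph.tracking import track_max_overlap

    nz = min(gt_labels.shape[0], label_volume.shape[0])
    mapping = track_max_overlap(gt_labels.labels[:nz], label_volume.labels[:nz])
    return {v: k for k, v in mapping.items() if v is not None}


def speckle_texture(shape, sigma=1.5, seed=0):
    """Blurred-noise texture with sharp enough autocorrelation for PIV."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)
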