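"""Per-cell and per-tissue shape measurements on labelled volumes.

Definitions follow the voxel conventions of the segmentation pipeline:

* volume — voxel count × voxel volume;
* apical/basal contact — cell voxels 6-adjacent to background in the
  apical (low z) / basal (high z) direction, with out-of-volume treated
  as background;
* contact area — contact voxels projected to the x-y plane, pixel count
  × pixel area;
* height — distance between the average apical contact plane and the
  average basal contact plane.  Contact positions are taken at the
  voxel *faces* touching the background, so a prism spanning ``n``
  voxels measures ``n × voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point

from .stack import ImageStack, LabelVolume


@dataclass
class CellRecord:
    """One cell's morphometry in one frame (µm units)."""

    label: int
    frame: int
    volume: float
    apical_area: float
    basal_area: float
    height: float
    centroid: tuple[float, float, float]

    @property
    def apical_basal_ratio(self) -> float:
        return self.apical_area / self.basal_area if self.basal_area > 0 else np.nan


def contact_maps(labels: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Boolean maps of apical- and basal-contact voxels.

    A voxel is in apical contact when the voxel directly above it
    (toward low z, the apical side) is background or outside the volume;
    basal contact is the mirror condition toward high z.
    """
    lab = labels.labels
    bg_above = np.ones_like(lab, dtype=bool)
    bg_above[1:] = lab[:-1] == 0
    bg_below = np.ones_like(lab, dtype=bool)
    bg_below[:-1] = lab[1:] == 0
    fg = lab > 0
    return fg & bg_above, fg & bg_below


def cell_volume(labels: LabelVolume, label_id: int) -> float:
    """Voxel-counting volume of one cell, in µm³."""
    n = int(np.count_nonzero(labels.labels == label_id))
    if n == 0:
        raise KeyError(f"label {label_id} not present in volume")
    return n * labels.voxel_volume


def cell_height(
    labels: LabelVolume,
    label_id: int,
    apical_contact: np.ndarray | None = None,
    basal_contact: np.ndarray | None = None,
) -> float:
    """Mean apical-contact to mean basal-contact distance, in µm.

    Uses the *average* z of the contact voxels on each side (not the
    extrema), so tilted surfaces are handled gracefully.  Returns NaN
    when the cell touches only one side (the caller should flag it).
    """
    if apical_contact is None or basal_contact is None:
        apical_contact, basal_contact = contact_maps(labels)
    sel = labels.labels == label_id
    if not np.any(sel):
        raise KeyError(f"label {label_id} not present in volume")
    za = np.nonzero(apical_contact & sel)[0]
    zb = np.nonzero(basal_contact & sel)[0]
    if za.size == 0 or zb.size == 0:
        return np.nan
    vz = labels.voxel_size[0]
    # +1: faces rather than centres — a prism of n voxels is n*vz tall
    return (zb.mean() - za.mean() + 1.0) * vz


def contact_area(
    labels: LabelVolume,
    label_id: int,
    side: str,
    apical_contact: np.ndarray | None = None,
    basal_contact: np.ndarray | None = None,
) -> float:
    """Apical or basal contact area of one cell, projected to x-y (µm²)."""
    if side not in ("apical", "basal"):
        raise ValueError("side must be 'apical' or 'basal'")
    if apical_contact is None or basal_contact is None:
        apical_contact, basal_contact = contact_maps(labels)
    contact = apical_contact if side == "apical" else basal_contact
    sel = (labels.labels == label_id) & contact
    if not np.any(labels.labels == label_id):
        raise KeyError(f"label {label_id} not present in volume")
    # project contact voxels to the x-y plane and count distinct pixels
    footprint = np.any(sel, axis=0)
    _, vy, vx = labels.voxel_size
    return float(np.count_nonzero(footprint)) * vy * vx


def apical_label_image(labels: LabelVolume) -> np.ndarray:
    """2D label image of each cell's apical contact footprint."""
    apical, _ = contact_maps(labels)
    lab = np.where(apical, labels.labels, 0)
    # first nonzero label down the column
    nz = (lab > 0).argmax(axis=0)
    out = np.take_along_axis(lab, nz[None], axis=0)[0]
    return out


def measure_cells(labels: LabelVolume, frame: int = 0) -> pd.DataFrame:
    """Full morphometry table for every cell in a label volume.

    Columns: label, frame, volume_um3, apical_area_um2, basal_area_um2,
    height_um, centroid x/y/z (µm), touches_both_sides.
    """
    lab = labels.labels
    ids = labels.ids()
    apical, basal = contact_maps(labels)
    vz, vy, vx = labels.voxel_size
    counts = np.bincount(lab.ravel(), minlength=int(lab.max()) + 1)
    cents = ndimage.center_of_mass(np.ones_like(lab, dtype=np.uint8), lab, ids) if ids.size else []
    rows = []
    for i, cen in zip(ids, cents):
        i = int(i)
        aa = contact_area(labels, i, "apical", apical, basal)
        ab = contact_area(labels, i, "basal", apical, basal)
        h = cell_height(labels, i, apical, basal)
        rows.append(
            {
                "label": i,
                "frame": frame,
                "volume_um3": counts[i] * labels.voxel_volume,
                "apical_area_um2": aa,
                "basal_area_um2": ab,
                "height_um": h,
                "centroid_x_um": (cen[2] + 0.5) * vx,
                "centroid_y_um": (cen[1] + 0.5) * vy,
                "centroid_z_um": (cen[0] + 0.5) * vz,
                "touches_both_sides": bool(np.isfinite(h)),
            }
        )
    return pd.DataFrame(rows)


def normalize_series(values, reference_index: int = 0) -> np.ndarray:
    """Divide a per-frame series by its value at the reference frame.

    The conventional reference is the last measurement before
    stimulation, which then maps to 1.
    """
    v = np.asarray(values, dtype=float)
    ref = v[reference_index]
    if ref == 0 or not np.isfinite(ref):
        raise ValueError("reference value is zero or non-finite; cannot normalize")
    return v / ref


def projected_area(image, pixel_size: float | None = None) -> float:
    """Area of the segmented object in a maximum-intensity z-projection (µm²).

    Accepts an :class:`~optomorph.stack.ImageStack` (projected, Otsu
    thresholded, holes filled), a 2D intensity image with ``pixel_size``,
    or a boolean mask with ``pixel_size``.
    """
    from skimage import filters

    if isinstance(image, ImageStack):
        proj = image.data.max(axis=0)
        px = image.voxel_size[2]
    else:
        proj = np.asarray(image)
        if pixel_size is None:
            raise ValueError("pixel_size required for plain arrays")
        px = pixel_size
    if proj.dtype == bool:
        mask = proj
    else:
        if proj.max() <= proj.min():
            return 0.0
        mask = proj > filters.threshold_otsu(proj)
    mask = ndimage.binary_fill_holes(mask)
    return float(np.count_nonzero(mask)) * px * px


def longest_diameter(mask: np.ndarray, pixel_size: float) -> float:
    """Maximum Feret diameter of a 2D mask, in µm.

    Computed as the largest pairwise distance between boundary-pixel
    centres on the convex hull, plus one pixel to account for pixel
    extent (a single pixel has diameter one pixel size).
    """
    mask = np.asarray(mask).astype(bool)
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    if pts.shape[0] == 1:
        return pixel_size
    try:
        hull = ConvexHull(pts, qhull_options="QJ")
        hp = pts[hull.vertices]
    except Exception:
        hp = pts
    d = np.linalg.norm(hp[:, None, :] - hp[None, :, :], axis=-1)
    return float(d.max()) * pixel_size + pixel_size


def thickness_measure(
    apical_boundary: np.ndarray,
    basal_boundary: np.ndarray,
    n_repeats: int = 3,
    seed: int = 0,
    margin: float = 0.1,
) -> float:
    """Epithelium thickness as the mean of repeated normal-distance probes.

    At ``n_repeats`` seeded random positions along the apical boundary, a
    probe is cast along the local normal and the distance to the basal
    boundary recorded; the repeats are averaged (formalising the common
    practice of measuring three times and averaging).

    Parameters
    ----------
    apical_boundary, basal_boundary:
        (N, 2) polylines in µm.
    margin:
        Fraction of the polyline length excluded at each end so probes
        stay away from the open boundary ends.

    Raises
    ------
    ValueError
        If the two boundaries cross, or a probe fails to hit the basal
        boundary.
    """
    ap = np.asarray(apical_boundary, dtype=float)
    ba = np.asarray(basal_boundary, dtype=float)
    if ap.ndim != 2 or ba.ndim != 2 or ap.shape[0] < 2 or ba.shape[0] < 2:
        raise ValueError("boundaries must be (N, 2) polylines with N >= 2")
    ap_ls = LineString(ap)
    ba_ls = LineString(ba)
    if ap_ls.crosses(ba_ls):
        raise ValueError("apical and basal boundaries cross")
    rng = np.random.default_rng(seed)
    span = np.hypot(*(ba.max(axis=0) - ba.min(axis=0))) + np.hypot(*(ap.max(axis=0) - ap.min(axis=0)))
    dists = []
    for _ in range(int(n_repeats)):
        s = rng.uniform(margin, 1.0 - margin) * ap_ls.length
        p = np.asarray(ap_ls.interpolate(s).coords[0])
        p2 = np.asarray(ap_ls.interpolate(min(s + 1e-3 * ap_ls.length, ap_ls.length)).coords[0])
        tang = p2 - p
        nrm = np.array([-tang[1], tang[0]])
        nrm = nrm / (np.linalg.norm(nrm) + 1e-12)
        best = np.inf
        for sign in (1.0, -1.0):
            ray = LineString([p, p + sign * nrm * 2 * span])
            hit = ray.intersection(ba_ls)
            if not hit.is_empty:
                best = min(best, Point(p).distance(hit))
        if not np.isfinite(best):
            raise ValueError("thickness probe did not intersect the basal boundary")
        dists.append(best)
    return float(np.mean(dists))


__all__ = [
    "CellRecord",
    "contact_maps",
    "cell_volume",
    "cell_height",
    "contact_area",
    "apical_label_image",
    "measure_cells",
    "normalize_series",
    "projected_area",
    "longest_diameter",
    "thickness_measure",
]
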