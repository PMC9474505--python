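"""Signed curvature of skeletons and organoid perimeters.

Local curvature at a point B of an ordered curve is the inverse radius
of the circumscribed circle through three equally spaced points
(A, B, C), computed from the triangle they form:

    kappa = 1/R = 4K / (|AB| |BC| |CA|),

where K is the triangle area.  The spacing between the three points is
a tunable number of (resampled, 1-px arc-length) curve points — small
(20 px) for colony skeletons, large (320 px) for organoid perimeters
where small features such as delaminating cells must be filtered out.

Sign convention: curvature is positive where the curve is concave
toward its declared apical side (for an upward-opening colony arc with
``apical_side="left"`` and counter-clockwise travel, the concave top is
positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import filters, morphology


@dataclass
class CurvatureProfile:
    """Per-point signed curvature along a curve.

    ``positions`` is the arc-length coordinate (µm) for open curves or
    the angular coordinate (degrees, 0° toward the stimulation centre)
    for closed perimeters.
    """

    positions: np.ndarray
    kappa: np.ndarray  # µm^-1, signed
    closed: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.kappa))

    @property
    def mean_abs(self) -> float:
        return float(np.mean(np.abs(self.kappa)))


def resample_arclength(points: np.ndarray, step: float, closed: bool = False) -> np.ndarray:
    """Resample a polyline to uniform arc-length steps.

    The triangle spacing parameter counts points of this uniform
    parametrisation, so "s points apart" means an arc-length separation
    of ``s * step``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate curve of zero length")
    n = max(int(round(total / step)), 2)
    si = np.linspace(0.0, total, n, endpoint=not closed)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y])


def circumradius_curvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Signed curvature of the circle through point triples (vectorised).

    Magnitude is ``4K / (|AB| |BC| |CA|)``; the sign is that of the
    cross product (B-A) x (C-B): positive where the triple turns
    counter-clockwise.  Collinear triples give exactly 0.
    """
    ab = b - a
    bc = c - b
    ca = a - c
    cross = ab[..., 0] * bc[..., 1] - ab[..., 1] * bc[..., 0]
    lab = np.linalg.norm(ab, axis=-1)
    lbc = np.linalg.norm(bc, axis=-1)
    lca = np.linalg.norm(ca, axis=-1)
    denom = lab * lbc * lca
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 1e-15, 2.0 * cross / np.maximum(denom, 1e-300), 0.0)
    return kappa


def local_curvature(
    points: np.ndarray,
    spacing: int = 20,
    pixel_size: float = 1.0,
    closed: bool = False,
    apical_side: str = "left",
) -> CurvatureProfile:
    """Signed local curvature along an ordered curve.

    Parameters
    ----------
    points:
        Ordered (N, 2) physical coordinates (µm).  The curve is
        resampled to 1-pixel arc-length steps internally.
    spacing:
        Triangle half-window in resampled points (pixels of arc length):
        the triple for centre point B is (B - spacing, B, B + spacing).
    pixel_size:
        Physical size of one resampling step, µm.
    closed:
        Wrap around (perimeters) instead of dropping the ends.
    apical_side:
        "left" or "right" of the direction of travel; curvature is
        positive where the centre of the osculating circle lies on that
        side (concave toward apical = positive).
    """
    if apical_side not in ("left", "right"):
        raise ValueError("apical_side must be 'left' or 'right'")
    pts = resample_arclength(points, pixel_size, closed=closed)
    n = pts.shape[0]
    if closed:
        if n < 2 * spacing + 1 or spacing >= n // 2:
            raise ValueError(
                f"perimeter of {n} points is too short for spacing {spacing}"
            )
        idx = np.arange(n)
        a = pts[(idx - spacing) % n]
        b = pts[idx]
        c = pts[(idx + spacing) % n]
        centers = idx
    else:
        if n < 2 * spacing + 1:
            raise ValueError(f"curve of {n} points is too short for spacing {spacing}")
        centers = np.arange(spacing, n - spacing)
        a = pts[centers - spacing]
        b = pts[centers]
        c = pts[centers + spacing]
    kappa = circumradius_curvature(a, b, c)
    if apical_side == "left":
        # CCW turn => centre on the left => concave toward the left side
        signed = kappa
    else:
        signed = -kappa
    positions = centers.astype(float) * pixel_size
    return CurvatureProfile(positions=positions, kappa=signed, closed=closed)


def mean_curvature(profile: CurvatureProfile) -> float:
    """Arithmetic mean of the signed local curvatures (µm⁻¹)."""
    return profile.mean


def extract_skeleton(section: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Ordered midline of a segmented band in a 2D section image.

    The image is thresholded (Otsu, unless already boolean), the
    dominant connected component skeletonised, and the skeleton's
    longest end-to-end path returned as an ordered (N, 2) array of (x, y)
    µm coordinates.

    Raises
    ------
    ValueError
        For blank images or fragmented masks without a dominant
        component.
    """
    img = np.asarray(section)
    if img.dtype == bool:
        mask = img
    else:
        if img.max() <= img.min():
            raise ValueError("blank image: nothing to skeletonise")
        mask = img > filters.threshold_otsu(img)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] > 0.5 * sizes[order[0]]:
        raise ValueError("fragmented mask: no dominant component")
    mask = lab == (order[0] + 1)
    skel = morphology.skeletonize(mask)
    coords = np.column_stack(np.nonzero(skel))  # (row, col)
    if coords.shape[0] < 2:
        raise ValueError("skeleton too short")
    g = nx.Graph()
    index = {tuple(c): i for i, c in enumerate(coords)}
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    if g.number_of_nodes() == 0:
        raise ValueError("skeleton graph is empty")
    # double-BFS heuristic for the longest path (exact on trees)
    start = next(iter(g.nodes))
    far1 = max(nx.single_source_dijkstra_path_length(g, start).items(), key=lambda kv: kv[1])[0]
    lengths, paths = nx.single_source_dijkstra(g, far1)
    far2 = max(lengths.items(), key=lambda kv: kv[1])[0]
    path = paths[far2]
    ordered = coords[path]
    # skeletons of a band grow hooks into its square-cut ends; trim each
    # end by the local band half-width so only the true midline remains
    edt = ndimage.distance_transform_edt(mask)
    half_width = int(np.ceil(np.median(edt[skel])))
    trim = min(2 * half_width, (len(ordered) - 2) // 2)
    if trim > 0:
        ordered = ordered[trim:-trim]
    # (row, col) -> (x, y) µm at pixel centres
    xy = np.column_stack([(ordered[:, 1] + 0.5), (ordered[:, 0] + 0.5)]) * pixel_size
    return xy


def perimeter_curvature(
    mask: np.ndarray,
    stim_center: np.ndarray,
    spacing: int = 320,
    pixel_size: float = 1.0,
    convex_positive: bool = True,
) -> CurvatureProfile:
    """Curvature around a closed organoid perimeter, indexed by angle.

    The perimeter of the (largest component of the) mask is traced,
    curvature evaluated with a wide point spacing to suppress small
    features (such as delaminating cells), and each evaluation point
    given an angular coordinate about the organoid centroid with 0°
    toward ``stim_center``.

    With ``convex_positive`` (default) a circular organoid of radius R
    yields κ = +1/R at all angles; set it False for tissues whose
    apical side faces the lumen, where concave-toward-the-lumen is the
    positive direction.
    """
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col)
    xy = np.column_stack([contour[:, 1] + 0.5, contour[:, 0] + 0.5]) * pixel_size
    pts = resample_arclength(xy, pixel_size, closed=True)
    n = pts.shape[0]
    if n <= 2 * spacing:
        raise ValueError(f"perimeter of {n} px is too short for spacing {spacing} px")
    # fix traversal direction so the shoelace orientation is positive
    area2 = np.dot(pts[:, 0], np.roll(pts[:, 1], -1)) - np.dot(pts[:, 1], np.roll(pts[:, 0], -1))
    if area2 < 0:
        pts = pts[::-1]
    idx = np.arange(n)
    kappa = circumradius_curvature(pts[(idx - spacing) % n], pts, pts[(idx + spacing) % n])
    if not convex_positive:
        kappa = -kappa
    centroid = pts.mean(axis=0)
    stim_center = np.asarray(stim_center, dtype=float)
    ref = np.arctan2(stim_center[1] - centroid[1], stim_center[0] - centroid[0])
    rel = pts - centroid
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]) - ref)
    ang = (ang + 180.0) % 360.0 - 180.0
    order = np.argsort(ang)
    return CurvatureProfile(positions=ang[order], kappa=kappa[order], closed=True)


def curvature_change(before: CurvatureProfile, after: CurvatureProfile):
    """Absolute and relative change in mean curvature (and per point).

    Returns a dict with ``delta_mean``, ``relative_mean`` (NaN-flagged
    when the reference mean is 0) and, when the profiles are congruent,
    per-point ``delta``.
    """
    out = {
        "mean_before": before.mean,
        "mean_after": after.mean,
        "delta_mean": after.mean - before.mean,
    }
    out["relative_mean"] = (
        (after.mean - before.mean) / before.mean if before.mean != 0 else np.nan
    )
    if before.kappa.shape == after.kappa.shape:
        out["delta"] = after.kappa - before.kappa
    return out


__all__ = [
    "CurvatureProfile",
    "resample_arclength",
    "circumradius_curvature",
    "local_curvature",
    "mean_curvature",
    "extract_skeleton",
    "perimeter_curvature",
    "curvature_change",
]
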