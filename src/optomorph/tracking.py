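"""Frame-to-frame cell tracking, quality control and stimulation/layer classes.

Cells are linked across frames by maximum voxel overlap of their labels.
Quality control discards tracks that miss any frame and tracks whose
volume changes by more than 30% between consecutive frames (the signature
of mis-segmentation, division or apoptosis).  Cells are classified as
stimulated either by any apical contact with the illumination rectangle
("contact" mode) or by holding the majority (>50%) of their apical area
inside it ("majority" mode); the remaining cells are organised into
concentric neighbour layers by graph distance from the stimulated set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .stack import LabelVolume

QC_PASS = "pass"
QC_MISSING = "missing_frame"
QC_VOLUME_JUMP = "volume_jump"

#: maximum tolerated consecutive-frame fractional volume change
VOLUME_JUMP_THRESHOLD = 0.30


@dataclass
class StimulationROI:
    """Rectangular illumination region in physical coordinates.

    Coordinates are µm with the image origin at the top-left corner,
    x to the right and y down.  ``t_start``/``t_end`` delimit the
    stimulation time window (same units as the frame times).
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    t_start: float = 0.0
    t_end: float = np.inf

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("ROI must have positive x and y extents")

    @property
    def center(self) -> np.ndarray:
        return np.array([(self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0])

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-rectangle test for an (N, 2) array of (x, y) µm."""
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.x_min)
            & (p[:, 0] <= self.x_max)
            & (p[:, 1] >= self.y_min)
            & (p[:, 1] <= self.y_max)
        )

    def distance_outside(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each (x, y) point to the rectangle (0 inside)."""
        p = np.atleast_2d(points)
        dx = np.maximum(np.maximum(self.x_min - p[:, 0], p[:, 0] - self.x_max), 0.0)
        dy = np.maximum(np.maximum(self.y_min - p[:, 1], p[:, 1] - self.y_max), 0.0)
        return np.hypot(dx, dy)

    def active(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass
class CellTrack:
    """A time-linked cell: per-frame label ids and its QC verdict."""

    track_id: int
    labels_by_frame: dict[int, int]
    qc_status: str = QC_PASS
    cls: str | None = None  # "stimulated", "layer1", ...

    def label_at(self, frame: int) -> int | None:
        return self.labels_by_frame.get(frame)


def track_max_overlap(labels_t: LabelVolume | np.ndarray, labels_next: LabelVolume | np.ndarray):
    """Map each label at t to the label at t+1 with maximum voxel overlap.

    Ties are broken by centroid distance, then by the smaller candidate
    label id, so the mapping is deterministic.  The assignment is greedy
    one-to-one in descending overlap; labels with zero overlap map to
    ``None``.

    Returns
    -------
    dict[int, int | None]
        Mapping ``label_at_t -> label_at_t+1`` (``None`` if unmatched).
    """
    a = labels_t.labels if isinstance(labels_t, LabelVolume) else np.asarray(labels_t)
    b = labels_next.labels if isinstance(labels_next, LabelVolume) else np.asarray(labels_next)
    if a.shape != b.shape:
        raise ValueError(f"label volumes differ in shape: {a.shape} vs {b.shape}")

    ids_a = np.unique(a)
    ids_a = ids_a[ids_a > 0]
    ids_b = np.unique(b)
    ids_b = ids_b[ids_b > 0]
    mapping: dict[int, int | None] = {int(i): None for i in ids_a}
    if ids_a.size == 0 or ids_b.size == 0:
        return mapping

    # joint histogram of (label_t, label_t+1) pairs over foreground voxels
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount((a.ravel().astype(np.int64) * nb + b.ravel()), minlength=na * nb)
    joint = joint.reshape(na, nb)
    joint[0, :] = 0
    joint[:, 0] = 0

    cent_a = _centroids(a)
    cent_b = _centroids(b)

    candidates = []
    rows, cols = np.nonzero(joint)
    for i, j in zip(rows, cols):
        dist = float(np.linalg.norm(cent_a[i] - cent_b[j]))
        candidates.append((-int(joint[i, j]), dist, int(j), int(i)))
    # descending overlap, then nearest centroid, then lowest target id
    candidates.sort()

    used_b: set[int] = set()
    assigned_a: set[int] = set()
    for neg_ov, _dist, j, i in candidates:
        if i in assigned_a or j in used_b:
            continue
        mapping[i] = j
        assigned_a.add(i)
        used_b.add(j)
    return mapping


def _centroids(labels: np.ndarray) -> dict[int, np.ndarray]:
    from scipy import ndimage

    ids = np.unique(labels)
    ids = ids[ids > 0]
    out: dict[int, np.ndarray] = {}
    if ids.size:
        cents = ndimage.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
        for i, c in zip(ids, cents):
            out[int(i)] = np.asarray(c, dtype=float)
    return out


def build_tracks(label_series: list[LabelVolume]) -> list[CellTrack]:
    """Chain :func:`track_max_overlap` across a label series into tracks.

    Every label in frame 0 seeds a track; labels appearing later start
    new tracks (which then necessarily fail the all-frames QC rule).
    """
    n = len(label_series)
    tracks: list[CellTrack] = []
    open_by_label: dict[int, CellTrack] = {}
    next_id = 1
    for lab in (label_series[0].ids() if n else []):
        tr = CellTrack(track_id=next_id, labels_by_frame={0: int(lab)})
        tracks.append(tr)
        open_by_label[int(lab)] = tr
        next_id += 1
    for f in range(n - 1):
        mapping = track_max_overlap(label_series[f], label_series[f + 1])
        new_open: dict[int, CellTrack] = {}
        for lab, tr in open_by_label.items():
            nxt = mapping.get(lab)
            if nxt is not None:
                tr.labels_by_frame[f + 1] = int(nxt)
                new_open[int(nxt)] = tr
        # labels in f+1 not claimed by any track start fresh ones
        for lab in label_series[f + 1].ids():
            if int(lab) not in new_open:
                tr = CellTrack(track_id=next_id, labels_by_frame={f + 1: int(lab)})
                tracks.append(tr)
                new_open[int(lab)] = tr
                next_id += 1
        open_by_label = new_open
    return tracks


def qc_filter(tracks: list[CellTrack], volumes: dict[tuple[int, int], float], n_frames: int):
    """Apply the two quality-control rules and split tracks by verdict.

    A track is rejected iff (a) it lacks a cell in any of the
    ``n_frames`` frames, or (b) any consecutive-frame volume ratio falls
    outside ``(0.7, 1.3)`` — i.e. a sudden volume change strictly greater
    than 30%.

    Parameters
    ----------
    volumes:
        ``(frame, label) -> volume`` lookup (µm³).

    Returns
    -------
    (passing, rejected):
        Lists of tracks; rejected tracks carry ``qc_status`` of
        ``"missing_frame"`` or ``"volume_jump"``.
    """
    passing: list[CellTrack] = []
    rejected: list[CellTrack] = []
    for tr in tracks:
        if any(f not in tr.labels_by_frame for f in range(n_frames)):
            tr.qc_status = QC_MISSING
            rejected.append(tr)
            continue
        jump = False
        for f in range(n_frames - 1):
            v0 = volumes[(f, tr.labels_by_frame[f])]
            v1 = volumes[(f + 1, tr.labels_by_frame[f + 1])]
            if v0 <= 0 or abs(v1 / v0 - 1.0) > VOLUME_JUMP_THRESHOLD:
                jump = True
                break
        if jump:
            tr.qc_status = QC_VOLUME_JUMP
            rejected.append(tr)
        else:
            tr.qc_status = QC_PASS
            passing.append(tr)
    return passing, rejected


def classify_stimulated(
    apical_labels: np.ndarray,
    pixel_size: float,
    roi: StimulationROI,
    mode: str = "contact",
) -> set[int]:
    """Identify stimulated cells from the apical label image at t0.

    ``contact`` mode marks any cell with at least one apical pixel inside
    the ROI; ``majority`` mode requires strictly more than 50% of the
    cell's apical pixels inside (the stricter rule used for the layer
    analysis).
    """
    if mode not in ("contact", "majority"):
        raise ValueError(f"unknown classification mode {mode!r}")
    lab = np.asarray(apical_labels)
    ys, xs = np.nonzero(lab)
    if ys.size == 0:
        return set()
    # pixel centres in µm, origin top-left, x right / y down
    px = (xs + 0.5) * pixel_size
    py = (ys + 0.5) * pixel_size
    inside = roi.contains(np.column_stack([px, py]))
    vals = lab[ys, xs]
    ids = np.unique(vals)
    total = np.bincount(vals, minlength=ids.max() + 1)
    hits = np.bincount(vals[inside], minlength=ids.max() + 1)
    out: set[int] = set()
    for i in ids:
        if mode == "contact":
            if hits[i] > 0:
                out.add(int(i))
        else:
            if hits[i] > 0.5 * total[i]:
                out.add(int(i))
    return out


def build_adjacency(apical_labels: np.ndarray) -> nx.Graph:
    """Neighbour graph of labels sharing a 4-adjacent boundary.

    Works on the apical label image (the layer definition concerns
    apical-area effects); also accepts a 3D volume, in which case
    adjacency is evaluated across all three axes.
    """
    lab = np.asarray(apical_labels)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.unique(lab) if i > 0)
    pairs: set[tuple[int, int]] = set()
    for axis in range(lab.ndim):
        a = np.moveaxis(lab, axis, 0)[:-1]
        b = np.moveaxis(lab, axis, 0)[1:]
        sel = (a != b) & (a > 0) & (b > 0)
        if np.any(sel):
            pa = a[sel].ravel()
            pb = b[sel].ravel()
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    g.add_edges_from(pairs)
    return g


def assign_layers(graph: nx.Graph, stimulated: set[int], max_layer: int = 3) -> dict[int, str]:
    """Breadth-first layer assignment from the stimulated set.

    Layer 1 contains cells directly in contact with a stimulated cell,
    layer 2 their unvisited neighbours, and so on.  Cells farther than
    ``max_layer`` (or disconnected) are labelled ``"unclassified"``.
    """
    assignment: dict[int, str] = {}
    seeds = [s for s in stimulated if s in graph]
    dist: dict[int, int] = {}
    if seeds:
        dist = nx.multi_source_dijkstra_path_length(graph, set(seeds), weight=None)
    for node in graph.nodes:
        if node in stimulated:
            assignment[node] = "stimulated"
        elif node in dist and dist[node] <= max_layer:
            assignment[node] = f"layer{dist[node]}"
        else:
            assignment[node] = "unclassified"
    return assignment


__all__ = [
    "StimulationROI",
    "CellTrack",
    "track_max_overlap",
    "build_tracks",
    "qc_filter",
    "classify_stimulated",
    "build_adjacency",
    "assign_layers",
    "QC_PASS",
    "QC_MISSING",
    "QC_VOLUME_JUMP",
    "VOLUME_JUMP_THRESHOLD",
]
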