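"""Displacement fields between frames and their zonal radial statistics.

PIV here is the classic single-pass scheme: the frame pair is tiled
into square interrogation windows (default 64 px), each window pair is
cross-correlated via FFT (with unbiased overlap normalisation), and
the correlation peak — refined to sub-pixel precision with a 3-point
Gaussian fit per axis — gives the window's displacement.  Vectors whose correlation peak is not clearly
dominant (peak-to-second-peak ratio below a threshold) are flagged
invalid and excluded from averages.

Downstream, displacement fields are reduced the way tissue-scale
optogenetics experiments are analysed: each vector is projected onto
the unit vector pointing at the stimulation centre (positive = inward),
grid points are classified as stimulated / adjacent / outer relative to
the illumination rectangle, and per-zone mean radial components are
accumulated over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .tracking import StimulationROI

ZONES = ("stimulated", "adjacent", "outer")


@dataclass
class VectorField:
    """Gridded displacement vectors for one frame interval.

    ``x``/``y`` are the 1D window-centre coordinates (µm); ``u``/``v``
    the displacement components (µm per frame interval) on the
    ``(len(y), len(x))`` grid; ``valid`` flags trustworthy vectors.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    frame_interval: float = 1.0
    valid: np.ndarray | None = None
    peak_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != (self.y.size, self.x.size) or self.v.shape != self.u.shape:
            raise ValueError("u/v must have shape (len(y), len(x))")
        if self.valid is None:
            self.valid = np.ones_like(self.u, dtype=bool)

    @property
    def positions(self) -> np.ndarray:
        """(ny, nx, 2) array of (x, y) µm grid positions."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.stack([xx, yy], axis=-1)


def _subpixel_offset(cm: float, cc: float, cp: float) -> float:
    """Sub-pixel peak offset from three correlation samples."""
    if cm > 0 and cc > 0 and cp > 0:
        lm, lc, lp = np.log(cm), np.log(cc), np.log(cp)
        den = lm - 2 * lc + lp
        if den < 0:
            return float(0.5 * (lm - lp) / den)
    den = cm - 2 * cc + cp
    if den < 0:
        return float(0.5 * (cm - cp) / den)
    return 0.0


def piv_single_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 64,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    min_peak_ratio: float = 1.5,
) -> VectorField:
    """Single-pass cross-correlation PIV between two frames.

    Windows tile the frames without overlap; the maximum detectable
    displacement is ``window // 2`` pixels.  Displacements are returned
    in µm per frame interval, positive u to the right (+x) and positive
    v downward (+y), matching the image coordinate convention.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be two 2D arrays of identical shape")
    if window > min(a.shape):
        raise ValueError(f"window {window} px exceeds frame size {a.shape}")
    ny = a.shape[0] // window
    nx = a.shape[1] // window
    half = window // 2
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    ratio = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            wa = a[iy * window : (iy + 1) * window, ix * window : (ix + 1) * window]
            wb = b[iy * window : (iy + 1) * window, ix * window : (ix + 1) * window]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            if wa.std() < 1e-12 or wb.std() < 1e-12:
                continue
            corr = signal.fftconvolve(wb, wa[::-1, ::-1], mode="full")
            c0 = window - 1  # zero-shift index
            sub = corr[c0 - half : c0 + half + 1, c0 - half : c0 + half + 1]
            # unbiased normalisation: finite windows overlap less at larger
            # shifts, which otherwise pulls the peak toward zero
            shifts = np.abs(np.arange(-half, half + 1, dtype=float))
            overlap = np.outer(window - shifts, window - shifts) / window**2
            # cap the correction so spurious far-shift noise peaks are not
            # amplified into false detections
            sub = sub / np.maximum(overlap, 0.5)
            peak = np.unravel_index(np.argmax(sub), sub.shape)
            dy = peak[0] - half
            dx = peak[1] - half
            # sub-pixel: 3-point Gaussian fit per axis (exact for the
            # Gaussian-shaped peaks of smooth textures), parabolic
            # fallback when a neighbour correlation is non-positive
            fy, fx = float(dy), float(dx)
            py, px = peak
            if 0 < py < sub.shape[0] - 1:
                fy += _subpixel_offset(sub[py - 1, px], sub[py, px], sub[py + 1, px])
            if 0 < px < sub.shape[1] - 1:
                fx += _subpixel_offset(sub[py, px - 1], sub[py, px], sub[py, px + 1])
            # peak dominance: best correlation outside an exclusion zone
            # wide enough to step off the main peak's shoulder
            excl = max(2, window // 16)
            masked = sub.copy()
            masked[max(0, py - excl) : py + excl + 1, max(0, px - excl) : px + excl + 1] = -np.inf
            second = masked.max()
            pr = sub[py, px] / second if second > 0 else np.inf
            ratio[iy, ix] = pr
            valid[iy, ix] = pr >= min_peak_ratio
            u[iy, ix] = fx * pixel_size
            v[iy, ix] = fy * pixel_size
    x = (np.arange(nx) + 0.5) * window * pixel_size
    y = (np.arange(ny) + 0.5) * window * pixel_size
    return VectorField(x=x, y=y, u=u, v=v, frame_interval=frame_interval,
                       valid=valid, peak_ratio=ratio)


def radial_component(fld: VectorField, center: np.ndarray) -> np.ndarray:
    """Projection of each vector onto the inward unit vector (µm).

    Positive values are displacements toward ``center``; a vector sitting
    exactly at the centre contributes 0 by convention.
    """
    center = np.asarray(center, dtype=float)
    pos = fld.positions
    rel = center[None, None, :] - pos
    d = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[..., None] > 1e-12, rel / np.maximum(d, 1e-12)[..., None], 0.0)
    return fld.u * unit[..., 0] + fld.v * unit[..., 1]


def tangential_component(fld: VectorField, center: np.ndarray) -> np.ndarray:
    """Component perpendicular to the inward direction (signed, µm)."""
    center = np.asarray(center, dtype=float)
    pos = fld.positions
    rel = center[None, None, :] - pos
    d = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[..., None] > 1e-12, rel / np.maximum(d, 1e-12)[..., None], 0.0)
    # left-perpendicular of the inward unit vector
    return fld.u * (-unit[..., 1]) + fld.v * unit[..., 0]


def classify_zones(fld: VectorField, roi: StimulationROI, adjacent_width: float) -> np.ndarray:
    """Zone label per grid point: stimulated / adjacent / outer.

    Stimulated points lie inside the ROI rectangle; adjacent points lie
    outside it but within ``adjacent_width`` µm of its boundary; the
    rest are outer.
    """
    if adjacent_width <= 0:
        raise ValueError("adjacent_width must be positive")
    pos = fld.positions.reshape(-1, 2)
    inside = roi.contains(pos)
    dist = roi.distance_outside(pos)
    zones = np.where(inside, "stimulated", np.where(dist <= adjacent_width, "adjacent", "outer"))
    return zones.reshape(fld.u.shape)


def zonal_series(
    fields: list[VectorField],
    zones: np.ndarray,
    center: np.ndarray,
) -> pd.DataFrame:
    """Per-zone mean radial component per frame, with its running sum.

    Only valid vectors enter the means.  Returns a tidy frame with
    columns ``frame, zone, mean_radial_um, cumulative_um``.
    """
    rows = []
    for f, fld in enumerate(fields):
        if zones.shape != fld.u.shape:
            raise ValueError("zone map does not match the field grid")
        rad = radial_component(fld, center)
        for z in ZONES:
            sel = (zones == z) & fld.valid
            mean = float(rad[sel].mean()) if np.any(sel) else np.nan
            rows.append({"frame": f, "zone": z, "mean_radial_um": mean})
    df = pd.DataFrame(rows)
    df["cumulative_um"] = df.groupby("zone")["mean_radial_um"].cumsum()
    return df


def distance_profile(
    fields: list[VectorField],
    roi: StimulationROI,
    center: np.ndarray | None = None,
    bin_width: float = 5.0,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """Cumulative radial displacement vs distance from the ROI boundary.

    Grid points outside the ROI are binned by their Euclidean distance
    to the rectangle (``[0, bin_width)``, ``[bin_width, 2*bin_width)``,
    ...); per bin, the radial components of valid vectors are averaged
    per frame and summed over frames.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if center is None:
        center = roi.center
    fld0 = fields[0]
    pos = fld0.positions.reshape(-1, 2)
    inside = roi.contains(pos)
    dist = roi.distance_outside(pos)
    if max_distance is None:
        max_distance = float(dist.max()) + bin_width
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel_flat = (~inside) & (which == b)
        if not np.any(sel_flat):
            continue
        sel = sel_flat.reshape(fld0.u.shape)
        cum = 0.0
        for fld in fields:
            rad = radial_component(fld, center)
            ok = sel & fld.valid
            if np.any(ok):
                cum += float(rad[ok].mean())
        rows.append(
            {
                "distance_lo_um": edges[b],
                "distance_hi_um": edges[b + 1],
                "n_points": int(sel_flat.sum()),
                "cumulative_radial_um": cum,
            }
        )
    return pd.DataFrame(rows)


def average_experiments(items: list):
    """Pointwise arithmetic mean of congruent zonal tables or field series.

    Accepts a list of :func:`zonal_series` DataFrames (same frames and
    zones) or a list of per-experiment ``list[VectorField]`` (same grids
    and frame counts).
    """
    if len(items) == 0:
        raise ValueError("nothing to average")
    first = items[0]
    if isinstance(first, pd.DataFrame):
        for df in items[1:]:
            if not (df[["frame", "zone"]].values == first[["frame", "zone"]].values).all():
                raise ValueError("zonal tables are not congruent")
        out = first.copy()
        for col in ("mean_radial_um", "cumulative_um"):
            out[col] = np.mean([df[col].to_numpy() for df in items], axis=0)
        return out
    # list of VectorField series
    n_frames = len(first)
    for series in items[1:]:
        if len(series) != n_frames:
            raise ValueError("experiments have mismatched frame counts")
    out_series = []
    for f in range(n_frames):
        ref = first[f]
        for series in items[1:]:
            fld = series[f]
            if not (np.allclose(fld.x, ref.x) and np.allclose(fld.y, ref.y)):
                raise ValueError("experiments have mismatched grids")
        u = np.mean([s[f].u for s in items], axis=0)
        v = np.mean([s[f].v for s in items], axis=0)
        valid = np.logical_and.reduce([s[f].valid for s in items])
        out_series.append(
            VectorField(x=ref.x, y=ref.y, u=u, v=v, frame_interval=ref.frame_interval,
                        valid=valid)
        )
    return out_series


__all__ = [
    "VectorField",
    "ZONES",
    "piv_single_pass",
    "radial_component",
    "tangential_component",
    "classify_zones",
    "zonal_series",
    "distance_profile",
    "average_experiments",
]
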