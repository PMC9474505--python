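"""Optogenetic translocation ratios and binding/unbinding kinetics.

Translocation of the cytosolic half of a light-induced dimer to apical
junctions is quantified as the ratio of junctional to cytoplasmic
fluorescence.  Two estimators are provided:

* :func:`roi_ratio_series` — small square ROIs (default 5×5 px) placed
  on junctions and in cytoplasm; each junction ROI is divided by its
  *nearest* cytoplasm ROI and the pairs averaged per time point,
  reproducing the three-ROI manual protocol.
* :func:`mask_ratio` — a junction mask segmented from a reference
  channel; the target channel's mean inside the mask divided by its
  mean over the remaining pixels.

Kinetics: the on/off ratio time course is fitted with single
exponentials (rise during stimulation, decay after), and the unbinding
half-life reported as ``tau_off * ln 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import filters


@dataclass
class KineticsFit:
    """Single-exponential on/off fit of a translocation ratio series."""

    baseline: float
    amplitude: float
    tau_on: float
    tau_off: float
    residual: float
    identifiable: bool = True

    @property
    def half_life_off(self) -> float:
        return self.tau_off * np.log(2.0)

    @property
    def fold_change(self) -> float:
        return (self.baseline + self.amplitude) / self.baseline if self.baseline else np.nan


def _roi_mean(frame: np.ndarray, center: tuple[float, float], roi_size: int) -> float:
    """Mean over a roi_size×roi_size pixel box centred on (x, y)."""
    h = roi_size // 2
    x, y = int(round(center[0])), int(round(center[1]))
    if (
        x - h < 0
        or y - h < 0
        or x + h + 1 > frame.shape[1]
        or y + h + 1 > frame.shape[0]
    ):
        raise ValueError(f"ROI at {center} falls outside the frame {frame.shape}")
    return float(frame[y - h : y + h + 1, x - h : x + h + 1].mean())


def roi_ratio_series(
    frames: np.ndarray,
    junction_rois: list[tuple[float, float]],
    cytoplasm_rois: list[tuple[float, float]],
    times: np.ndarray | None = None,
    roi_size: int = 5,
) -> pd.DataFrame:
    """Junction/cytoplasm intensity ratio per time point.

    Each junction ROI is divided by the cytoplasm ROI nearest to it
    (Euclidean centre distance); the ratios of all junction ROIs are
    then averaged.  ROI centres are (x, y) pixel coordinates.

    Returns a frame with columns ``time`` and ``ratio``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if not junction_rois or not cytoplasm_rois:
        raise ValueError("need at least one junction and one cytoplasm ROI")
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    jc = np.asarray(junction_rois, dtype=float)
    cc = np.asarray(cytoplasm_rois, dtype=float)
    nearest = np.argmin(np.linalg.norm(jc[:, None, :] - cc[None, :, :], axis=-1), axis=1)
    rows = []
    for t, frame in zip(times, frames):
        ratios = []
        for j, (jx, jy) in enumerate(jc):
            jm = _roi_mean(frame, (jx, jy), roi_size)
            cm = _roi_mean(frame, tuple(cc[nearest[j]]), roi_size)
            if cm == 0:
                raise ValueError("cytoplasm ROI mean is zero; ratio undefined")
            ratios.append(jm / cm)
        rows.append({"time": float(t), "ratio": float(np.mean(ratios))})
    return pd.DataFrame(rows)


def mask_ratio(
    reference: np.ndarray,
    target: np.ndarray,
    smooth_sigma: float = 1.0,
    threshold_percentile: float | None = None,
) -> float:
    """Junctional/cytoplasmic mean-intensity ratio of the target channel.

    The junction mask is segmented from the reference channel (Otsu on
    a smoothed copy, or a percentile override); the cytoplasm is the
    complement of the mask.  Channels must be aligned and same-shaped.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must have the same shape")
    smooth = ndimage.gaussian_filter(ref, smooth_sigma)
    if threshold_percentile is not None:
        thr = np.percentile(smooth, threshold_percentile)
    else:
        if smooth.max() <= smooth.min():
            raise ValueError("flat reference channel; cannot segment junctions")
        thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    if not mask.any() or mask.all():
        raise ValueError("junction mask is empty or covers the whole image")
    return float(tgt[mask].mean() / tgt[~mask].mean())


def fit_kinetics(
    times: np.ndarray,
    ratios: np.ndarray,
    stim_window: tuple[float, float],
    min_amplitude: float = 1e-3,
) -> KineticsFit:
    """Least-squares single-exponential on/off fit of a ratio series.

    The model is the saturating rise
    ``baseline + A (1 - exp(-(t - t_on)/tau_on))`` inside the
    stimulation window and the matching decay with ``tau_off`` after
    it; the series must cover both transitions.

    A flat series (amplitude below ``min_amplitude``) is returned with
    ``identifiable=False`` and NaN time constants rather than an error.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if t.size != y.size or t.size < 6:
        raise ValueError("need matched time/ratio arrays with at least 6 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timebase must be strictly increasing")
    t_on, t_off = stim_window
    if not ((t < t_on).any() or (t[0] <= t_on)) or not (t > t_off).any():
        raise ValueError("series must cover the end of stimulation")

    def model(tt, base, amp, tau_on, tau_off):
        out = np.full_like(tt, base)
        during = (tt >= t_on) & (tt <= t_off)
        out[during] = base + amp * (1 - np.exp(-(tt[during] - t_on) / tau_on))
        amp_end = amp * (1 - np.exp(-(t_off - t_on) / tau_on))
        after = tt > t_off
        out[after] = base + amp_end * np.exp(-(tt[after] - t_off) / tau_off)
        return out

    base0 = float(np.median(y[t < t_on])) if (t < t_on).any() else float(y[0])
    amp0 = float(np.max(y) - base0)
    if amp0 <= min_amplitude:
        return KineticsFit(
            baseline=base0, amplitude=max(amp0, 0.0), tau_on=np.nan, tau_off=np.nan,
            residual=float(np.sqrt(np.mean((y - base0) ** 2))), identifiable=False,
        )
    span = t_off - t_on
    p0 = (base0, amp0, max(span / 5, 1e-3), max(span / 5, 1e-3))
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([0, 0, 1e-6, 1e-6], [np.inf, np.inf, 100 * span, 100 * span]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"kinetics fit did not converge: {exc}") from exc
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return KineticsFit(
        baseline=float(popt[0]), amplitude=float(popt[1]),
        tau_on=float(popt[2]), tau_off=float(popt[3]), residual=resid,
    )


def half_life_from_crossing(
    times: np.ndarray, ratios: np.ndarray, t_off: float
) -> float:
    """Model-free unbinding half-life: time to cross halfway back to baseline.

    Reported alongside the exponential fit; linear interpolation between
    samples.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ratios, dtype=float)
    after = t >= t_off
    ta, ya = t[after], y[after]
    if ta.size < 2:
        raise ValueError("no samples after the end of stimulation")
    base = float(y[t < t_off][:max(1, int((t < t_off).sum() // 4))].mean())
    target = base + (ya[0] - base) / 2.0
    below = np.nonzero(ya <= target)[0]
    if below.size == 0:
        raise ValueError("series never decays to half amplitude")
    i = below[0]
    if i == 0:
        return 0.0
    frac = (ya[i - 1] - target) / (ya[i - 1] - ya[i])
    return float(ta[i - 1] + frac * (ta[i] - ta[i - 1]) - t_off)


__all__ = [
    "KineticsFit",
    "roi_ratio_series",
    "mask_ratio",
    "fit_kinetics",
    "half_life_from_crossing",
]
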