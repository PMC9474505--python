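"""Linear-taper geometric cell model.

A columnar cell is modelled with a cross-sectional area that changes
linearly from the basal to the apical surface,

    A(z) = A_basal + z (A_apical - A_basal),   z in [0, 1],

so its volume is V = h (A_apical + A_basal) / 2.  Given any three of
(V, A_apical, A_basal, h) the fourth follows algebraically — in
particular h = 2V / (A_apical + A_basal), which predicts the cell
elongation that accompanies apical constriction at conserved volume and
fixed basal area.

A quadratic "frustum" variant (side length linear in z, area quadratic,
V = h (Aa + Ab + sqrt(Aa*Ab)) / 3) is available behind ``variant`` for
sensitivity analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

_VARIANTS = ("linear", "frustum")


def area_profile(
    volume: float, a_apical: float, a_basal: float, z: float | np.ndarray
) -> float | np.ndarray:
    """Cross-sectional area at normalised height z (0 = basal, 1 = apical).

    The geometry must be consistent (positive areas); ``volume`` is
    accepted for interface symmetry but the profile depends only on the
    endpoint areas.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("z must lie in [0, 1]")
    if a_apical < 0 or a_basal < 0:
        raise ValueError("areas must be non-negative")
    out = a_basal + z * (a_apical - a_basal)
    return float(out) if out.ndim == 0 else out


def predict_height(volume: float, a_apical: float, a_basal: float, variant: str = "linear") -> float:
    """h = 2V / (A_apical + A_basal) (linear-taper model)."""
    _check_variant(variant)
    denom = a_apical + a_basal
    if denom <= 0:
        raise ValueError("A_apical + A_basal must be positive")
    if variant == "linear":
        return 2.0 * volume / denom
    return 3.0 * volume / (a_apical + a_basal + math.sqrt(a_apical * a_basal))


def predict_missing(
    volume: float | None = None,
    a_apical: float | None = None,
    a_basal: float | None = None,
    height: float | None = None,
    variant: str = "linear",
) -> float:
    """Solve V = h (Aa + Ab) / 2 for whichever quantity is ``None``.

    Exactly three of the four arguments must be given.  Raises
    ``ValueError`` with a diagnostic if the implied solution is negative
    (inconsistent measurements).
    """
    _check_variant(variant)
    known = [volume, a_apical, a_basal, height]
    if sum(k is None for k in known) != 1:
        raise ValueError("exactly one of (volume, a_apical, a_basal, height) must be None")
    if volume is None:
        if variant == "linear":
            return height * (a_apical + a_basal) / 2.0
        return height * (a_apical + a_basal + math.sqrt(a_apical * a_basal)) / 3.0
    if height is None:
        return predict_height(volume, a_apical, a_basal, variant)
    if variant != "linear":
        raise ValueError("area inversion is only defined for the linear variant")
    if height <= 0:
        raise ValueError("height must be positive to invert for an area")
    if a_apical is None:
        out = 2.0 * volume / height - a_basal
        which = "apical"
    else:
        out = 2.0 * volume / height - a_apical
        which = "basal"
    if out < 0:
        raise ValueError(
            f"implied {which} area is negative ({out:.4g} µm²): "
            "inputs are inconsistent with the linear-taper model"
        )
    return out


def predict_series(
    df: pd.DataFrame,
    predict: str = "height_um",
    volume: str = "volume_um3",
    a_apical: str = "apical_area_um2",
    a_basal: str = "basal_area_um2",
    height: str = "height_um",
    variant: str = "linear",
) -> pd.Series:
    """Per-frame model prediction of one quantity from the other three.

    ``df`` holds one row per frame (typically class-averaged
    measurements); the returned series is aligned to ``df.index``.
    """
    cols = {"volume_um3": volume, "apical_area_um2": a_apical,
            "basal_area_um2": a_basal, "height_um": height}
    if predict not in cols:
        raise ValueError(f"unknown quantity {predict!r}")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(volume=None, a_apical=None, a_basal=None, height=None)
        mapping = {"volume_um3": "volume", "apical_area_um2": "a_apical",
                   "basal_area_um2": "a_basal", "height_um": "height"}
        for key, col in cols.items():
            if key != predict:
                kwargs[mapping[key]] = float(row[col])
        out.append(predict_missing(variant=variant, **kwargs))
    return pd.Series(out, index=df.index, name=f"predicted_{predict}")


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")


__all__ = ["area_profile", "predict_height", "predict_missing", "predict_series"]
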