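#!/usr/bin/env python
"""Normalized constriction read-outs and the linear-taper height model.

From the measured morphometry table: per-class (stimulated / layers)
apical-area series normalized to the last pre-stimulation frame, the
measured height increase of the stimulated cells, and the model-predicted
height h = 2V/(Aa+Ab) from class-averaged measurements, reported with
its constant voxelisation offset.  Writes results/monolayer/
normalized_series.csv and height_model.csv.
"""

from pathlib import Path

import pandas as pd

from optomorph.morphometry import normalize_series
from optomorph.shape_model import predict_series

OUT = Path(__file__).resolve().parent.parent / "results" / "monolayer"


def main() -> None:
    df = pd.read_csv(OUT / "morphometry.csv")
    ok = df[df.qc_status == "pass"]

    rows = []
    for cls, sub in ok.groupby("class"):
        m = sub.groupby("frame")[["apical_area_um2", "basal_area_um2",
                                  "height_um", "volume_um3"]].mean()
        for col in m.columns:
            norm = normalize_series(m[col].to_numpy(), 0)
            for f, (raw, nv) in enumerate(zip(m[col], norm)):
                rows.append({"class": cls, "frame": f, "metric": col,
                             "value": raw, "normalized": nv})
    tidy = pd.DataFrame(rows)
    tidy.to_csv(OUT / "normalized_series.csv", index=False)

    stim = tidy[(tidy["class"] == "stimulated")]
    red = 100 * (1 - stim[(stim.metric == "apical_area_um2") & (stim.frame == 3)]
                 .normalized.iloc[0])
    hinc = 100 * (stim[(stim.metric == "height_um") & (stim.frame == 3)]
                  .normalized.iloc[0] - 1)
    print(f"stimulated cells: apical area -{red:.1f}%, height +{hinc:.1f}% at plateau")
    for cls in sorted(tidy["class"].unique()):
        sub = tidy[(tidy["class"] == cls) & (tidy.metric == "apical_area_um2")
                   & (tidy.frame == 3)]
        if len(sub):
            print(f"  {cls}: apical area x{sub.normalized.iloc[0]:.3f}")

    avg = ok.groupby("frame")[["volume_um3", "apical_area_um2",
                               "basal_area_um2", "height_um"]].mean()
    avg["predicted_height_um"] = predict_series(avg, predict="height_um")
    avg["offset_um"] = avg.predicted_height_um - avg.height_um
    avg.to_csv(OUT / "height_model.csv")
    print(f"model height offset (pred - measured): {avg.offset_um.mean():.2f} µm "
          f"(constant across frames to ±{avg.offset_um.std():.3f})")


if __name__ == "__main__":
    main()
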