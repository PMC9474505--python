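#!/usr/bin/env python
"""Colony skeleton curvature and organoid flattening.

Two curvature studies: (i) the midline skeleton of a synthetic curved
colony cross-section, whose circumcircle curvature should read 1/R;
(ii) an organoid perimeter flattened over a chord, measured with the
wide 320-px point spacing and indexed by angle from the stimulation
centre.  Writes results/curvature/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from optomorph.curvature import extract_skeleton, local_curvature, perimeter_curvature
from optomorph.synthetic import contour_to_mask, flattened_disc_contour, generate_colony_profile

OUT = Path(__file__).resolve().parent.parent / "results" / "curvature"
PX = 0.207


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    img, true_k = generate_colony_profile(
        arc_radius=100.0, arc_span=120.0, thickness=8.0,
        shape=(640, 1024), pixel_size=PX, noise_sd=0.02, seed=seed,
    )
    skel = extract_skeleton(img, pixel_size=PX)
    prof = local_curvature(skel, spacing=20, pixel_size=PX)
    pd.DataFrame({"arc_position_um": prof.positions, "kappa_per_um": prof.kappa}).to_csv(
        OUT / "colony_skeleton_curvature.csv", index=False
    )
    print(f"colony skeleton: mean kappa {prof.mean:.5f} /µm (true {true_k:.5f})")

    radius, span, px = 80.0, 70.0, 0.2
    sz = int(2 * radius / px * 1.15)
    stim_center = (sz * px / 2 + radius, sz * px / 2)
    rows = []
    for label, contour in (
        ("before", None),
        ("after", flattened_disc_contour(radius, span, 0.0, 6000)),
    ):
        if contour is None:
            th = np.linspace(0, 2 * np.pi, 6000, endpoint=False)
            contour = radius * np.column_stack([np.cos(th), np.sin(th)])
        prof = perimeter_curvature(
            contour_to_mask(contour, (sz, sz), px), stim_center, spacing=320, pixel_size=px
        )
        for a, k in zip(prof.positions, prof.kappa):
            rows.append({"state": label, "angle_deg": a, "kappa_per_um": k})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "organoid_perimeter_curvature.csv", index=False)
    win = df[np.abs(df.angle_deg) <= 35.0]
    k0 = win[win.state == "before"].kappa_per_um.mean()
    k1 = win[win.state == "after"].kappa_per_um.mean()
    print(f"organoid window (|angle|<=35°): kappa {k0:.5f} -> {k1:.5f} /µm "
          f"({100 * (1 - k1 / k0):.1f}% reduction)")


if __name__ == "__main__":
    main()
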