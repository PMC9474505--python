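#!/usr/bin/env python
"""Generate the study-condition monolayer timelapse and its ground truth.

A 5×5 MDCK-like monolayer (0.207 µm x-y / 0.7 µm z voxels, 10 µm cells)
receives a 26.5 µm square stimulation with a programmed 25.4% plateau
apical-area reduction at conserved volume and fixed basal surface.
Writes the membrane stacks, ground-truth label volumes and ground-truth
table under results/monolayer/.
"""

from pathlib import Path

from optomorph.stack import write_labels, write_stack
from optomorph.synthetic import ConstrictionProgram, SyntheticTissueSpec, generate_monolayer
from optomorph.tracking import StimulationROI

OUT = Path(__file__).resolve().parent.parent / "results" / "monolayer"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticTissueSpec(grid_shape=(5, 5), n_frames=4, frame_interval=25.0, seed=seed)
    w, h = spec.field_size
    roi = StimulationROI(w / 2 - 13.25, w / 2 + 13.25, h / 2 - 13.25, h / 2 + 13.25,
                         t_start=1.0)
    mono = generate_monolayer(spec, ConstrictionProgram(roi=roi))
    for f, (st, lab) in enumerate(zip(mono.stacks, mono.labels)):
        write_stack(OUT / f"membrane_t{f:03d}.tif", st)
        write_labels(OUT / f"truth_labels_t{f:03d}.tif", lab)
    mono.truth.to_csv(OUT / "ground_truth.csv", index=False)
    (OUT / "roi.txt").write_text(
        f"{roi.x_min} {roi.x_max} {roi.y_min} {roi.y_max} {roi.t_start}\n"
    )
    stim = mono.truth[mono.truth["class"] == "stimulated"]
    print(f"wrote {len(mono.stacks)} frames, {mono.truth.label.nunique()} cells "
          f"({stim.label.nunique()} stimulated) -> {OUT}")


if __name__ == "__main__":
    main()
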