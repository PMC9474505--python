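#!/usr/bin/env python
"""Segment, track, QC-filter and measure the simulated timelapse.

Reads the stacks written by 01_simulate_monolayer.py, rescales each to
isotropic voxels, runs the seeded 3D watershed, links cells by maximum
overlap, applies the all-frames and 30%-volume-jump quality rules, and
classifies cells as stimulated / neighbour layers.  Writes the tidy
morphometry table to results/monolayer/morphometry.csv.
"""

from pathlib import Path

from optomorph.pipeline import analyze_timelapse
from optomorph.stack import read_stack
from optomorph.tracking import StimulationROI

OUT = Path(__file__).resolve().parent.parent / "results" / "monolayer"


def main() -> None:
    stacks = [read_stack(p) for p in sorted(OUT.glob("membrane_t*.tif"))]
    if not stacks:
        raise SystemExit("run 01_simulate_monolayer.py first")
    vals = [float(x) for x in (OUT / "roi.txt").read_text().split()]
    roi = StimulationROI(*vals[:4], t_start=vals[4])
    res = analyze_timelapse(stacks, roi)
    res.table.to_csv(OUT / "morphometry.csv", index=False)
    n_pass = res.table[res.table.qc_status == "pass"].track_id.nunique()
    print(f"{len(res.tracks)} tracks pass QC ({len(res.rejected)} rejected); "
          f"{len(res.stimulated_majority)} stimulated (majority rule); "
          f"{n_pass} cells in the final table -> {OUT/'morphometry.csv'}")


if __name__ == "__main__":
    main()
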