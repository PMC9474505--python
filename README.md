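# optomorph

Quantitative image analysis of optogenetically induced apical constriction
in epithelia.

When an optogenetic dimerizer reconstitutes an apical-constriction
regulator under blue light, illuminated cells shrink their apical surface,
elongate, pull their neighbours inward, and — at tissue scale — thicken
epithelia, shrink lumens and flatten organoid walls. `optomorph`
implements the complete measurement chain used to quantify these effects
from confocal microscopy, together with a ground-truthed synthetic tissue
generator so every stage can be validated without access to raw
microscopy data:

- **synthetic** — membrane-labelled columnar monolayers (Voronoi packing,
  programmable constriction with conserved volume), analytic displacement
  fields, colony cross-sections, organoid contours, junction images and
  kinetics series — all with exact ground truth;
- **segmentation** — rescaling of anisotropic stacks to 1:1:1 voxels
  (linear interpolation), seeded 3D watershed of the membrane channel,
  2D apical-slice watershed, apical/basal slice selection;
- **morphometry** — voxel-counting volume, apical/basal contact areas,
  contact-plane cell height, normalized series, projected colony area,
  maximum Feret lumen diameter, repeated-probe epithelial thickness;
- **tracking** — maximum-overlap frame linking, quality control
  (all-frames rule and the 30% volume-jump rule), stimulated-cell
  classification (contact and majority rules) and neighbour-layer
  assignment by graph distance;
- **shape_model** — the linear-taper cell model `V = h (Aa + Ab) / 2`,
  predicting any one of volume, apical area, basal area or height from
  the other three (`h = 2V / (Aa + Ab)`);
- **curvature** — signed local curvature from the circumscribed circle of
  three equally spaced curve points, `κ = 1/R = 4K / (AB·BC·CA)`, applied
  to colony skeletons (20 px spacing) and organoid perimeters (320 px
  spacing, angle-indexed from the stimulation centre);
- **flow** — single-pass cross-correlation PIV (64 px interrogation
  windows, sub-pixel peak fit), radial components toward the stimulation
  centre, stimulated/adjacent/outer zone averaging, accumulated
  displacement and distance profiles;
- **intensity** — junction/cytoplasm translocation ratios (5×5-px ROIs
  with nearest-cytoplasm pairing, or mask-based) and single-exponential
  on/off kinetics with the unbinding half-life `τ_off · ln 2`.

## Worked example

The `analysis/` scripts form the full narrative; the core of it in a few
lines:

```python
from optomorph.pipeline import analyze_timelapse
from optomorph.synthetic import (ConstrictionProgram, SyntheticTissueSpec,
                                 generate_monolayer)
from optomorph.tracking import StimulationROI

spec = SyntheticTissueSpec(grid_shape=(5, 5), n_frames=4,
                           frame_interval=25.0, seed=1)
w, h = spec.field_size
roi = StimulationROI(w/2 - 13.25, w/2 + 13.25, h/2 - 13.25, h/2 + 13.25,
                     t_start=1.0)
mono = generate_monolayer(spec, ConstrictionProgram(roi=roi))  # r = 0.254
res = analyze_timelapse(mono.stacks, roi)

ok = res.table[res.table.qc_status == "pass"]
stim = ok[ok["class"] == "stimulated"].groupby("frame")
m = stim[["apical_area_um2", "height_um"]].mean()
print(f"apical area -{100*(1 - m.apical_area_um2.iloc[-1]/m.apical_area_um2.iloc[0]):.1f}%")
print(f"height      +{100*(m.height_um.iloc[-1]/m.height_um.iloc[0] - 1):.1f}%")
```

prints

```
apical area -23.1%
height      +14.1%
```

— the pipeline recovers the programmed 25.4% plateau constriction within
a few percentage points, and the accompanying cell elongation matches
the linear-taper prediction (`2/(2 - r)` ≈ +14.5% for equal initial
apical and basal areas at conserved volume).

Running the numbered scripts in `analysis/` reproduces the remaining
studies (curvature, PIV zones, translocation kinetics, organoid
measures), each writing tidy CSV tables under `results/`. A thin
`optomorph` command-line wrapper exposes the same stages
(`optomorph simulate`, `segment`, `measure`, `model`, …) over a YAML
configuration.

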