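# canalfill

Volumetric humeral canal fill analysis for stemmed reverse shoulder
arthroplasty, rebuilt end-to-end on synthetic data: CT-style phantom
generation, bone-density calibration, medullary canal segmentation,
three-dimensional and radiographic fill ratios, virtual implant
planning, 2D–3D registration verification, cyclic-loading kinematics
from optically tracked point clouds, and the reliability/group
statistics that connect them.

## Who this is for

Biomechanics and orthopaedic-imaging researchers who need a tested,
reusable implementation of the canal-fill measurement chain — and a
synthetic test bed for it. Cadaveric datasets behind published fill-ratio
studies are rarely deposited; here every input (CT volume, implant
geometry, radiograph, marker trajectory) is generated with known ground
truth, so every estimator in the chain can be validated by closure
against its generator.

## The quantities at the core

* **Volumetric fill ratio (3D VFR)** — implant volume (stem + cup)
  distal to the anatomic-neck resection plane divided by the segmented
  canal volume between that plane and the implant-tip level, computed by
  congruent voxel counting. Specimens split into low/high fill groups at
  VFR = 0.72 (low: VFR < 0.72).
* **2D metaphysis / diaphysis FR** — implant-to-canal width ratios on a
  simulated AP radiograph; for concentric cylinders VFR = (2D FR)².
* **BMD calibration** — grayscale → mgHA/cm³ by piecewise-linear
  interpolation through air/fat/muscle anchors (−840 / −80 / 30), plus
  pixel-counting VOI metrics (BMD means, BV/TV).
* **Primary stability & bone loading** — implant subsidence s and
  coronal tilt α per 220/520/820 N load block, bone micromotion as the
  final-cycle hysteresis width, and total bone deformation from the
  time-zero reference — all from rigid-body-corrected marker clouds.
* **Reliability** — ICC(C,1) (two-way random effects, single measures,
  consistency) between planned and implanted fill ratios, with exact
  F-based confidence intervals; ANOVA + Holm–Šidák, Shapiro–Wilk /
  Brown–Forsythe gating, Kruskal–Wallis + Dunn/Bonferroni, Pearson r.

See `docs/methods.md` for models, parameters and design choices.

## Worked example

An eight-specimen synthetic cohort — phantom → plan → implant →
register → recompute → cyclic loading → statistics:

```sh
canalfill cohort --n-specimens 8 --seed 7 --out cohort/
```

`cohort/report.md` then contains the reliability block (this is the
actual output for seed 7):

| measure          |      icc |    ci_low |   ci_high |     p_value | category  |
|:-----------------|---------:|----------:|----------:|------------:|:----------|
| 3D VFR           | 0.979 | 0.901  |  0.996 | 2.0e-06 | excellent |
| 2D Metaphysis FR | 0.961 | 0.821  |  0.992 | 1.8e-05 | excellent |
| 2D Diaphysis FR  | 0.662 | -0.008 |  0.922 | 0.026   | moderate  |

Reading it: the planned (preoperative) and implanted (postoperative,
recovered by 2D–3D registration) fill ratios agree almost perfectly in
3D, while the projection-based diaphyseal width ratio is noticeably less
reliable — the 3D measure survives the plan→implant→verify round trip
better than the radiographic ones, which is the methodological point of
the volumetric measure. `table2_groups.csv` holds the four-group
(standard/short × low/high fill) comparison of density and fill
parameters, and `correlations.csv` the fill-ratio-versus-bone-micromotion
correlations per load block.

Individual stages are available as library functions and as subcommands:

```sh
canalfill simulate phantom --seed 1 --spacing 0.5 --out phantom/
canalfill simulate xray --volume phantom/phantom.mhd --view AP --out ap.tiff
canalfill plan --volume phantom/phantom.mhd --masks phantom/masks.mhd \
    --mode target:0.72 --out placement.json
canalfill simulate tracking --seed 2 --out tracking.csv
canalfill kinematics --tracking tracking.csv --out metrics.csv
```

`placement.json` reports the selected component with its achieved
`3D VFR` (`0.718` for this seed), the 2D ratios and the group label
(`Standard_low` — 0.718 falls just below the 0.72 threshold);
`metrics.csv` has one row per load block with
`s_implant_mm`, `alpha_implant_deg`, `s_bone_hw_um`, `s_bone_tot_um`.

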