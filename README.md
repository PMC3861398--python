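# nestmorph

Tumor-nest morphometrics and prognostic scoring from cytokeratin-stained
core images.

Invasive ductal carcinoma grows as *tumor nests* — connected groups of
carcinoma cells embedded in stroma. Immunohistochemical cytokeratin (CK)
staining turns nests DAB-brown against a pale hematoxylin background, which
makes their boundaries machine-readable. `nestmorph` implements the full
analysis chain from such images to prognosis, for researchers studying
whether nest architecture carries independent prognostic information:

1. **Segmentation** of nests from RGB core images: H-DAB color
   deconvolution, median de-noising, global Otsu thresholding, disk
   opening, hole filling, optional mask overrides (a non-interactive
   stand-in for expert correction), 8-connected labeling with a
   minimum-size filter, and Moore boundary tracing.
2. **Eight mathematical parameters (MPs)** per core, for nests
   *i = 1..n* with pixel area *Aᵢ* and contour perimeter *Pᵢ*:
   number *n*; total perimeter ΣPᵢ; average perimeter ΣPᵢ/n; total area
   ΣAᵢ; average area ΣAᵢ/n; total-area/total-perimeter ΣAᵢ/ΣPᵢ;
   average area/perimeter (1/n)Σ(Aᵢ/Pᵢ); and circularity
   (1/n)Σ(4πAᵢ/Pᵢ²), which is 1 for a perfect disk.
3. **Survival-driven grading**: each parameter is split into grades
   I/II/III by an exhaustive two-cutpoint search maximizing the 2-df
   log-rank statistic (the "best-P" / X-tile principle), subject to a
   minimum group fraction. Grades are scored 1/2/3 and summed into
   **integrated parameter 1** (number + circularity + total perimeter,
   range 3–9) and **integrated parameter 2** (the four average-size
   parameters, range 4–12), each re-divided into low/middle/high tiles by
   the same search.
4. **Survival statistics**: Kaplan-Meier curves with multi-group log-rank
   tests, Pearson chi-square associations, ROC analysis of five-year
   recurrence (trapezoidal AUC, Hanley-McNeil CI), and multivariate Cox
   models with Efron tie handling, grades/tiles entered as ordinal 1/2/3.

Because no public dataset accompanies this problem, the package ships a
first-class synthetic-data layer: seeded core images with exact geometric
ground truth (circles, ellipses, perturbed blobs; analytic areas and
perimeters) and survival cohorts with known feature-hazard structure,
including a full default study bundle of 202 patients × 2 cores in which a
latent per-patient aggressiveness drives both nest morphology and hazard.

## Worked example

```python
from nestmorph import (SyntheticImageSpec, generate_core_image, segment_core,
                       measure_all_nests, compute_core_features, FEATURE_COLUMNS)

spec = SyntheticImageSpec(n_nests=12, shape_family="blob", noise_sd=6.0, seed=7)
image, truth = generate_core_image(spec)     # 512x512 RGB + ground truth
seg = segment_core(image)                    # four-step segmentation
feats = compute_core_features(measure_all_nests(seg), core_id="demo")
print(f"true nests: {truth.n_nests}, segmented nests: {seg.n_nests}")
for name in FEATURE_COLUMNS:
    print(f"{name:18s} {getattr(feats, name):10.3f}")
```

prints

```
true nests: 12, segmented nests: 12
number                 12.000
total_perimeter      1489.675
average_perimeter     124.140
total_area          13925.000
average_area         1160.417
ta_over_tp              9.348
avg_a_over_p            8.433
circularity             0.862
```

All 12 rendered nests are recovered; areas and perimeters are in pixels
(perimeter = Moore chain-code length, axial step 1, diagonal step √2), and
the mean circularity of 0.86 reflects the moderate radial irregularity of
the rendered blobs.

The full pipeline runs from the command line:

```bash
nestmorph run-all --output-dir out --seed 1
```

which simulates the default 404-core / 202-patient bundle, segments every
core, grades the parameters against the simulated disease-free survival,
and writes `features.csv`, `graded.csv`, `cutpoints.json`, `results.json`,
a markdown report and a checksummed manifest. The closing line summarizes
the headline result, e.g. a Cox hazard ratio per integrated-parameter-1
tile step of about 1.5 and a three-tile log-rank p-value around 1e-6: the
morphology-hazard link wired into the simulation is recovered from pixels
alone. Individual stages are available as `simulate`, `segment`, `grade`,
`survival` and `report` subcommands operating on the same plain-text files.

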