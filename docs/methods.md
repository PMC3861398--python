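# Methods

This note documents the models, conventions and design choices behind
`nestmorph`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic core images

`SyntheticImageSpec` / `generate_core_image` render non-overlapping nest
shapes on a uniform background with optional additive Gaussian noise.

* **Shape families.** `circle` (radius r), `ellipse` (semi-major r, aspect
  ratio drawn from U(1.2, 1.8), random orientation), and `blob`: a
  star-convex radial perturbation r(θ) = r·(1 + Σⱼ aⱼ sin(kⱼθ + φⱼ)) with
  two harmonics of order 2–6 and total relative amplitude
  `blob_irregularity` (default 0.15, capped below 0.5 so shapes stay
  simple and star-convex). Blobs are the general family; circles and
  ellipses are the analytically tractable special cases.
* **Ground truth.** Rasterization is pixel-center-in-shape, so the label
  mask is the exact digitization of the analytic geometry. Analytic areas
  and perimeters use πr² / 2πr for circles, πab and Ramanujan's
  approximation for ellipses, and a dense (4096-vertex) polygon of the
  radial function for blobs. Pixel-count areas agree with analytic areas
  to within 2% for radius ≥ 10 px (asserted in tests).
* **Placement** is rejection sampling with a hard cap of 10,000 attempts
  across a call; bounding circles must clear each other by 4 px so that
  morphological opening never has to separate touching nests and the
  per-nest ground truth stays well defined. Failure raises
  `PlacementError`; the nest count is never silently reduced.
* **Colors.** Foreground DAB-brown (120, 70, 40), background pale
  hematoxylin (225, 220, 235). Distractors (unstained vessel/nerve-like
  shapes, rendered as thin ellipses of aspect 3–5) use a blue-grey tint of
  the background (−35, −25, −5) chosen so its DAB deconvolution response
  is at or below the background's: distractors must be stain-negative by
  construction, including on noise-free images.
* **Working raster** defaults to 512×512 for desk-scale speed; the
  original acquisition scale (2781×2781) is reachable through the spec.
* **Determinism.** One `numpy.random.default_rng(seed)` per call; no
  global state. Identical spec + seed ⇒ bit-identical image and mask.

The generator emulates contrast structure, object geometry, additive
sensor noise and stain-negative distractors. It does **not** emulate stain
physics (uneven DAB uptake, edge gradients), tissue texture, out-of-focus
blur, scanner artifacts, or touching/overlapping nests. Passing tests
therefore demonstrate correctness of the measurement chain on images whose
segmentation is well posed, not segmentation robustness on marginal
histology.

## Synthetic survival cohorts

`generate_cohort` draws three per-patient grades i.i.d. from {1, 2, 3}
with probabilities (0.4, 0.4, 0.2), sums them into a score (3–9), and
samples event times from an exponential with hazard

    λᵢ = baseline_hazard · exp(β_score · scoreᵢ + Σ_c β_c · x_c,i)

with independent exponential censoring (`censoring_rate`) and
administrative censoring at `followup_horizon` (months; default 60 = five
years). Clinical covariates (T stage, N status, histological grade,
hormone receptor, Her-2) are drawn from fixed categorical distributions
loosely shaped like a breast-carcinoma TMA cohort. Under β = 0 the
Kaplan-Meier estimate matches the closed-form exponential survivor
function within Monte-Carlo error (asserted at n = 2000, ±3 SE).

`generate_study` builds the full default bundle (202 patients × 2 cores):
a latent per-patient aggressiveness u ~ U(0, 1) drives both morphology and
hazard. Cores get 5 + Binomial(25, u) blob nests whose size range scales
by (1.3 − 0.6u) and whose irregularity is 0.35 − 0.30u, so an aggressive
core is a field of many small round nests: nest number, circularity and
total perimeter rise with u while the four average-size parameters fall —
the direction structure the grading layer's two integrated parameter sets
encode. The hazard is baseline · exp(1.8·(u − ½) + covariate terms),
giving roughly half the cohort an event within the 60-month horizon.

## Segmentation

Four steps, each a classical operation with explicit parameters:

1. **Stain channel** — H-DAB color deconvolution with the published
   standard stain matrix (Ruifrok & Johnston, as shipped in
   scikit-image); no per-image stain estimation. Median filter with a
   disk footprint (`denoise_radius`, default 2 px at the 512×512 working
   scale), then a linear stretch to [0, 1]. An all-constant channel is
   returned unchanged and flagged degenerate (the stretch would divide by
   zero); downstream binarization refuses it explicitly.
2. **Otsu threshold** on a 256-bin histogram; foreground strictly above
   the threshold, which is recorded in `params_used`.
3. **Opening** with a disk of `opening_radius` (default 2 px) — smooths
   silhouettes and removes protrusions; opening is anti-extensive, so it
   never merges nests.
4. **Hole filling** of background components not 4-connected to the
   raster border.

Then the optional override raster ({0 keep, 1 add, 2 remove}) — the
non-interactive stand-in for expert correction — and 8-connected component
labeling with a minimum size (`min_size`, default 50 px, the automated
proxy for expert deletion of noise signals). Components touching the
raster rim are kept (a tissue core is a circular field; no exclusion rule)
and flagged.

**Conventions.** Foreground 8-connected, background 4-connected (the
standard digital-topology pairing); 0-based (row, col) coordinates, origin
top-left. The boundary map is the inner 4-neighbour boundary — foreground
pixels with a background 4-neighbour, off-raster pixels counting as
background (a full-raster foreground's boundary is the raster rim). This
is the set a gradient operator run on the binary raster is meant to
highlight, made exact: a literal Sobel-magnitude threshold marks
second-layer pixels on 45° staircases and misses the interior of
one-pixel-wide lines, so the neighbour-based definition is used as the
canonical one and is what the tests' independent scan oracle checks.

**Contours** are closed Moore traces through boundary-pixel centers,
walked clockwise from the topmost-leftmost pixel with background
backtracking; the walk stops when its (pixel, backtrack) state repeats,
which traverses the boundary cycle exactly once and handles one-pixel
spurs (traced out and back) and cut vertices (passed through twice).

## Feature measurement

Area is the pixel count of a labeled nest; perimeter is the chain-code
length of its Moore contour — axial step 1, diagonal step √2; an isolated
single-pixel contour gets length 1 by convention so perimeters stay
positive. All quantities remain in pixels; no micron conversion. The
convention string is written into every features row.

This perimeter convention is the most consequential choice in the package
and deserves its numbers. Chain-code length systematically overestimates
the length of a smooth curve: for a digital straight line at angle θ the
overestimate factor is cos θ + (√2−1)·sin θ, which averages ≈ 1.055 over
orientations. The bias is scale-dependent at small radii — a digitized
disk's measured perimeter runs from ≈ 2.3% over 2πr at r = 10 to ≈ 5%
at r = 50 (small disks digitize as near-octagons, whose 0°/45° edges the
chain code measures exactly) — so circularity 4πA/P² of digitized disks
sits in ≈ 0.91–0.96 rather than at 1, and drifts by more than 3% between a
radius-10 shape and its 4× dilation. From baseline radius ≈ 30 px the
drift over 2–4× dilation stays within ≈ 3% for all three shape families
(typical draws 1–3%; individual irregular blob draws can reach ≈ 3.5%);
the scale-invariance tests therefore use radius-30 baselines, and the
digitized-disk circularity band [0.9, 1.1] is asserted for r ≥ 20.
Circularity is deliberately not clamped at 1; the minimum-size filter
bounds small-object distortion.

Degenerate cores (zero nests) get NaN ratio fields and are excluded from
per-patient aggregation with a logged warning, never imputed. Cores are
aggregated per patient by the mean of non-degenerate cores (configurable:
mean / max / first).

## Grading and integrated scores

`search_cutpoints` enumerates every ordered pair of distinct observed
values (cut1 < cut2; boundary belongs to the lower grade, applied
uniformly) whose induced three groups each hold ≥ `min_frac` of the cohort
(default 0.10 — an X-tile-style floor consistent with the smallest
published group sizes in this literature), computes the 2-df log-rank
chi-square for each partition, and returns the maximizer, breaking ties
toward the smaller cut1 then cut2. The implementation vectorizes all
candidate pairs against a pre-aggregated risk table (standard
hypergeometric mean/variance with the (N−d)/(N−1) tie factor) and is
validated against both lifelines and a naive from-scratch double loop:
for n ≤ 80 the returned (cut1, cut2, chi-square) are identical.

Grades map to scores 1/2/3 and sum into integrated parameter 1 (the
negatively prognostic set: number, circularity, total perimeter) and
integrated parameter 2 (the positively prognostic set: the four
average-size parameters); each score is re-divided into low/middle/high
tiles by the same search. Cutpoints are always re-derived from the cohort
at hand — published cutoffs are cohort-specific and not portable. No
cross-validation or split-sample validation of cutpoints is performed.

**Honesty of the best-P principle.** The uncorrected p-value compares the
*maximum* of many correlated statistics against a fixed χ²₂ reference and
is anti-conservative: on null score cohorts (n = 60, no score-hazard
effect) it rejects at nominal 0.05 in roughly 9–13% of replicates
(computed by the acceptance suite). Each result therefore also carries
`p_value_corrected`, a Bonferroni bound over the number of candidate pairs
actually evaluated. A Bonferroni bound over exchangeable valid p-values
controls the level exactly; the small residue observed above nominal
(≈ 4–7% across seeds in the null calibration) comes from the asymptotic
χ²₂ approximation itself, whose extreme tail is too light at 25–40 events
with groups as small as six patients — not from the multiplicity handling.
With a dense continuous marker (≈ 950 candidate pairs at n = 60) the
correction probes even deeper tails and the residual inflation grows; the
corrected p should be read as a strong, honest attenuation of selection
bias, not an exact size-α test at small n. A selection adjustment designed
for a single cutpoint (one degree of freedom) does not transfer to the
two-cutpoint, 2-df search, which is why the generic Bonferroni bound is
used instead.

## Survival statistics

* **Kaplan-Meier / log-rank**: product-limit curves per group (lifelines)
  and the (k−1)-df multi-group log-rank test. On uncensored data the KM
  curve equals the empirical survivor function exactly.
* **Pearson chi-square** on the contingency table, no continuity
  correction; zero marginals are an error.
* **ROC for five-year recurrence**: positives have an observed event at or
  before the horizon; negatives are event-free with follow-up reaching it;
  patients censored before the horizon carry no five-year label and are
  excluded, with the count reported in the result, the log and the run
  manifest. The trapezoidal AUC over the tie-aware ROC curve equals the
  Mann-Whitney U statistic divided by n₊·n₋ (asserted to 1e-12); the CI
  uses the Hanley-McNeil variance and the p-value is the two-sided normal
  test against AUC = 0.5.
* **Cox proportional hazards** via lifelines with Efron tie handling
  (better than Breslow under ties). Graded/tiled variables enter as
  ordinal 1/2/3, so each HR is per one grade/tile step. Constant
  covariates and non-convergence raise explicit errors; fewer than five
  events per covariate logs a warning. No proportional-hazards
  diagnostics are run.

All tests are two-sided at α = 0.05.

## Pipeline and reproducibility

Stages exchange plain CSV/JSON (and PNG images/16-bit PNG masks when image
saving is on), so any stage can be inspected, replaced or resumed from
file. The manifest records the config snapshot, package version, per-stage
output SHA-256 checksums, timings, record counts in/out, and every warning
that changes an n (degenerate cores, ROC exclusions). Given (inputs,
config, seed) the pipeline is deterministic end to end; rerunning
reproduces `results.json` byte-identically. CLI exit codes separate
configuration errors (2), data errors (3) and statistical degeneracy (4).

## Problem sizes

The test suite and acceptance script run at the study's own scale where
that is cheap and at reduced replicate counts where it is not: 20
noise-free 512×512 cores (5–30 nests) for segmentation recovery; 25
cohorts of n = 60 for cutpoint-oracle equivalence; 100 random draws for
the AUC identity; n = 2000 (plus 100 × n = 500 for CI coverage) for Cox
recovery at true HR 1.5 per score step with ≈ 30% censoring; the full
404-core / 202-patient bundle end to end; and 200 null replicates for the
best-P calibration.

## Known limitations

* The synthetic images are far cleaner than real IHC; real-world
  segmentation would need stain normalization, adaptive thresholding or
  learned methods, and the expert-override mechanism would carry real
  weight.
* The perimeter convention is declared, not claimed identical to any
  other software's; absolute perimeter and circularity values are only
  comparable within the same convention (see the bias numbers above).
* Optimal-cutpoint grading overfits by construction; the corrected
  p-value attenuates but, at small n and deep tails, does not exactly
  restore the nominal level, and grades should be validated on
  independent data before any clinical claim.
* Cores are aggregated per patient by a simple summary (default mean);
  intra-patient heterogeneity is not modeled.
* No competing risks, time-dependent ROC, or proportional-hazards
  diagnostics.
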