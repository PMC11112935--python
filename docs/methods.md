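# Methods

This note documents the models, conventions and design decisions behind
`tilspot`: what the synthetic cohort generator simulates, how the WTA and
ROI quantification protocols are defined, and which statistical conventions
are pinned for reproducibility.

## Quantification protocols

**Coordinates and masks.** All geometry is in physical micrometres, image
convention (origin top-left, y down); converting pixel exports to µm is the
upstream exporter's job, absorbed by the reader's column map. Tumor masks
are GeoJSON polygons; a cell belongs to the tumor if its centroid lies in a
mask polygon, with boundary points counted inside (closed polygons — a
deterministic tie rule). Mask area is the polygon-area sum in mm².

**WTA protocol.** Marker counts over the whole mask divided by mask area.
CCR8⁺ Tregs are strictly CCR8⁺Foxp3⁺ double positives; Foxp3⁺CCR8⁻ cells
count toward the total-Treg density only, and CCR8⁺Foxp3⁻ toward neither.
GzmB⁺ records without CD8 positivity are tolerated on input but ignored by
all CD8-denominated metrics. %GzmB⁺ in CD8⁺ T is undefined (NaN) exactly
when the region contains no CD8⁺ cell. No stromal/intra-tumoral
compartmentalization is attempted.

**ROI protocol.** Candidate fields are 360 × 270 µm rectangles with
half-open extents [x0, x0+w) × [y0, y0+h) — a cell on a shared edge belongs
to exactly one field — enumerated on a stride grid (default stride 90 µm,
¼ field width) covering the mask bounding box. The density map is a plain
box count of CCR8⁺Foxp3⁺ cells per candidate field; no kernel smoothing.

*Hot Spots*: greedy maximum selection — repeatedly take the highest-count
candidate that does not overlap an already-selected field, until five fields
or exhaustion; ties break by (count desc, y0 asc, x0 asc), which makes the
selection a pure function of the map, independent of enumeration order.
Non-overlap is the default (one dense cluster must not supply all five
fields) and is configurable (`allow_overlap`).

*Cold Spots*: a field is eligible unless it is lymphocyte-free, parsed as
(CD8⁺ count < 10 AND Foxp3⁺ count < 10) — one stain clearing the threshold
suffices. Fields overlapping a selected Hot Spot are also excluded: Hot and
Cold Spots represent distinct areas of one case, and without this exclusion
a low-Treg field straddling a cluster edge can exceed the fifth Hot Spot's
count, breaking the intended separation (min Hot-Spot Treg count ≥ max
Cold-Spot Treg count, which the test suite asserts). Among eligible fields
the five lowest CCR8⁺Treg counts are taken greedily, ties by (count asc,
y0 asc, x0 asc). When fewer than five fields are selectable, the available
ones are used and a warning logged; the patient is retained.

*Patient summaries*: unweighted means over the selected fields; fields with
undefined %GzmB are dropped from the %GzmB mean only (logged). The
GzmB/CCR8 ratio is hot-mean %GzmB divided by hot-mean CCR8⁺ Treg count,
undefined when the denominator is zero — such patients are excluded from
ratio-based groupings but from nothing else. CD8/Foxp3, GzmB/Foxp3 and
CD8/CCR8 ratios are built analogously from the Hot-Spot means.

## Statistical conventions

* **Median split**: high iff strictly above the cohort median; values at the
  median go low. With 81 distinct values this yields the 40/41 split used in
  clinical tables. Undefined metrics exclude a patient from that grouping
  only.
* **Fisher's exact test**: two-sided by probability ordering (summing
  hypergeometric probabilities ≤ that of the observed table), the convention
  of R's `fisher.test` and common clinical software; mid-p and doubling
  variants differ and are not used. The reported odds ratio is the
  conditional MLE. The `replay-table1` subcommand replays a published
  81-patient cohort's 2×2 counts through this implementation; all printed
  p-values (including the duplicated-table pair at 0.048) reproduce at
  printed precision, pinning the convention.
* **Mann–Whitney U**: exact enumeration when the pooled sample is ≤ 20 and
  tie-free, otherwise the normal approximation with tie and continuity
  corrections.
* **Correlation**: ordinary least squares with Pearson r and the two-sided
  slope test; pairs with undefined members are dropped and logged.
* **Survival**: Kaplan–Meier product-limit curves (right-continuous;
  3-year PFS is S(36 months)); two-group log-rank with 1 df; Cox partial
  likelihood with Efron tie handling and Wald CIs/p-values (the tie method
  matters little at these sample sizes but is pinned for reproducibility).
  Univariate hazard ratios are reported for the *low* group of each metric
  (high = reference). The multivariate model takes the primary ratio
  grouping plus every clinical covariate with univariate p < 0.05 — a
  configurable rule, since variable-selection criteria vary across studies.
  Kaplan–Meier, log-rank and Cox are computed via `lifelines`; the test
  suite checks them against hand product-limit, O−E/V and score-test
  oracles.

## The synthetic cohort generator

The generator emulates the data structure the analysis consumes, not any
particular cohort's values.

**Spatial process.** Lymphocytes on a slide follow a Thomas-type cluster
process: a Poisson number of parent centers (mean `n_clusters` = 20)
uniform in the tumor mask, each with a Poisson number of Gaussian offspring
(mean `cells_per_cluster` = 80, sd `cluster_sd_um` = 110 µm), plus uniform
background (`background_intensity` = 8 cells/mm²) on a default 8 × 6 mm
rectangular mask. Offspring falling outside the mask are re-drawn
conditional on the mask, so the expected count per panel is exactly
`n_clusters·cells_per_cluster + background·area` (the intensity test relies
on this). The two stain panels of a patient share one realization of the
parent centers and draw offspring independently — mimicking serially
sectioned slides, where regional densities correspond but individual cells
do not. Each cell is assigned one phenotype class (CD8⁺ with probability
0.45, Foxp3⁺ 0.30, other 0.25); panel A records Foxp3 and CCR8, panel B
records CD8 and GzmB.

**Between-patient heterogeneity.** Each patient draws their CCR8⁺ fraction
among Foxp3⁺ cells from a logit-normal law (median 0.40, logit-scale sd
1.0), creating the high/low CCR8⁺ Treg contrast between cases.

**Local suppression link.** A CD8⁺ cell in panel B is GzmB⁺ with
probability `logistic(beta0 − beta1·d)`, where d is the number of panel-A
CCR8⁺ Tregs within `suppression_radius_um` = 150 µm, rescaled from the
circular neighborhood to cells-per-field units (field area 0.0972 mm², so
the coefficient is comparable to field counts). Defaults `beta0` = 0.5
(≈ 62% GzmB⁺ far from Tregs) and `beta1` = 0.05 per cells/field are
*illustrative*: no quantitative estimate of the suppression magnitude
exists, so these were chosen once to place Hot-Spot %GzmB in a plausible
20–60% range and are documented rather than fitted. Uniform draws are made
per cell from the seed, so under common random numbers increasing `beta1`
can only switch cells off — the monotonicity property tested in the suite.

**Survival model.** PFS is exponential proportional hazards:
hazard = `baseline_hazard` (0.012/month, ≈ 65% 3-year PFS at baseline) ×
exp(`log_hr_per_unit` × z), where z is the cohort-standardized log
GzmB/CCR8 ratio computed by the ROI protocol on the patient's simulated
slide (patients with undefined ratio sit at z = 0 and are flagged). The
default `log_hr_per_unit` = −0.7 gives a hazard ratio of ≈ 2 per SD of the
log ratio, hence a dichotomized high/low contrast above 2. Censoring is
independent exponential, calibrated so the odds of censoring before an
event at baseline equal `censor_rate`/(1 − `censor_rate`) (default 0.15),
plus administrative censoring at 60 months. Binary clinicopathological
covariates are independent Bernoulli draws at cohort-realistic prevalences;
age and smoking index are drawn from plausible marginals. All randomness
descends from a single `SeedSequence`, so identical config + seed gives
byte-identical tables.

**What the generator does *not* emulate — and what passing tests show.**
No pixels, staining artifacts, segmentation error, stromal structure, or
tumor-margin geometry; masks are rectangles by default; covariates are
independent of outcome (so clinical association tables on synthetic cohorts
should reject at chance level, which is exactly what the calibration tests
assert). One deliberate structural difference from real cohorts: in the
generator, suppression acts only through the patient-level CCR8 fraction
and local density, so the whole-tumor %GzmB–Treg correlation is negative;
in real tumors, patients with many TILs tend to have more of *all* T-cell
activity, which can flip the whole-tumor correlation weakly positive while
the within-slide Hot-Spot correlation stays negative. The generator makes
no attempt to reproduce that confounding — passing direction-recovery tests
therefore validates the pipeline's measurement chain, not any claim about
real-cohort effect sizes.

## Numerical choices and degenerate inputs

* Density-map counting is vectorized with the same closed/open comparisons
  as the brute-force definition, so counts equal a per-field recount
  exactly, for any stride (tested at strides that do and do not divide the
  field size).
* CSV round trips use `float_precision="round_trip"`, so written cohorts
  re-read bit-identically; the ingest path and the in-memory path produce
  identical results (tested).
* Empty cell tables, empty candidate sets, all-censored survival input,
  zero-area masks, one-level covariates, and zero-variance regressors all
  raise typed errors or warn-and-continue as documented on each function;
  a patient with fewer than five selectable spots keeps the spots that
  exist.
* Greedy spot selection equals an exhaustive-search oracle applying the
  same rule over all candidates (tested on 125 random slides across the
  unit and acceptance suites).

## Problem sizes used in replicated checks

Replicated calibration and coverage checks run at reduced sizes chosen for
the repository's test budget, with the statistical structure unchanged:
null-calibration cohorts use 40 patients on 2000 × 1500 µm slides
(8 clusters × 40 cells); Fisher calibration runs at the full n = 81 on
clinical tables alone (its discrete null level is size-dependent, so the
study size is the right place to measure it); Cox CI coverage uses 200
replicates of n = 200 with the point-recovery check at n = 1000. The
single-cohort direction-recovery check runs at the full study scale
(81 patients, default slides).

## Known limitations

* Cross-panel co-registration is assumed given (the caller supplies
  co-registered coordinates); no image registration is implemented.
* The ROI candidate grid and the non-overlap constraint are this package's
  reproducible stand-ins for a commercial viewer's unspecified field
  placement; both are configurable.
* No multiple-testing correction in association tables (deliberately,
  matching common single-cohort reporting); no proportional-hazards
  diagnostics, time-varying covariates, or competing risks.
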