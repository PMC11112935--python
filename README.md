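# tilspot

Spatial Hot/Cold-Spot profiling of tumor-infiltrating lymphocytes from
double-immunohistochemistry cell tables, with the association and survival
statistics to evaluate prognostic immune scores.

## The problem

Immunosuppressive CCR8⁺ regulatory T cells (Tregs, defined here strictly as
CCR8⁺Foxp3⁺ double-positive cells) accumulate inside tumors and are thought
to blunt the cytotoxic function of neighboring CD8⁺ T cells, measurable as
loss of granzyme B (GzmB) expression. Because tumor-infiltrating lymphocytes
are spatially heterogeneous — dense aggregates next to empty stroma —
whole-tumor averages can mask this local suppression. `tilspot` implements
the two complementary quantification protocols used in digital-pathology
studies of this question, plus the statistics layer around them:

* **WTA protocol** (whole tumor area): marker-positive cells per mm² over the
  full pathologist-annotated tumor region, for each slide pair stained
  CCR8/Foxp3 (panel A) and CD8/GzmB (panel B).
* **ROI protocol**: a box-count density map of CCR8⁺Foxp3⁺ cells on a stride
  grid of 360 × 270 µm analysis fields; per slide the five highest-count
  non-overlapping fields are **Hot Spots** and the five lowest-count fields
  that still contain lymphocytes (≥ 10 CD8⁺ or ≥ 10 Foxp3⁺ cells) are
  **Cold Spots**. The matched fields of both panels are quantified, and
  Hot-Spot means are each patient's representative values.

Per region the four core quantities are

```
[CCR8+ Treg]        = CCR8+Foxp3+ cells per area
[Total CD8+ T]      = CD8+ cells per area
[GzmB+ CD8+ T]      = GzmB+CD8+ cells per area
[%GzmB+ in CD8+ T]  = 100 x GzmB+CD8+ / CD8+
```

and the composite prognostic score is the **GzmB/CCR8 ratio** =
[%GzmB⁺ in CD8⁺ T] / [CCR8⁺ Treg], with CD8/Foxp3, GzmB/Foxp3 and CD8/CCR8
as alternatives. The statistics layer provides median dichotomization
(strictly-above-median = high, so n = 81 splits 40/41), OLS correlation,
Mann–Whitney U, Fisher's exact test (probability-ordering two-sided p,
conditional odds ratio), Kaplan–Meier with 3-year PFS = S(36 months),
log-rank, and Cox proportional hazards (Efron ties, Wald CIs).

Because the kind of patient-level data this pipeline consumes is rarely
public, `tilspot.simulate` generates full synthetic cohorts — clustered
two-panel cell tables (a Thomas process with shared parent centers across
the serially-sectioned panels), tumor masks, a logistic local-suppression
link from CCR8⁺ Treg density to GzmB positivity, and proportional-hazards
PFS driven by the standardized log GzmB/CCR8 ratio — so every stage is
testable end to end.

## Worked example

```python
from tilspot import SimConfig, simulate_cohort, survival_report
from tilspot.roi import summaries_to_frame
from tilspot.stats import linreg_correlation
from tilspot.survival import metric_survival_frame

cohort = simulate_cohort(SimConfig(seed=1))       # 81 patients, ~2 panels x 2000 cells each
hot = cohort.field_table[cohort.field_table.spot_class == "HOT"]
r = linreg_correlation(hot.ccr8_treg_count, hot.pct_gzmb_in_cd8)
print(f"Hot-Spot fields: r = {r.pearson_r:.2f}, p = {r.p_value:.1e}, n = {r.n}")

rep = survival_report(summaries_to_frame(cohort.summaries), cohort.clinical,
                      ["gzmb_ccr8_ratio"])
print(metric_survival_frame(rep)[["metric", "pfs36_high_pct", "pfs36_low_pct",
                                  "logrank_p", "hr_low"]])
```

prints

```
Hot-Spot fields: r = -0.43, p = 5.9e-20, n = 405
            metric  pfs36_high_pct  pfs36_low_pct  logrank_p    hr_low
0  gzmb_ccr8_ratio       78.778595       50.78125   0.001953  2.628369
```

i.e. across the 405 Hot-Spot fields of the cohort, %GzmB⁺ in CD8⁺ T cells
falls as the local CCR8⁺ Treg count rises (the local-suppression direction),
and patients in the low GzmB/CCR8-ratio half have markedly worse simulated
3-year progression-free survival (50.8% vs 78.8%, log-rank p = 0.002, hazard
ratio 2.63 for the low group).

The same analyses are available as numbered drivers:

```sh
python analysis/01_simulate_cohort.py      # writes scratch/cohort + results/cohort
python analysis/02_quantify_slides.py      # WTA + ROI per patient
python analysis/03_spatial_associations.py # correlations, Hot vs Cold
python analysis/04_clinical_associations.py
python analysis/05_survival.py             # KM / log-rank / Cox
```

or through the CLI: `tilspot simulate`, `tilspot analyze`, `tilspot report`,
and `tilspot replay-table1` (replays a published cohort's clinicopathological
2×2 tables through the Fisher implementation as a convention cross-check).

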