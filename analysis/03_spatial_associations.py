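#!/usr/bin/env python
"""Spatial association analysis: does local CCR8+ Treg accumulation track
reduced GzmB expression in CD8+ T cells?

Runs the correlation and two-group comparisons at both scales: per patient
over whole-tumor densities (WTA) and per field over Hot-Spot counts (ROI),
plus the Hot-vs-Cold-Spot comparison. Writes a tidy results table and prints
the headline directions.
"""

from pathlib import Path

import pandas as pd

from tilspot.stats import linreg_correlation, mann_whitney_u, median_split

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    summaries = pd.read_csv(results / "patient_summaries.csv")
    fields = pd.read_csv(results / "field_metrics.csv")
    hot = fields[fields.spot_class == "HOT"]
    cold = fields[fields.spot_class == "COLD"]
    rows = []

    # WTA scale: CCR8+ Treg density vs CD8 parameters across patients
    for y in ("wta_cd8_per_mm2", "wta_gzmb_cd8_per_mm2", "wta_pct_gzmb_in_cd8"):
        r = linreg_correlation(summaries.wta_ccr8_treg_per_mm2, summaries[y])
        rows.append({"scale": "WTA", "x": "ccr8_treg_per_mm2", "y": y,
                     "pearson_r": r.pearson_r, "p_value": r.p_value, "n": r.n})

    # ROI scale: pooled Hot-Spot fields
    for y in ("cd8_count", "gzmb_cd8_count", "pct_gzmb_in_cd8"):
        r = linreg_correlation(hot.ccr8_treg_count, hot[y])
        rows.append({"scale": "ROI-hot", "x": "ccr8_treg_count", "y": y,
                     "pearson_r": r.pearson_r, "p_value": r.p_value, "n": r.n})

    # field-level high/low split at the pooled median, and Hot vs Cold
    g = median_split(hot.reset_index().set_index("index").ccr8_treg_count)
    hi = hot.reset_index().set_index("index").loc[g.labels.index[g.labels == "high"]]
    lo = hot.reset_index().set_index("index").loc[g.labels.index[g.labels == "low"]]
    for y in ("cd8_count", "pct_gzmb_in_cd8"):
        _, p = mann_whitney_u(hi[y].dropna(), lo[y].dropna())
        rows.append({"scale": "ROI-hot-split", "x": "treg_high_vs_low", "y": y,
                     "pearson_r": float("nan"), "p_value": p, "n": len(hot)})
    _, p = mann_whitney_u(hot.pct_gzmb_in_cd8.dropna(), cold.pct_gzmb_in_cd8.dropna())
    rows.append({"scale": "hot_vs_cold", "x": "spot_class", "y": "pct_gzmb_in_cd8",
                 "pearson_r": float("nan"), "p_value": p, "n": len(hot) + len(cold)})

    out = pd.DataFrame(rows)
    out.to_csv(results / "spatial_associations.csv", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    roi_pct = out[(out.scale == "ROI-hot") & (out.y == "pct_gzmb_in_cd8")].iloc[0]
    print(
        f"\nHot-Spot fields: CCR8+ Treg count vs %GzmB+ r = {roi_pct.pearson_r:.2f} "
        f"(p = {roi_pct.p_value:.1e}) -> local suppression direction"
    )
    print(
        "Hot vs Cold %%GzmB+: %.1f%% vs %.1f%%"
        % (hot.pct_gzmb_in_cd8.mean(), cold.pct_gzmb_in_cd8.mean())
    )


if __name__ == "__main__":
    main()
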