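"""Published clinicopathological 2×2 tables used as a fixed exact-test cross-check.

Counts transcribed from the clinicopathological characteristics table of a
published 81-patient lung squamous cell carcinoma cohort, stratified by the
median split (40 high / 41 low) of three metrics: CCR8⁺ Treg density, %GzmB⁺
in CD8⁺ T, and the GzmB/CCR8 ratio. Each entry holds the (high, low) × two-
level counts and the p-value printed alongside them; replaying the counts
through :func:`tilspot.stats.fisher_exact_2x2` reproduces the printed
values and so pins the two-sided Fisher convention this package uses.

Note: the pT × ratio row is transcribed as printed even though its low-group
counts sum to 45 rather than 41 (an inconsistency in the published table).
"""

from __future__ import annotations

from dataclasses import dataclass

from tilspot.stats import ContingencyTable2x2, fisher_exact_2x2

import pandas as pd


@dataclass(frozen=True)
class PublishedTable:
    grouping: str  # metric used for the median split
    variable: str
    high: tuple[int, int]  # counts at (level0, level1) in the metric-high group
    low: tuple[int, int]
    printed_p: float

    def to_contingency(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(self.high[0], self.high[1], self.low[0], self.low[1])


PUBLISHED_TABLES: list[PublishedTable] = [
    # grouping: CCR8+ Treg density
    PublishedTable("ccr8_treg", "sex", (6, 34), (2, 39), 0.15),
    PublishedTable("ccr8_treg", "smoking_status", (2, 38), (1, 40), 0.62),
    PublishedTable("ccr8_treg", "tumor_laterality", (19, 21), (18, 23), 0.82),
    PublishedTable("ccr8_treg", "tumor_location", (22, 18), (25, 16), 0.66),
    PublishedTable("ccr8_treg", "surgical_procedure", (5, 35), (6, 35), 1.00),
    PublishedTable("ccr8_treg", "postoperative_treatment", (6, 34), (3, 38), 0.31),
    PublishedTable("ccr8_treg", "histological_differentiation", (38, 2), (35, 6), 0.26),
    PublishedTable("ccr8_treg", "pT", (33, 7), (31, 10), 0.59),
    PublishedTable("ccr8_treg", "pN", (26, 14), (36, 5), 0.019),
    PublishedTable("ccr8_treg", "pStage", (20, 20), (26, 15), 0.27),
    PublishedTable("ccr8_treg", "lymphatic_invasion", (33, 7), (37, 4), 0.35),
    PublishedTable("ccr8_treg", "vascular_invasion", (33, 7), (38, 3), 0.19),
    PublishedTable("ccr8_treg", "pleural_invasion", (33, 7), (37, 4), 0.35),
    # grouping: %GzmB+ in CD8+ T
    PublishedTable("pct_gzmb", "sex", (6, 34), (2, 39), 0.15),
    PublishedTable("pct_gzmb", "smoking_status", (2, 38), (1, 40), 0.62),
    PublishedTable("pct_gzmb", "tumor_laterality", (18, 22), (19, 22), 1.00),
    PublishedTable("pct_gzmb", "tumor_location", (23, 17), (24, 17), 1.00),
    PublishedTable("pct_gzmb", "surgical_procedure", (4, 36), (7, 34), 0.52),
    PublishedTable("pct_gzmb", "postoperative_treatment", (5, 35), (4, 37), 0.74),
    PublishedTable("pct_gzmb", "histological_differentiation", (34, 6), (39, 2), 0.15),
    PublishedTable("pct_gzmb", "pT", (33, 7), (31, 10), 0.59),
    PublishedTable("pct_gzmb", "pN", (33, 7), (29, 12), 0.30),
    PublishedTable("pct_gzmb", "pStage", (25, 15), (21, 20), 0.37),
    PublishedTable("pct_gzmb", "lymphatic_invasion", (38, 2), (32, 9), 0.048),
    PublishedTable("pct_gzmb", "vascular_invasion", (38, 2), (33, 8), 0.088),
    PublishedTable("pct_gzmb", "pleural_invasion", (39, 1), (31, 10), 0.0070),
    # grouping: GzmB/CCR8 ratio
    PublishedTable("gzmb_ccr8_ratio", "sex", (5, 35), (3, 38), 0.48),
    PublishedTable("gzmb_ccr8_ratio", "smoking_status", (2, 38), (1, 40), 0.62),
    PublishedTable("gzmb_ccr8_ratio", "tumor_laterality", (19, 21), (18, 23), 0.82),
    PublishedTable("gzmb_ccr8_ratio", "tumor_location", (25, 16), (22, 18), 0.66),
    PublishedTable("gzmb_ccr8_ratio", "surgical_procedure", (6, 34), (5, 36), 0.76),
    PublishedTable("gzmb_ccr8_ratio", "postoperative_treatment", (3, 37), (6, 35), 0.48),
    PublishedTable("gzmb_ccr8_ratio", "histological_differentiation", (31, 9), (30, 11), 0.80),
    PublishedTable("gzmb_ccr8_ratio", "pT", (32, 8), (35, 10), 1.00),
    PublishedTable("gzmb_ccr8_ratio", "pN", (35, 5), (27, 14), 0.035),
    PublishedTable("gzmb_ccr8_ratio", "pStage", (25, 15), (21, 20), 0.37),
    PublishedTable("gzmb_ccr8_ratio", "lymphatic_invasion", (37, 3), (33, 8), 0.19),
    PublishedTable("gzmb_ccr8_ratio", "vascular_invasion", (38, 2), (33, 8), 0.088),
    PublishedTable("gzmb_ccr8_ratio", "pleural_invasion", (38, 2), (32, 9), 0.048),
]

#: the five entries printed as significant (p < 0.05)
SIGNIFICANT_KEYS: list[tuple[str, str]] = [
    ("ccr8_treg", "pN"),
    ("gzmb_ccr8_ratio", "pN"),
    ("pct_gzmb", "pleural_invasion"),
    ("gzmb_ccr8_ratio", "pleural_invasion"),
    ("pct_gzmb", "lymphatic_invasion"),
]


def get_published(grouping: str, variable: str) -> PublishedTable:
    for t in PUBLISHED_TABLES:
        if t.grouping == grouping and t.variable == variable:
            return t
    raise KeyError((grouping, variable))


def replay_published_tables() -> pd.DataFrame:
    """Run every published 2×2 table through the Fisher exact test.

    Returns a tidy frame with the computed odds ratio and p next to the
    printed p, for eyeballing the convention match.
    """
    rows = []
    for t in PUBLISHED_TABLES:
        orr, p = fisher_exact_2x2(t.to_contingency())
        rows.append({
            "grouping": t.grouping,
            "variable": t.variable,
            "high_counts": f"{t.high[0]}/{t.high[1]}",
            "low_counts": f"{t.low[0]}/{t.low[1]}",
            "odds_ratio": orr,
            "computed_p": p,
            "printed_p": t.printed_p,
        })
    return pd.DataFrame(rows)
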