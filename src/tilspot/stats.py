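"""Association statistics: median splits, correlation, rank and exact tests.

Conventions match the common clinical reporting style: patients are
dichotomized at the cohort median of a metric (strictly-greater = "high", so
an odd cohort with distinct values splits n//2 high / n//2+1 low, e.g. 40/41
at n = 81); continuous variables are compared with the Mann–Whitney U test,
categorical variables with Fisher's exact test (two-sided by the
probability-ordering rule, as in R's ``fisher.test``); correlations are
ordinary least squares with the two-sided slope test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = metric group (high, low), columns = category levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")
        if self.n == 0:
            raise ValueError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class GroupLabeling:
    """High/low labels from a median split, with the split value used."""

    labels: pd.Series  # index: patient ids; values: "high" / "low"
    split_value: float

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def median_split(values: pd.Series) -> GroupLabeling:
    """Dichotomize at the median: strictly above = "high", at or below = "low".

    Undefined (NaN) values are excluded from both the median and the labels;
    their patients simply carry no label for this grouping.
    """
    defined = values.dropna()
    if len(defined) < 2:
        raise ValueError("median split needs at least 2 defined values")
    med = float(defined.median())
    labels = pd.Series(
        np.where(defined.to_numpy(dtype=float) > med, "high", "low"),
        index=defined.index,
        name=values.name,
    )
    if (labels == "high").sum() == 0:
        logger.warning("median split: no value above the median (all tied?); all labeled low")
    return GroupLabeling(labels=labels, split_value=med)


@dataclass
class LinRegResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def linreg_correlation(x, y) -> LinRegResult:
    """OLS fit of y on x with Pearson r and the two-sided p for slope ≠ 0.

    Pairs with an undefined member are dropped (and logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < len(x):
        logger.info("linreg: dropped %d pair(s) with undefined values", int(len(x) - ok.sum()))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 defined pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = sps.linregress(x, y)
    return LinRegResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when the pooled sample is small (≤ 20) and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U for group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney requires two non-empty groups")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 table.

    Two-sided p sums hypergeometric probabilities (margins fixed) of all
    tables as or less probable than the observed one. The odds ratio is the
    conditional maximum-likelihood estimate. Returns (odds_ratio, p).
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table, dtype=int)
        table = ContingencyTable2x2(*arr.ravel())
    arr = table.to_array()
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        orr = math.nan  # degenerate margin: OR undefined
    else:
        orr = float(_conditional_odds_ratio(arr, kind="conditional").statistic)
    return orr, float(p)


#: clinical covariates treated as continuous in association tables
DEFAULT_CONTINUOUS = ("age", "brinkmann_index")


def clinico_association_table(
    clinical: pd.DataFrame,
    grouping: GroupLabeling,
    continuous_vars: tuple[str, ...] = DEFAULT_CONTINUOUS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each clinical variable against a high/low metric grouping.

    Binary/categorical variables get a 2×2 Fisher exact test (high/low ×
    level), continuous variables a Mann–Whitney comparison with per-group
    median (range). Patients without a group label (undefined metric) are
    excluded from this grouping only. Returns one tidy row per variable.
    """
    labeled = clinical.set_index("patient_id").loc[grouping.labels.index]
    is_high = (grouping.labels == "high").to_numpy()
    rows = []
    skip = {"pfs_months", "event"}
    for var in [c for c in labeled.columns if c not in skip]:
        col = labeled[var]
        if var in continuous_vars:
            a = col.to_numpy(dtype=float)[is_high]
            b = col.to_numpy(dtype=float)[~is_high]
            u, p = mann_whitney_u(a, b)
            rows.append({
                "variable": var, "test": "mann-whitney",
                "high_summary": f"{np.median(a):g} ({np.min(a):g}-{np.max(a):g})",
                "low_summary": f"{np.median(b):g} ({np.min(b):g}-{np.max(b):g})",
                "statistic": u, "odds_ratio": math.nan, "p_value": p,
                "significant": p < alpha,
            })
            continue
        levels = sorted(col.dropna().unique().tolist())
        if len(levels) != 2:
            logger.warning("variable %s has %d level(s); skipped", var, len(levels))
            continue
        lv0 = col == levels[0]
        tab = ContingencyTable2x2(
            a=int((is_high & lv0).sum()),
            b=int((is_high & ~lv0).sum()),
            c=int((~is_high & lv0).sum()),
            d=int((~is_high & ~lv0).sum()),
        )
        orr, p = fisher_exact_2x2(tab)
        rows.append({
            "variable": var, "test": "fisher",
            "high_summary": f"{tab.a}/{tab.b}", "low_summary": f"{tab.c}/{tab.d}",
            "statistic": math.nan, "odds_ratio": orr, "p_value": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
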