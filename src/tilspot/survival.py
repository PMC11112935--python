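"""Survival statistics: Kaplan–Meier, log-rank, Cox proportional hazards.

Progression-free survival (PFS) is analyzed per metric grouping: the
product-limit curve per group with the 3-year PFS read at S(36 months), a
two-group log-rank comparison, a univariate Cox hazard ratio for the low
group, and a multivariate Cox model over a configurable covariate set
(default rule: clinical covariates with univariate p < 0.05 plus the primary
ratio grouping). Ties are handled with Efron's method; confidence intervals
and p-values are Wald-type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from tilspot.stats import GroupLabeling, median_split

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


def _check_times(times: np.ndarray) -> None:
    if len(times) == 0:
        raise SurvivalError("no survival records")
    if not np.isfinite(times).all() or (times <= 0).any():
        raise SurvivalError("survival times must be finite and positive")


@dataclass
class KaplanMeierEstimate:
    """Product-limit survival estimate with a right-continuous step accessor."""

    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous, S(0) = 1; flat beyond the last event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
        })


def kaplan_meier(times, events) -> KaplanMeierEstimate:
    """Kaplan–Meier product-limit estimator for right-censored data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    _check_times(times)
    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    tbl = km.event_table
    has_event = tbl["observed"] > 0
    event_times = tbl.index.to_numpy(dtype=float)[has_event]
    surv = np.array([km.predict(t) for t in event_times], dtype=float)
    return KaplanMeierEstimate(
        event_times=event_times,
        survival=surv,
        at_risk=tbl.loc[has_event, "at_risk"].to_numpy(dtype=int),
        events=tbl.loc[has_event, "observed"].to_numpy(dtype=int),
        n=len(times),
    )


def log_rank(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test (1 df). Returns (chi2, two-sided p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    _check_times(times)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise SurvivalError(f"log-rank requires exactly 2 groups, got {len(uniq)}")
    g0 = groups == uniq[0]
    res = _ll_logrank(times[g0], times[~g0], events[g0], events[~g0])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    table: pd.DataFrame  # index: covariate; columns: hazard_ratio, ci95_low, ci95_high, p_value
    n: int
    n_events: int
    ties: str = "efron"
    log_likelihood: float = math.nan

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hazard_ratio"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["ci95_low"]), float(row["ci95_high"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p_value"])


def cox_ph(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "pfs_months",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    Supports univariate (one covariate) and multivariate fits. Requires more
    events than covariates; non-convergence and separation surface as errors
    from the optimizer with lifelines' diagnostic advice attached.
    """
    df = data[[duration_col, event_col] + list(covariates)].copy()
    df[event_col] = df[event_col].astype(bool)
    _check_times(df[duration_col].to_numpy(dtype=float))
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise SurvivalError(
            f"too few events ({n_events}) for {len(covariates)} covariate(s)"
        )
    for c in covariates:
        if df[c].nunique() < 2:
            raise SurvivalError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)  # lifelines: Efron ties
    if ties != "efron":
        raise SurvivalError("only Efron tie handling is supported")
    summ = cph.summary
    table = pd.DataFrame({
        "hazard_ratio": summ["exp(coef)"],
        "ci95_low": summ["exp(coef) lower 95%"],
        "ci95_high": summ["exp(coef) upper 95%"],
        "p_value": summ["p"],
        "coef": summ["coef"],
        "se_coef": summ["se(coef)"],
    })
    return CoxResult(
        table=table,
        n=len(df),
        n_events=n_events,
        ties=ties,
        log_likelihood=float(cph.log_likelihood_),
    )


@dataclass
class MetricSurvival:
    """Survival comparison for one metric's high/low grouping."""

    metric: str
    grouping: GroupLabeling
    km_high: KaplanMeierEstimate
    km_low: KaplanMeierEstimate
    pfs36_high: float
    pfs36_low: float
    logrank_chi2: float
    logrank_p: float
    cox_univariate: CoxResult | None


@dataclass
class SurvivalReport:
    per_metric: dict[str, MetricSurvival]
    clinical_univariate: pd.DataFrame
    multivariate: CoxResult | None
    multivariate_covariates: list[str] = field(default_factory=list)


def _merge(summaries: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    return summaries.merge(clinical, on="patient_id", validate="one_to_one")


def survival_report(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    grouping_metrics: list[str],
    primary_metric: str = "gzmb_ccr8_ratio",
    clinical_covariates: list[str] | None = None,
    multivariate_alpha: float = 0.05,
    horizon_months: float = 36.0,
) -> SurvivalReport:
    """Full survival layer over per-patient summaries and clinical outcomes.

    For each metric in ``grouping_metrics``: median split, per-group KM with
    S(horizon), log-rank p, and a univariate Cox HR for the low group (high =
    reference, matching the convention that low ratio marks the at-risk
    group). Clinical covariates get univariate Cox fits; the multivariate
    model takes those with univariate p < ``multivariate_alpha`` plus the
    ``primary_metric`` low-group indicator.
    """
    data = _merge(summaries, clinical)
    per_metric: dict[str, MetricSurvival] = {}
    for metric in grouping_metrics:
        grouping = median_split(data.set_index("patient_id")[metric])
        sub = data.set_index("patient_id").loc[grouping.labels.index]
        is_high = (grouping.labels == "high").to_numpy()
        t = sub["pfs_months"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=bool)
        km_hi = kaplan_meier(t[is_high], e[is_high])
        km_lo = kaplan_meier(t[~is_high], e[~is_high])
        chi2, p = log_rank(t, e, np.where(is_high, "high", "low"))
        cox_uni = None
        try:
            fit_df = pd.DataFrame({
                "pfs_months": t, "event": e, f"{metric}_low": (~is_high).astype(int)
            })
            cox_uni = cox_ph(fit_df, [f"{metric}_low"])
        except SurvivalError as err:
            logger.warning("univariate Cox for %s failed: %s", metric, err)
        per_metric[metric] = MetricSurvival(
            metric=metric,
            grouping=grouping,
            km_high=km_hi,
            km_low=km_lo,
            pfs36_high=km_hi.survival_at(horizon_months),
            pfs36_low=km_lo.survival_at(horizon_months),
            logrank_chi2=chi2,
            logrank_p=p,
            cox_univariate=cox_uni,
        )

    if clinical_covariates is None:
        skip = {"patient_id", "pfs_months", "event", "age", "brinkmann_index"}
        clinical_covariates = [
            c for c in clinical.columns if c not in skip and data[c].nunique() == 2
        ]
    uni_rows = []
    for cov in clinical_covariates:
        col = data[cov]
        codes = col if pd.api.types.is_numeric_dtype(col) else col.astype("category").cat.codes
        fit_df = pd.DataFrame({
            "pfs_months": data["pfs_months"], "event": data["event"], cov: codes
        })
        try:
            res = cox_ph(fit_df, [cov])
            uni_rows.append({
                "covariate": cov,
                "hazard_ratio": res.hr(cov),
                "ci95_low": res.ci(cov)[0],
                "ci95_high": res.ci(cov)[1],
                "p_value": res.p(cov),
            })
        except SurvivalError as err:
            logger.warning("univariate Cox for %s failed: %s", cov, err)
    clinical_uni = pd.DataFrame(uni_rows)

    multivariate = None
    mv_covs: list[str] = []
    if primary_metric in per_metric and len(clinical_uni):
        selected = clinical_uni.loc[clinical_uni["p_value"] < multivariate_alpha, "covariate"]
        mv_covs = selected.tolist()
        grouping = per_metric[primary_metric].grouping
        sub = data.set_index("patient_id").loc[grouping.labels.index]
        fit_df = pd.DataFrame({
            "pfs_months": sub["pfs_months"].to_numpy(dtype=float),
            "event": sub["event"].to_numpy(dtype=bool),
            f"{primary_metric}_low": (grouping.labels == "low").astype(int).to_numpy(),
        })
        for cov in mv_covs:
            col = sub[cov]
            fit_df[cov] = (
                col if pd.api.types.is_numeric_dtype(col)
                else col.astype("category").cat.codes
            ).to_numpy()
        try:
            multivariate = cox_ph(fit_df, [f"{primary_metric}_low"] + mv_covs)
        except SurvivalError as err:
            logger.warning("multivariate Cox failed: %s", err)
    return SurvivalReport(
        per_metric=per_metric,
        clinical_univariate=clinical_uni,
        multivariate=multivariate,
        multivariate_covariates=mv_covs,
    )


def metric_survival_frame(report: SurvivalReport) -> pd.DataFrame:
    """Tidy per-metric survival table (3-year PFS, log-rank, univariate HR)."""
    rows = []
    for m, res in report.per_metric.items():
        cov = f"{m}_low"
        rows.append({
            "metric": m,
            "n_high": res.grouping.n_high,
            "n_low": res.grouping.n_low,
            "pfs36_high_pct": 100 * res.pfs36_high,
            "pfs36_low_pct": 100 * res.pfs36_low,
            "logrank_chi2": res.logrank_chi2,
            "logrank_p": res.logrank_p,
            "hr_low": res.cox_univariate.hr(cov) if res.cox_univariate else math.nan,
            "hr_ci95_low": res.cox_univariate.ci(cov)[0] if res.cox_univariate else math.nan,
            "hr_ci95_high": res.cox_univariate.ci(cov)[1] if res.cox_univariate else math.nan,
            "hr_p": res.cox_univariate.p(cov) if res.cox_univariate else math.nan,
        })
    return pd.DataFrame(rows)
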