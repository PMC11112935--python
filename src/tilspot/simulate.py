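"""Synthetic cohort generator: clustered cell tables, masks, clinical outcomes.

Emulates the data structure the analysis consumes, with the statistical
features it assumes:

* lymphocytes arrive as a Thomas-type cluster process (Poisson parent centers
  uniform in the tumor mask, Gaussian offspring) plus uniform background, so
  infiltration is spatially heterogeneous with high-, low- and no-lymphocyte
  areas;
* the two stain panels are independent realizations of the same parent
  process in one shared coordinate frame, mimicking serially sectioned
  slides in which only regional densities correspond cell-to-cell;
* each patient draws a CCR8⁺ fraction among Foxp3⁺ Tregs from a logit-normal
  law, creating the between-patient high/low contrast;
* a CD8⁺ cell's probability of expressing GzmB decreases with the local
  CCR8⁺ Treg density through a logistic link (the local-suppression effect);
* progression-free survival follows an exponential proportional-hazards
  model driven by the standardized log GzmB/CCR8 ratio computed by the ROI
  protocol on the simulated slide, with independent exponential plus
  administrative censoring; clinicopathological covariates are independent
  draws at cohort-realistic prevalences.

Defaults are illustrative study conditions (the suppression magnitude has no
published quantitative estimate); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit, logit

from tilspot.io import Panel, PanelTable, TumorMask
from tilspot.roi import FIELD_AREA_MM2, PatientSummary, RoiParams, analyze_patient
from tilspot.wta import ConfigurationError

RngLike = int | np.random.SeedSequence | np.random.Generator


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """All generator parameters; deterministic output for a fixed seed."""

    n_patients: int = 81
    slide_width_um: float = 8000.0
    slide_height_um: float = 6000.0
    n_clusters: float = 20.0  # mean clusters (parent centers) per slide
    cluster_sd_um: float = 110.0  # Gaussian offspring spread
    cells_per_cluster: float = 80.0  # mean offspring per cluster
    background_intensity: float = 8.0  # cells/mm² uniform noise
    frac_cd8: float = 0.45  # phenotype fractions among lymphocytes
    frac_foxp3: float = 0.30
    frac_ccr8_mean: float = 0.40  # patient-level CCR8+ fraction among Foxp3+ (logit-normal median)
    frac_ccr8_sd: float = 1.0  # sd on the logit scale
    beta0: float = 0.5  # baseline GzmB logit
    beta1: float = 0.05  # suppression per CCR8+ Treg cells/field; ≥ 0
    suppression_radius_um: float = 150.0
    baseline_hazard: float = 0.012  # events/month
    log_hr_per_unit: float = -0.7  # per SD of log GzmB/CCR8 ratio
    censor_rate: float = 0.15  # target fraction censored before follow-up end
    follow_up_months: float = 60.0  # administrative censoring horizon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.slide_width_um <= 0 or self.slide_height_um <= 0:
            raise ConfigurationError("slide dimensions must be positive")
        if min(self.cluster_sd_um, self.suppression_radius_um) <= 0:
            raise ConfigurationError("lengths must be positive")
        if min(self.n_clusters, self.cells_per_cluster, self.background_intensity) < 0:
            raise ConfigurationError("process intensities must be non-negative")
        for name in ("frac_cd8", "frac_foxp3", "frac_ccr8_mean", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_cd8 + self.frac_foxp3 > 1.0:
            raise ConfigurationError("frac_cd8 + frac_foxp3 must be <= 1")
        if self.beta1 < 0:
            raise ConfigurationError("beta1 (suppression coefficient) must be >= 0")
        if self.baseline_hazard <= 0 or self.follow_up_months <= 0:
            raise ConfigurationError("baseline_hazard and follow_up_months must be positive")


@dataclass
class SlideSim:
    """One simulated patient slide: both panels, mask, and the drawn CCR8 fraction."""

    patient_id: str
    panel_a: PanelTable
    panel_b: PanelTable
    mask: TumorMask
    frac_ccr8: float


@dataclass
class CohortSim:
    """A simulated cohort: slides, clinical table, and the ROI summaries used for the survival link."""

    config: SimConfig
    slides: list[SlideSim]
    clinical: pd.DataFrame
    summaries: list[PatientSummary]
    field_table: pd.DataFrame
    z_log_ratio: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _uniform_in_mask(rng: np.random.Generator, mask: TumorMask, n: int) -> np.ndarray:
    import shapely

    geom = mask.geometry
    xmin, ymin, xmax, ymax = mask.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(max(n * 2, 16), 2))
        inside = shapely.covers(geom, shapely.points(cand))
        out = np.vstack([out, cand[inside]])
    return out[:n]


def _parent_centers(
    rng: np.random.Generator, config: SimConfig, mask: TumorMask
) -> np.ndarray:
    """Poisson number of cluster parent centers, uniform in the mask.

    Parents represent tissue structures (e.g. lymphoid aggregates) and are
    shared by a slide's two serially sectioned panels, so regional densities
    correspond across panels while individual cells do not.
    """
    return _uniform_in_mask(rng, mask, rng.poisson(config.n_clusters))


def _cluster_points(
    rng: np.random.Generator, config: SimConfig, mask: TumorMask, parents: np.ndarray
) -> np.ndarray:
    """One panel's Thomas-process realization around shared parent centers.

    Gaussian offspring (independent per panel) plus uniform background.
    Offspring falling outside the mask are re-drawn (placement conditional on
    the mask), so the expected total count is exactly
    E[parents]·E[offspring] + background·area."""
    import shapely

    geom = mask.geometry
    pts = []
    for px, py in parents:
        n_off = rng.poisson(config.cells_per_cluster)
        placed = np.empty((0, 2))
        while len(placed) < n_off:
            cand = rng.normal((px, py), config.cluster_sd_um, size=(n_off - len(placed), 2))
            inside = shapely.covers(geom, shapely.points(cand))
            placed = np.vstack([placed, cand[inside]])
        pts.append(placed)
    n_bg = rng.poisson(config.background_intensity * mask.area_mm2)
    pts.append(_uniform_in_mask(rng, mask, n_bg))
    return np.vstack(pts) if pts else np.empty((0, 2))


def _phenotype(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Assign each lymphocyte one class: 0 = CD8+, 1 = Foxp3+, 2 = other."""
    u = rng.random(n)
    classes = np.full(n, 2, dtype=int)
    classes[u < config.frac_cd8] = 0
    classes[(u >= config.frac_cd8) & (u < config.frac_cd8 + config.frac_foxp3)] = 1
    return classes


def assign_gzmb(
    cd8_xy: np.ndarray,
    ccr8_treg_xy: np.ndarray,
    beta0: float,
    beta1: float,
    radius_um: float,
    seed: RngLike,
) -> np.ndarray:
    """Draw per-cell GzmB positivity with local CCR8⁺ Treg suppression.

    For each CD8⁺ cell, P(GzmB⁺) = logistic(beta0 − beta1·d) where d is the
    CCR8⁺ Treg count within ``radius_um``, rescaled from the circular
    neighborhood to cells-per-analysis-field units (field area 0.0972 mm²).
    The uniform draws are made per cell from the seed, so with common random
    numbers a larger beta1 can only switch cells off, never on.
    """
    if radius_um <= 0:
        raise ConfigurationError("suppression radius must be positive")
    cd8_xy = np.asarray(cd8_xy, dtype=float).reshape(-1, 2)
    n = len(cd8_xy)
    if n == 0:
        return np.zeros(0, dtype=bool)
    ccr8_treg_xy = np.asarray(ccr8_treg_xy, dtype=float).reshape(-1, 2)
    if len(ccr8_treg_xy) == 0:
        counts = np.zeros(n)
    else:
        tree = cKDTree(ccr8_treg_xy)
        counts = np.asarray(
            tree.query_ball_point(cd8_xy, r=radius_um, return_length=True), dtype=float
        )
    circle_area_mm2 = math.pi * (radius_um / 1000.0) ** 2
    d = counts * (FIELD_AREA_MM2 / circle_area_mm2)
    p = expit(beta0 - beta1 * d)
    rng = _as_rng(seed)
    return rng.random(n) < p


def _make_panel(
    patient_id: str, panel: Panel, xy: np.ndarray, marks: dict[str, np.ndarray]
) -> PanelTable:
    prefix = "A" if panel is Panel.A_CCR8_FOXP3 else "B"
    df = pd.DataFrame({
        "cell_id": [f"{prefix}{i + 1:05d}" for i in range(len(xy))],
        "x_um": xy[:, 0] if len(xy) else np.array([], dtype=float),
        "y_um": xy[:, 1] if len(xy) else np.array([], dtype=float),
    })
    for name, vals in marks.items():
        df[name] = vals.astype(bool)
    return PanelTable(
        slide_id=f"{patient_id}_{prefix}", patient_id=patient_id, panel=panel, cells=df
    )


def simulate_slide(
    config: SimConfig,
    patient_seed: RngLike,
    patient_id: str = "P001",
    frac_ccr8: float | None = None,
    mask: TumorMask | None = None,
) -> SlideSim:
    """Simulate one patient's pair of serially-sectioned panel tables.

    Both panels are independent realizations of the same cluster process in
    one shared frame. Panel A carries CCR8/Foxp3 marks; panel B carries
    CD8/GzmB marks, with GzmB suppressed near panel A's CCR8⁺ Tregs (regional
    correspondence across the serial sections). All cells lie inside the mask.
    """
    rng = _as_rng(patient_seed)
    if mask is None:
        mask = TumorMask.rectangle(config.slide_width_um, config.slide_height_um)
    if frac_ccr8 is None:
        frac_ccr8 = float(
            expit(rng.normal(logit(config.frac_ccr8_mean), config.frac_ccr8_sd))
        )

    parents = _parent_centers(rng, config, mask)

    # panel A: CCR8/Foxp3
    xy_a = _cluster_points(rng, config, mask, parents)
    cls_a = _phenotype(rng, len(xy_a), config)
    foxp3 = cls_a == 1
    ccr8 = foxp3 & (rng.random(len(xy_a)) < frac_ccr8)
    panel_a = _make_panel(patient_id, Panel.A_CCR8_FOXP3, xy_a, {"CCR8": ccr8, "FOXP3": foxp3})

    # panel B: CD8/GzmB, independent offspring around the shared parents
    xy_b = _cluster_points(rng, config, mask, parents)
    cls_b = _phenotype(rng, len(xy_b), config)
    cd8 = cls_b == 0
    gzmb = np.zeros(len(xy_b), dtype=bool)
    treg_xy = xy_a[ccr8] if len(xy_a) else np.empty((0, 2))
    gzmb[cd8] = assign_gzmb(
        xy_b[cd8], treg_xy, config.beta0, config.beta1, config.suppression_radius_um, rng
    )
    panel_b = _make_panel(patient_id, Panel.B_CD8_GZMB, xy_b, {"CD8": cd8, "GZMB": gzmb})
    return SlideSim(patient_id, panel_a, panel_b, mask, frac_ccr8)


#: independent Bernoulli prevalences for binary clinicopathological covariates
COVARIATE_PREVALENCE: dict[str, float] = {
    "sex_male": 0.90,
    "smoker": 0.96,
    "laterality_right": 0.54,
    "location_lower_lobe": 0.42,
    "lobectomy": 0.86,
    "postop_chemo": 0.11,
    "differentiation_poor": 0.16,
    "pt_34": 0.21,
    "pn_positive": 0.23,
    "pstage_2_3": 0.43,
    "lymphatic_invasion": 0.14,
    "vascular_invasion": 0.12,
    "pleural_invasion": 0.14,
}


def standardized_log_ratio(ratios: pd.Series) -> pd.Series:
    """Cohort-standardized log ratio; undefined/non-positive ratios map to 0 (cohort mean)."""
    vals = ratios.to_numpy(dtype=float)
    ok = np.isfinite(vals) & (vals > 0)
    z = np.zeros(len(vals))
    if ok.sum() >= 2:
        lv = np.log(vals[ok])
        sd = lv.std(ddof=1)
        z[ok] = (lv - lv.mean()) / sd if sd > 0 else 0.0
    return pd.Series(z, index=ratios.index, name="z_log_ratio")


def draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Independent clinicopathological covariates at cohort-realistic prevalences."""
    cov = {
        name: (rng.random(n) < p).astype(int) for name, p in COVARIATE_PREVALENCE.items()
    }
    age = np.clip(np.round(rng.normal(71, 9, n)), 38, 90).astype(int)
    brinkmann = np.where(
        cov["smoker"] == 1,
        np.round(rng.lognormal(math.log(1000), 0.5, n) / 10) * 10,
        0.0,
    )
    return pd.DataFrame({"age": age, "brinkmann_index": np.clip(brinkmann, 0, 4000), **cov})


def draw_survival(
    rng: np.random.Generator,
    z: np.ndarray,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards PFS with exponential + administrative censoring.

    Hazard per patient: baseline_hazard · exp(log_hr_per_unit · z). The
    censoring rate parameter targets the odds of censoring before an event
    at the baseline hazard.
    """
    lam = config.baseline_hazard * np.exp(config.log_hr_per_unit * z)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        rate_c = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=len(z))
    else:
        t_cens = np.full(len(z), np.inf)
    horizon = np.minimum(t_cens, config.follow_up_months)
    time = np.minimum(t_event, horizon)
    event = t_event <= horizon
    return time, event


def simulate_cohort(
    config: SimConfig, roi_params: RoiParams | None = None
) -> CohortSim:
    """Simulate a full cohort: slides, ROI summaries, clinical outcomes.

    Per patient, a slide pair is simulated and the ROI protocol is run to
    obtain the GzmB/CCR8 ratio; PFS is then drawn from the proportional-
    hazards model on the cohort-standardized log ratio. Identical config and
    seed give identical output tables.
    """
    roi_params = roi_params or RoiParams()
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])

    slides: list[SlideSim] = []
    summaries: list[PatientSummary] = []
    field_frames: list[pd.DataFrame] = []
    for i, seed in enumerate(patient_seeds):
        pid = f"P{i + 1:03d}"
        slide = simulate_slide(config, seed, patient_id=pid)
        slides.append(slide)
        summary, fields = analyze_patient(
            pid, slide.panel_a, slide.panel_b, slide.mask, roi_params
        )
        summaries.append(summary)
        field_frames.append(fields)

    pids = [s.patient_id for s in slides]
    ratios = pd.Series([s.gzmb_ccr8_ratio for s in summaries], index=pids, name="gzmb_ccr8_ratio")
    z = standardized_log_ratio(ratios)
    time, event = draw_survival(cohort_rng, z.to_numpy(), config)
    clinical = pd.DataFrame({"patient_id": pids, "pfs_months": time, "event": event})
    clinical = pd.concat(
        [clinical, draw_covariates(cohort_rng, config.n_patients)], axis=1
    )
    return CohortSim(
        config=config,
        slides=slides,
        clinical=clinical,
        summaries=summaries,
        field_table=pd.concat(field_frames, ignore_index=True),
        z_log_ratio=z,
    )
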