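"""End-to-end orchestration: simulate → ingest → WTA → ROI → stats → survival → report.

A run is configured by :class:`RunConfig` with either a simulation block or an
input directory (the on-disk cohort layout below), executes every analysis
stage, and writes a reproducible report bundle: patient summaries, per-field
metrics, association tables per grouping metric, survival tables, and a run
manifest. Identical config + seed ⇒ identical outputs.

On-disk cohort layout (what ``simulate`` writes and ``analyze`` reads)::

    cohort_dir/
      clinical.csv            # patient_id, pfs_months, event, covariates
      P001_A.csv              # CCR8/Foxp3 panel cell table
      P001_B.csv              # CD8/GzmB panel cell table
      P001_mask.geojson       # tumor mask
      ...
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import tilspot
from tilspot.io import (
    Panel,
    PanelTable,
    TumorMask,
    read_cell_table,
    read_clinical_table,
    read_tumor_mask,
    write_cell_table,
    write_clinical_table,
    write_tumor_mask,
)
from tilspot.roi import RoiParams, analyze_patient, summaries_to_frame
from tilspot.simulate import CohortSim, SimConfig, simulate_cohort
from tilspot.stats import clinico_association_table, median_split
from tilspot.survival import metric_survival_frame, survival_report
from tilspot.wta import ConfigurationError

logger = logging.getLogger(__name__)

#: metrics offered for high/low grouping by default
DEFAULT_GROUPING_METRICS = [
    "hot_mean_ccr8_treg",
    "hot_mean_pct_gzmb",
    "gzmb_ccr8_ratio",
    "cd8_foxp3_ratio",
    "gzmb_foxp3_ratio",
    "cd8_ccr8_ratio",
    "wta_ccr8_treg_per_mm2",
    "wta_pct_gzmb_in_cd8",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (exactly one data source)."""

    sim: SimConfig | None = None
    input_dir: str | None = None
    roi: RoiParams = field(default_factory=RoiParams)
    grouping_metrics: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPING_METRICS))
    primary_metric: str = "gzmb_ccr8_ratio"
    output_dir: str = "results/run"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ConfigurationError("exactly one of {sim, input_dir} must be set")


def write_cohort_inputs(cohort: CohortSim, out_dir: str | Path) -> Path:
    """Write a simulated cohort in the on-disk layout ``analyze`` ingests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for slide in cohort.slides:
        write_cell_table(slide.panel_a, out / f"{slide.patient_id}_A.csv")
        write_cell_table(slide.panel_b, out / f"{slide.patient_id}_B.csv")
        write_tumor_mask(slide.mask, out / f"{slide.patient_id}_mask.geojson")
    write_clinical_table(cohort.clinical, out / "clinical.csv")
    return out


def load_cohort_inputs(
    in_dir: str | Path,
) -> tuple[list[tuple[str, PanelTable, PanelTable, TumorMask]], pd.DataFrame]:
    """Read a cohort directory back into panel tables, masks and the clinical table."""
    in_dir = Path(in_dir)
    clinical = read_clinical_table(in_dir / "clinical.csv")
    slides = []
    for pid in clinical["patient_id"]:
        pa = read_cell_table(in_dir / f"{pid}_A.csv", Panel.A_CCR8_FOXP3, patient_id=pid)
        pb = read_cell_table(in_dir / f"{pid}_B.csv", Panel.B_CD8_GZMB, patient_id=pid)
        mask = read_tumor_mask(in_dir / f"{pid}_mask.geojson")
        slides.append((pid, pa, pb, mask))
    return slides, clinical


def analyze_cohort(
    slides: list[tuple[str, PanelTable, PanelTable, TumorMask]],
    clinical: pd.DataFrame,
    roi_params: RoiParams | None = None,
    grouping_metrics: list[str] | None = None,
    primary_metric: str = "gzmb_ccr8_ratio",
) -> dict:
    """Run the full analysis over in-memory slides: WTA + ROI, associations, survival."""
    if not slides:
        raise ConfigurationError("empty cohort")
    roi_params = roi_params or RoiParams()
    grouping_metrics = grouping_metrics or list(DEFAULT_GROUPING_METRICS)
    summaries = []
    field_frames = []
    for pid, pa, pb, mask in slides:
        summary, fields = analyze_patient(pid, pa, pb, mask, roi_params)
        summaries.append(summary)
        field_frames.append(fields)
    summary_df = summaries_to_frame(summaries)
    field_df = pd.concat(field_frames, ignore_index=True)

    associations: dict[str, pd.DataFrame] = {}
    indexed = summary_df.set_index("patient_id")
    for metric in grouping_metrics:
        try:
            grouping = median_split(indexed[metric])
            associations[metric] = clinico_association_table(clinical, grouping)
        except ValueError as err:
            logger.warning("association table for %s skipped: %s", metric, err)
    surv = survival_report(
        summary_df, clinical, grouping_metrics, primary_metric=primary_metric
    )
    return {
        "summaries": summary_df,
        "fields": field_df,
        "associations": associations,
        "survival": surv,
        "survival_metrics": metric_survival_frame(surv),
    }


def run(config: RunConfig) -> dict:
    """Execute a configured run and write the report bundle to ``output_dir``."""
    if config.sim is not None:
        cohort = simulate_cohort(config.sim, config.roi)
        slides = [(s.patient_id, s.panel_a, s.panel_b, s.mask) for s in cohort.slides]
        clinical = cohort.clinical
    else:
        slides, clinical = load_cohort_inputs(config.input_dir)
    bundle = analyze_cohort(
        slides,
        clinical,
        config.roi,
        config.grouping_metrics,
        config.primary_metric,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["summaries"].to_csv(out / "patient_summaries.csv", index=False)
    bundle["fields"].to_csv(out / "field_metrics.csv", index=False)
    for metric, table in bundle["associations"].items():
        table.to_csv(out / f"associations_{metric}.csv", index=False)
    bundle["survival_metrics"].to_csv(out / "survival_metrics.csv", index=False)
    surv = bundle["survival"]
    surv.clinical_univariate.to_csv(out / "clinical_univariate_cox.csv", index=False)
    if surv.multivariate is not None:
        surv.multivariate.table.to_csv(out / "multivariate_cox.csv")
    for metric, res in surv.per_metric.items():
        res.km_high.to_frame().to_csv(out / f"km_{metric}_high.csv", index=False)
        res.km_low.to_frame().to_csv(out / f"km_{metric}_low.csv", index=False)
    manifest = {
        "tilspot_version": tilspot.__version__,
        "config": _config_to_jsonable(config),
        "n_patients": len(slides),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return bundle


def _config_to_jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
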