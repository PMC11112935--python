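"""ROI protocol: density maps, Hot/Cold-Spot selection, per-field metrics.

Immune infiltration in tumor sections is spatially heterogeneous, so
whole-area averages can hide local suppression. The ROI protocol scans the
slide with fixed-size analysis fields (default 360 × 270 µm), builds a box-
count density map of CCR8⁺Foxp3⁺ Tregs on a stride grid, and selects per
slide the five highest-count non-overlapping fields ("Hot Spots") and the
five lowest-count fields that still contain lymphocytes ("Cold Spots";
fields with fewer than 10 CD8⁺ AND fewer than 10 Foxp3⁺ cells are excluded
as lymphocyte-free). Matched fields of both stain panels are then quantified
and averaged into per-patient representative values, from which the
GzmB/CCR8 prognostic ratio and its alternatives are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from tilspot.io import Panel, PanelTable, TumorMask
from tilspot.wta import ConfigurationError, WtaMetrics, pct_gzmb, wta_metrics

logger = logging.getLogger(__name__)

#: default analysis-field size, µm
FIELD_WIDTH_UM = 360.0
FIELD_HEIGHT_UM = 270.0
#: analysis-field area, mm² (0.36 mm × 0.27 mm)
FIELD_AREA_MM2 = FIELD_WIDTH_UM * FIELD_HEIGHT_UM / 1e6

_EPS = 1e-9


@dataclass(frozen=True)
class Field:
    """A rectangular analysis field with half-open extent [x0, x0+w) × [y0, y0+h)."""

    x0_um: float
    y0_um: float
    width_um: float = FIELD_WIDTH_UM
    height_um: float = FIELD_HEIGHT_UM

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ConfigurationError("field dimensions must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0_um)
            & (x < self.x0_um + self.width_um)
            & (y >= self.y0_um)
            & (y < self.y0_um + self.height_um)
        )

    def overlaps(self, other: "Field") -> bool:
        return (
            self.x0_um < other.x0_um + other.width_um
            and other.x0_um < self.x0_um + self.width_um
            and self.y0_um < other.y0_um + other.height_um
            and other.y0_um < self.y0_um + self.height_um
        )


@dataclass
class FieldMetrics:
    """Per-field marker counts and %GzmB for one matched field pair."""

    field: Field
    ccr8_treg_count: int
    foxp3_count: int
    cd8_count: int
    gzmb_cd8_count: int
    pct_gzmb_in_cd8: float  # NaN when cd8_count == 0
    spot_class: str | None = None  # "HOT" / "COLD"


@dataclass
class PatientSummary:
    """Per-patient representative values: WTA metrics plus Hot/Cold-Spot means.

    Hot-Spot means are the patient's representative ROI values; ratios are
    built from them. A ratio is NaN when its denominator mean is zero (the
    patient is then excluded from ratio-based grouping, not from the cohort).
    """

    patient_id: str
    wta: WtaMetrics | None
    n_hot: int
    n_cold: int
    hot_mean_ccr8_treg: float
    hot_mean_foxp3: float
    hot_mean_cd8: float
    hot_mean_gzmb_cd8: float
    hot_mean_pct_gzmb: float
    cold_mean_ccr8_treg: float = math.nan
    cold_mean_foxp3: float = math.nan
    cold_mean_cd8: float = math.nan
    cold_mean_gzmb_cd8: float = math.nan
    cold_mean_pct_gzmb: float = math.nan
    gzmb_ccr8_ratio: float = math.nan
    cd8_foxp3_ratio: float = math.nan
    gzmb_foxp3_ratio: float = math.nan
    cd8_ccr8_ratio: float = math.nan


@dataclass
class RoiParams:
    """Tunable parameters of the ROI protocol (defaults follow the method)."""

    field_width_um: float = FIELD_WIDTH_UM
    field_height_um: float = FIELD_HEIGHT_UM
    stride_um: float = 90.0  # candidate-grid stride; ¼ field width
    k_hot: int = 5
    k_cold: int = 5
    min_lymph: int = 10
    allow_overlap: bool = False


MarkerPredicate = Sequence[str] | Callable[[pd.DataFrame], np.ndarray]


def _predicate_coords(table: PanelTable, predicate: MarkerPredicate) -> np.ndarray:
    if callable(predicate):
        mask = np.asarray(predicate(table.cells), dtype=bool)
        return table.coords()[mask]
    return table.positive(*predicate)[["x_um", "y_um"]].to_numpy(dtype=float)


def _grid_origins(lo: float, hi: float, extent: float, stride: float) -> np.ndarray:
    if stride <= 0:
        raise ConfigurationError("stride must be positive")
    if extent > hi - lo + _EPS:
        raise ConfigurationError("analysis field larger than the slide bounding box")
    n = int(math.floor((hi - lo - extent) / stride + _EPS)) + 1
    return lo + stride * np.arange(n)


def density_map(
    table: PanelTable,
    marker_predicate: MarkerPredicate,
    field_w: float = FIELD_WIDTH_UM,
    field_h: float = FIELD_HEIGHT_UM,
    stride_um: float = 90.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Box-count density map over a stride grid of candidate fields.

    Counts cells satisfying ``marker_predicate`` (a list of marker names that
    must all be positive, or a callable row-mask) inside every candidate
    field; no kernel smoothing. Returns a DataFrame with columns
    ``x0_um, y0_um, count`` sorted by (y0, x0).
    """
    if bounds is None:
        if len(table) == 0:
            raise ConfigurationError("empty table and no bounds: frame box unknown")
        xy = table.coords()
        bounds = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    xmin, ymin, xmax, ymax = bounds
    xs = _grid_origins(xmin, xmax, field_w, stride_um)
    ys = _grid_origins(ymin, ymax, field_h, stride_um)
    pts = _predicate_coords(table, marker_predicate)
    if len(pts) == 0:
        counts = np.zeros((len(xs), len(ys)), dtype=int)
    else:
        in_x = (pts[:, [0]] >= xs) & (pts[:, [0]] < xs + field_w)  # (n, nx)
        in_y = (pts[:, [1]] >= ys) & (pts[:, [1]] < ys + field_h)  # (n, ny)
        counts = np.rint(in_x.astype(np.float64).T @ in_y.astype(np.float64)).astype(int)
    gx, gy = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), indexing="ij")
    out = pd.DataFrame(
        {"x0_um": xs[gx.ravel()], "y0_um": ys[gy.ravel()], "count": counts.ravel()}
    )
    out = out.sort_values(["y0_um", "x0_um"], kind="mergesort").reset_index(drop=True)
    out.attrs["field_w"] = field_w
    out.attrs["field_h"] = field_h
    return out


def _greedy_select(
    dmap: pd.DataFrame,
    order: np.ndarray,
    k: int,
    field_w: float,
    field_h: float,
    allow_overlap: bool,
    label: str,
) -> list[Field]:
    x0 = dmap["x0_um"].to_numpy(dtype=float)
    y0 = dmap["y0_um"].to_numpy(dtype=float)
    selected: list[Field] = []
    for i in order:
        cand = Field(x0[i], y0[i], field_w, field_h)
        if allow_overlap or not any(cand.overlaps(s) for s in selected):
            selected.append(cand)
            if len(selected) == k:
                break
    if len(selected) < k:
        logger.warning("%s selection exhausted: %d of %d fields", label, len(selected), k)
    return selected


def select_hot_spots(
    dmap: pd.DataFrame,
    k: int = 5,
    allow_overlap: bool = False,
) -> list[Field]:
    """Select the top-k fields by count, greedily enforcing non-overlap.

    Intended for a CCR8⁺Foxp3⁺ density map (Hot Spots = highest CCR8⁺ Treg
    infiltration). Ties break by (count desc, y0 asc, x0 asc); the result is
    independent of candidate enumeration order. Returns fewer than ``k``
    fields (with a warning) when candidates are exhausted.
    """
    if len(dmap) == 0:
        logger.warning("hot-spot selection: empty candidate set")
        return []
    order = np.lexsort(
        (dmap["x0_um"].to_numpy(), dmap["y0_um"].to_numpy(), -dmap["count"].to_numpy())
    )
    return _greedy_select(
        dmap, order, k, dmap.attrs.get("field_w", FIELD_WIDTH_UM),
        dmap.attrs.get("field_h", FIELD_HEIGHT_UM), allow_overlap, "hot-spot",
    )


def select_cold_spots(
    map_ccr8_treg: pd.DataFrame,
    map_cd8: pd.DataFrame,
    map_foxp3: pd.DataFrame,
    k: int = 5,
    min_lymph: int = 10,
    allow_overlap: bool = False,
    exclude: list[Field] | None = None,
) -> list[Field]:
    """Select the k lowest CCR8⁺Treg-count fields that contain lymphocytes.

    A field is *ineligible* only when both stains are sparse: CD8⁺ count <
    ``min_lymph`` AND Foxp3⁺ count < ``min_lymph`` (i.e. an area with no
    lymphocytes). Candidates overlapping any field in ``exclude`` (typically
    the slide's Hot Spots, which are distinct areas of the same case) are
    also dropped. Among eligible fields, selection is greedy non-overlapping,
    ties by (count asc, y0 asc, x0 asc).
    """
    key = ["y0_um", "x0_um"]
    a = map_ccr8_treg.sort_values(key, kind="mergesort").reset_index(drop=True)
    b = map_cd8.sort_values(key, kind="mergesort").reset_index(drop=True)
    c = map_foxp3.sort_values(key, kind="mergesort").reset_index(drop=True)
    if not (
        len(a) == len(b) == len(c)
        and np.allclose(a[["x0_um", "y0_um"]], b[["x0_um", "y0_um"]])
        and np.allclose(a[["x0_um", "y0_um"]], c[["x0_um", "y0_um"]])
    ):
        raise ConfigurationError("cold-spot maps must share one candidate grid")
    sparse_both = (b["count"].to_numpy() < min_lymph) & (c["count"].to_numpy() < min_lymph)
    keep = ~sparse_both
    if exclude:
        fw = a.attrs.get("field_w", FIELD_WIDTH_UM)
        fh = a.attrs.get("field_h", FIELD_HEIGHT_UM)
        x0 = a["x0_um"].to_numpy()
        y0 = a["y0_um"].to_numpy()
        for hot in exclude:
            keep &= ~(
                (x0 < hot.x0_um + hot.width_um) & (hot.x0_um < x0 + fw)
                & (y0 < hot.y0_um + hot.height_um) & (hot.y0_um < y0 + fh)
            )
    eligible = a.loc[keep].reset_index(drop=True)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "cold-spot selection: excluded %d lymphocyte-free or Hot-Spot-overlapping fields",
            n_excluded,
        )
    if len(eligible) == 0:
        logger.warning("cold-spot selection: no eligible fields")
        return []
    eligible.attrs = dict(a.attrs)
    order = np.lexsort(
        (eligible["x0_um"].to_numpy(), eligible["y0_um"].to_numpy(), eligible["count"].to_numpy())
    )
    return _greedy_select(
        eligible, order, k, a.attrs.get("field_w", FIELD_WIDTH_UM),
        a.attrs.get("field_h", FIELD_HEIGHT_UM), allow_overlap, "cold-spot",
    )


def field_metrics(
    fld: Field,
    panel_a: PanelTable,
    panel_b: PanelTable,
    spot_class: str | None = None,
) -> FieldMetrics:
    """Count both panels' markers inside one matched field."""
    if panel_a.frame != panel_b.frame:
        raise ConfigurationError("panel frames differ; co-register before field analysis")

    def count(table: PanelTable, *markers: str) -> int:
        pos = table.positive(*markers)
        if len(pos) == 0:
            return 0
        xy = pos[["x_um", "y_um"]].to_numpy(dtype=float)
        return int(fld.contains(xy[:, 0], xy[:, 1]).sum())

    cd8 = count(panel_b, "CD8")
    gzmb_cd8 = count(panel_b, "CD8", "GZMB")
    return FieldMetrics(
        field=fld,
        ccr8_treg_count=count(panel_a, "CCR8", "FOXP3"),
        foxp3_count=count(panel_a, "FOXP3"),
        cd8_count=cd8,
        gzmb_cd8_count=gzmb_cd8,
        pct_gzmb_in_cd8=pct_gzmb(cd8, gzmb_cd8),
        spot_class=spot_class,
    )


def _mean_metrics(fields: list[FieldMetrics]) -> dict[str, float]:
    if not fields:
        return {k: math.nan for k in ("ccr8_treg", "foxp3", "cd8", "gzmb_cd8", "pct_gzmb")}
    pcts = [f.pct_gzmb_in_cd8 for f in fields if not math.isnan(f.pct_gzmb_in_cd8)]
    if len(pcts) < len(fields):
        logger.info("%d field(s) with no CD8+ cells excluded from the %%GzmB mean",
                    len(fields) - len(pcts))
    return {
        "ccr8_treg": float(np.mean([f.ccr8_treg_count for f in fields])),
        "foxp3": float(np.mean([f.foxp3_count for f in fields])),
        "cd8": float(np.mean([f.cd8_count for f in fields])),
        "gzmb_cd8": float(np.mean([f.gzmb_cd8_count for f in fields])),
        "pct_gzmb": float(np.mean(pcts)) if pcts else math.nan,
    }


def _safe_ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return math.nan
    return num / den


def patient_roi_summary(
    patient_id: str,
    hot: list[FieldMetrics],
    cold: list[FieldMetrics],
    wta: WtaMetrics | None = None,
) -> PatientSummary:
    """Average field metrics into per-patient representative values.

    Hot-Spot means are unweighted over the selected fields; fields with an
    undefined %GzmB (no CD8⁺ cell) are dropped from the %GzmB mean only. The
    GzmB/CCR8 ratio is the Hot-Spot mean %GzmB divided by the Hot-Spot mean
    CCR8⁺ Treg count, NaN when the denominator is zero (such patients are
    flagged out of ratio groupings); the alternative ratios are analogous.
    """
    if not hot:
        raise ValueError(f"patient {patient_id}: no Hot-Spot fields selected")
    h = _mean_metrics(hot)
    c = _mean_metrics(cold)
    summary = PatientSummary(
        patient_id=patient_id,
        wta=wta,
        n_hot=len(hot),
        n_cold=len(cold),
        hot_mean_ccr8_treg=h["ccr8_treg"],
        hot_mean_foxp3=h["foxp3"],
        hot_mean_cd8=h["cd8"],
        hot_mean_gzmb_cd8=h["gzmb_cd8"],
        hot_mean_pct_gzmb=h["pct_gzmb"],
        cold_mean_ccr8_treg=c["ccr8_treg"],
        cold_mean_foxp3=c["foxp3"],
        cold_mean_cd8=c["cd8"],
        cold_mean_gzmb_cd8=c["gzmb_cd8"],
        cold_mean_pct_gzmb=c["pct_gzmb"],
        gzmb_ccr8_ratio=_safe_ratio(h["pct_gzmb"], h["ccr8_treg"]),
        cd8_foxp3_ratio=_safe_ratio(h["cd8"], h["foxp3"]),
        gzmb_foxp3_ratio=_safe_ratio(h["pct_gzmb"], h["foxp3"]),
        cd8_ccr8_ratio=_safe_ratio(h["cd8"], h["ccr8_treg"]),
    )
    if math.isnan(summary.gzmb_ccr8_ratio):
        logger.warning("patient %s: GzmB/CCR8 ratio undefined", patient_id)
    return summary


def analyze_patient(
    patient_id: str,
    panel_a: PanelTable,
    panel_b: PanelTable,
    mask: TumorMask,
    params: RoiParams | None = None,
) -> tuple[PatientSummary, pd.DataFrame]:
    """Run WTA + full ROI protocol for one patient.

    Filters both panels to the tumor mask, computes WTA densities, builds the
    CCR8⁺Foxp3⁺ / Foxp3⁺ / CD8⁺ density maps on one shared candidate grid,
    selects Hot and Cold Spots, quantifies the matched fields, and returns the
    patient summary plus a tidy per-field metrics table.
    """
    from tilspot.io import filter_to_tumor  # local import to avoid cycle at module load

    params = params or RoiParams()
    if panel_a.panel is not Panel.A_CCR8_FOXP3 or panel_b.panel is not Panel.B_CD8_GZMB:
        raise ConfigurationError("analyze_patient expects (CCR8/Foxp3 panel, CD8/GzmB panel)")
    pa = filter_to_tumor(panel_a, mask)
    pb = filter_to_tumor(panel_b, mask)
    wta = wta_metrics(pa, pb, mask)
    kw = dict(
        field_w=params.field_width_um,
        field_h=params.field_height_um,
        stride_um=params.stride_um,
        bounds=mask.bounds,
    )
    map_treg = density_map(pa, ("CCR8", "FOXP3"), **kw)
    map_foxp3 = density_map(pa, ("FOXP3",), **kw)
    map_cd8 = density_map(pb, ("CD8",), **kw)
    hot_fields = select_hot_spots(map_treg, k=params.k_hot, allow_overlap=params.allow_overlap)
    cold_fields = select_cold_spots(
        map_treg, map_cd8, map_foxp3,
        k=params.k_cold, min_lymph=params.min_lymph, allow_overlap=params.allow_overlap,
        exclude=hot_fields,
    )
    hot = [field_metrics(f, pa, pb, "HOT") for f in hot_fields]
    cold = [field_metrics(f, pa, pb, "COLD") for f in cold_fields]
    summary = patient_roi_summary(patient_id, hot, cold, wta)
    rows = [
        {
            "patient_id": patient_id,
            "spot_class": m.spot_class,
            "x0_um": m.field.x0_um,
            "y0_um": m.field.y0_um,
            "ccr8_treg_count": m.ccr8_treg_count,
            "foxp3_count": m.foxp3_count,
            "cd8_count": m.cd8_count,
            "gzmb_cd8_count": m.gzmb_cd8_count,
            "pct_gzmb_in_cd8": m.pct_gzmb_in_cd8,
        }
        for m in hot + cold
    ]
    return summary, pd.DataFrame(rows)


def summaries_to_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    """Flatten patient summaries (WTA + ROI means + ratios) into a tidy table."""
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "n_hot": s.n_hot,
            "n_cold": s.n_cold,
            "hot_mean_ccr8_treg": s.hot_mean_ccr8_treg,
            "hot_mean_foxp3": s.hot_mean_foxp3,
            "hot_mean_cd8": s.hot_mean_cd8,
            "hot_mean_gzmb_cd8": s.hot_mean_gzmb_cd8,
            "hot_mean_pct_gzmb": s.hot_mean_pct_gzmb,
            "cold_mean_ccr8_treg": s.cold_mean_ccr8_treg,
            "cold_mean_foxp3": s.cold_mean_foxp3,
            "cold_mean_cd8": s.cold_mean_cd8,
            "cold_mean_gzmb_cd8": s.cold_mean_gzmb_cd8,
            "cold_mean_pct_gzmb": s.cold_mean_pct_gzmb,
            "gzmb_ccr8_ratio": s.gzmb_ccr8_ratio,
            "cd8_foxp3_ratio": s.cd8_foxp3_ratio,
            "gzmb_foxp3_ratio": s.gzmb_foxp3_ratio,
            "cd8_ccr8_ratio": s.cd8_ccr8_ratio,
        }
        if s.wta is not None:
            row.update(
                wta_ccr8_treg_per_mm2=s.wta.ccr8_treg_per_mm2,
                wta_foxp3_per_mm2=s.wta.foxp3_per_mm2,
                wta_cd8_per_mm2=s.wta.cd8_per_mm2,
                wta_gzmb_cd8_per_mm2=s.wta.gzmb_cd8_per_mm2,
                wta_pct_gzmb_in_cd8=s.wta.pct_gzmb_in_cd8,
                wta_area_mm2=s.wta.area_mm2,
            )
        rows.append(row)
    return pd.DataFrame(rows)
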