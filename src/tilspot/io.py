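"""Cell-object tables, tumor masks, and clinical tables: reading, writing, masking.

Cell tables are the per-cell exports of an automated IHC image-analysis system:
one row per detected cell with its centroid in physical micrometres (image
convention: origin top-left, y increasing downward) and boolean marker calls
for the slide's stain panel. Tumor masks are pathologist-drawn region
annotations, consumed as GeoJSON polygons in the same µm frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

logger = logging.getLogger(__name__)


class Panel(str, Enum):
    """Stain panel of a slide: which marker pair its cell records carry."""

    A_CCR8_FOXP3 = "A_CCR8_FOXP3"
    B_CD8_GZMB = "B_CD8_GZMB"


#: marker columns carried by each panel
PANEL_MARKERS: dict[Panel, tuple[str, ...]] = {
    Panel.A_CCR8_FOXP3: ("CCR8", "FOXP3"),
    Panel.B_CD8_GZMB: ("CD8", "GZMB"),
}

#: canonical non-marker columns of a cell table
BASE_COLUMNS = ("cell_id", "x_um", "y_um")


class FormatError(ValueError):
    """A file does not match the expected tabular/geometry dialect."""


class GeometryError(ValueError):
    """A mask polygon is invalid (e.g. self-intersecting)."""


@dataclass
class PanelTable:
    """Phenotype-marked 2-D cell centroids for one slide and one stain panel.

    ``cells`` holds one row per cell with columns ``cell_id``, ``x_um``,
    ``y_um`` and one boolean column per panel marker. ``frame`` tags the
    coordinate frame; a patient's two panels must share it before joint
    analysis (co-registration across serial sections is the caller's job).
    """

    slide_id: str
    patient_id: str
    panel: Panel
    cells: pd.DataFrame
    frame: str = "slide"

    def __post_init__(self) -> None:
        markers = PANEL_MARKERS[self.panel]
        missing = [c for c in BASE_COLUMNS + markers if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell table missing columns: {missing}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise FormatError("non-finite cell coordinates")

    @property
    def markers(self) -> tuple[str, ...]:
        return PANEL_MARKERS[self.panel]

    def __len__(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        """(n, 2) float array of centroids in µm."""
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    def positive(self, *markers: str) -> pd.DataFrame:
        """Rows positive for all given markers of this panel."""
        unknown = [m for m in markers if m not in self.markers]
        if unknown:
            raise ValueError(f"markers {unknown} not in panel {self.panel.value}")
        mask = np.ones(len(self.cells), dtype=bool)
        for m in markers:
            mask &= self.cells[m].to_numpy(dtype=bool)
        return self.cells.loc[mask]


@dataclass
class TumorMask:
    """Pathologist-annotated tumor region: one or more simple polygons in µm."""

    polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.polygons:
            if not p.is_valid:
                raise GeometryError(f"invalid (e.g. self-intersecting) polygon: {p.wkt[:80]}")
        if self.area_mm2 <= 0:
            raise GeometryError("tumor mask has non-positive area")

    @property
    def area_mm2(self) -> float:
        return sum(p.area for p in self.polygons) / 1e6

    @property
    def geometry(self) -> MultiPolygon:
        return MultiPolygon(self.polygons)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in µm over all polygons."""
        return self.geometry.bounds

    @classmethod
    def rectangle(cls, width_um: float, height_um: float) -> "TumorMask":
        if width_um <= 0 or height_um <= 0:
            raise GeometryError("rectangle mask needs positive dimensions")
        return cls([Polygon([(0, 0), (width_um, 0), (width_um, height_um), (0, height_um)])])


_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "+", "pos", "positive"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "-", "−", "neg", "negative", ""}


def _parse_bool_column(col: pd.Series, name: str) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    if pd.api.types.is_numeric_dtype(col):
        return col.fillna(0).astype(int).to_numpy() != 0
    out = np.empty(len(col), dtype=bool)
    for i, raw in enumerate(col.astype(str).str.strip().str.lower()):
        if raw in _TRUE_TOKENS:
            out[i] = True
        elif raw in _FALSE_TOKENS:
            out[i] = False
        else:
            raise FormatError(f"column {name!r}: cannot parse boolean value {raw!r}")
    return out


def read_cell_table(
    path: str | Path,
    panel: Panel,
    column_map: dict[str, str] | None = None,
    slide_id: str = "",
    patient_id: str = "",
    frame: str = "slide",
) -> PanelTable:
    """Read a per-cell CSV export into a :class:`PanelTable`.

    ``column_map`` maps canonical names (``cell_id``, ``x_um``, ``y_um`` and
    the panel's marker names) to the exporter's header names; identity by
    default. Boolean marker columns accept 0/1, true/false, +/−. Row order is
    preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    column_map = column_map or {}
    markers = PANEL_MARKERS[panel]
    cols: dict[str, pd.Series] = {}
    for canon in BASE_COLUMNS + markers:
        source = column_map.get(canon, canon)
        if source not in raw.columns:
            raise FormatError(f"{path.name}: missing mapped column {source!r} (for {canon!r})")
        cols[canon] = raw[source]
    df = pd.DataFrame(cols)
    if df.empty:
        logger.warning("%s: empty cell table (header only)", path.name)
    for axis in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        bad = coerced.isna() & df[axis].notna()
        if bad.any():
            # +2: 1-based line numbers and the header row
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"{path.name}: non-numeric coordinate in column {axis!r} at line {line}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise FormatError(f"{path.name}: missing coordinate in column {axis!r} at line {line}")
        df[axis] = coerced.astype(float)
    for m in markers:
        df[m] = _parse_bool_column(df[m], m)
    return PanelTable(slide_id=slide_id or path.stem, patient_id=patient_id,
                      panel=panel, cells=df.reset_index(drop=True), frame=frame)


def write_cell_table(table: PanelTable, path: str | Path) -> None:
    """Write a cell table to CSV in the same dialect :func:`read_cell_table` reads."""
    cols = list(BASE_COLUMNS) + list(table.markers)
    out = table.cells[cols].copy()
    for m in table.markers:
        out[m] = out[m].astype(int)
    out.to_csv(path, index=False)


def read_tumor_mask(path: str | Path) -> TumorMask:
    """Read a tumor mask from GeoJSON (Polygon/MultiPolygon features, µm)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    polys: list[Polygon] = []
    for g in geoms:
        if isinstance(g, Polygon):
            polys.append(g)
        elif isinstance(g, MultiPolygon):
            polys.extend(g.geoms)
        else:
            raise GeometryError(f"unsupported geometry type {g.geom_type}")
    return TumorMask(polys)


def write_tumor_mask(mask: TumorMask, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {}, "geometry": mapping(p)} for p in mask.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV: patient_id, pfs_months, event, covariate columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"patient_id", "pfs_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    df["event"] = _parse_bool_column(df["event"], "event")
    if (df["pfs_months"] <= 0).any() or not np.isfinite(df["pfs_months"]).all():
        raise FormatError("pfs_months must be finite and positive")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index=False)


def filter_to_tumor(table: PanelTable, mask: TumorMask) -> PanelTable:
    """Restrict a cell table to centroids inside the tumor mask.

    Boundary points count as inside (closed polygons), so the operation is a
    deterministic, idempotent restriction.
    """
    if len(table) == 0:
        return replace(table, cells=table.cells.copy())
    pts = shapely.points(table.coords())
    keep = np.zeros(len(table), dtype=bool)
    for poly in mask.polygons:
        keep |= shapely.covers(poly, pts)
    return replace(table, cells=table.cells.loc[keep].reset_index(drop=True))
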