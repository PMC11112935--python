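import pandas as pd
import pytest

from tilspot.io import Panel, PanelTable, TumorMask
from tilspot.roi import RoiParams
from tilspot.simulate import SimConfig, simulate_slide


def small_sim_config(**overrides) -> SimConfig:
    """Scaled-down study conditions for fast replicated tests: small slides,
    same spatial structure (clustered infiltration + background)."""
    params = dict(
        slide_width_um=2000.0,
        slide_height_um=1500.0,
        n_clusters=8.0,
        cluster_sd_um=90.0,
        cells_per_cluster=40.0,
        background_intensity=10.0,
        seed=0,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture
def sim_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture
def slide(sim_config):
    return simulate_slide(sim_config, patient_seed=123, patient_id="P001")


@pytest.fixture
def roi_params() -> RoiParams:
    return RoiParams()


def make_panel(panel: Panel, rows: list[dict], patient_id: str = "P001") -> PanelTable:
    """Build a small panel table from dicts; missing markers default to False."""
    from tilspot.io import PANEL_MARKERS

    records = []
    for i, r in enumerate(rows):
        rec = {"cell_id": r.get("cell_id", f"c{i}"), "x_um": r["x"], "y_um": r["y"]}
        for m in PANEL_MARKERS[panel]:
            rec[m] = bool(r.get(m, False))
        records.append(rec)
    cols = ["cell_id", "x_um", "y_um", *PANEL_MARKERS[panel]]
    df = pd.DataFrame(records, columns=cols)
    if df.empty:
        df = df.astype({"x_um": float, "y_um": float})
    return PanelTable(slide_id="S1", patient_id=patient_id, panel=panel, cells=df)


def rect_mask(w: float = 2000.0, h: float = 1500.0) -> TumorMask:
    return TumorMask.rectangle(w, h)
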