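"""ROI protocol: density maps, Hot/Cold-Spot selection vs exhaustive oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from tilspot.io import Panel
from tilspot.roi import (
    Field,
    RoiParams,
    analyze_patient,
    density_map,
    field_metrics,
    patient_roi_summary,
    select_cold_spots,
    select_hot_spots,
)
from tilspot.simulate import simulate_slide
from tilspot.wta import ConfigurationError

from conftest import make_panel, small_sim_config


# ---------- oracles (independent reimplementations) ----------


def brute_force_map(pts, bounds, fw, fh, stride):
    """Direct per-field recount over the candidate grid."""
    xmin, ymin, xmax, ymax = bounds
    rows = []
    y0 = ymin
    while y0 + fh <= ymax + 1e-9:
        x0 = xmin
        while x0 + fw <= xmax + 1e-9:
            n = sum(
                1
                for (x, y) in pts
                if x0 <= x < x0 + fw and y0 <= y < y0 + fh
            )
            rows.append((x0, y0, n))
            x0 += stride
        y0 += stride
    return rows


def oracle_greedy(cands, k, fw, fh, descending):
    """Exhaustive greedy selection by explicit stable sort + pairwise overlap."""
    def overlaps(a, b):
        return a[0] < b[0] + fw and b[0] < a[0] + fw and a[1] < b[1] + fh and b[1] < a[1] + fh

    key = (lambda c: (-c[2], c[1], c[0])) if descending else (lambda c: (c[2], c[1], c[0]))
    chosen = []
    for c in sorted(cands, key=key):
        if not any(overlaps(c, s) for s in chosen):
            chosen.append(c)
            if len(chosen) == k:
                break
    return [(c[0], c[1]) for c in chosen]


# ---------- density maps ----------


def test_empty_table_gives_all_zero_map():
    table = make_panel(Panel.A_CCR8_FOXP3, [])
    m = density_map(table, ("CCR8", "FOXP3"), bounds=(0, 0, 1000, 800))
    assert len(m) > 0
    assert (m["count"] == 0).all()


def test_half_open_boundary_convention():
    table = make_panel(Panel.A_CCR8_FOXP3, [{"x": 10, "y": 10, "CCR8": True, "FOXP3": True}])
    m = density_map(table, ("CCR8", "FOXP3"), stride_um=360, bounds=(0, 0, 720, 270))
    by_origin = m.set_index(["x0_um", "y0_um"])["count"]
    assert by_origin.loc[(0, 0)] == 1
    assert by_origin.loc[(360, 0)] == 0


def test_cell_on_field_edge_belongs_to_right_field():
    table = make_panel(Panel.A_CCR8_FOXP3, [{"x": 360, "y": 0, "CCR8": True, "FOXP3": True}])
    m = density_map(table, ("CCR8", "FOXP3"), stride_um=360, bounds=(0, 0, 720, 270))
    by_origin = m.set_index(["x0_um", "y0_um"])["count"]
    assert by_origin.loc[(0, 0)] == 0  # [0, 360) excludes x=360
    assert by_origin.loc[(360, 0)] == 1


@pytest.mark.parametrize("stride", [90.0, 100.0, 137.0])
def test_density_map_equals_brute_force_recount(stride):
    rng = np.random.default_rng(int(stride))
    pts = rng.uniform((0, 0), (2000, 1500), size=(400, 2))
    rows = [{"x": x, "y": y, "FOXP3": True} for x, y in pts]
    table = make_panel(Panel.A_CCR8_FOXP3, rows)
    m = density_map(table, ("FOXP3",), stride_um=stride, bounds=(0, 0, 2000, 1500))
    expect = brute_force_map(pts, (0, 0, 2000, 1500), 360, 270, stride)
    got = sorted(zip(m.x0_um, m.y0_um, m["count"]))
    assert got == sorted(expect)


def test_field_larger_than_slide_is_configuration_error():
    table = make_panel(Panel.A_CCR8_FOXP3, [{"x": 1, "y": 1}])
    with pytest.raises(ConfigurationError):
        density_map(table, ("FOXP3",), bounds=(0, 0, 300, 200))


# ---------- hot spots ----------


def test_single_cluster_dominates_first_hot_spot():
    rows = [
        {"x": 500 + 10 * i, "y": 400 + 5 * i, "CCR8": True, "FOXP3": True}
        for i in range(20)
    ]
    table = make_panel(Panel.A_CCR8_FOXP3, rows)
    m = density_map(table, ("CCR8", "FOXP3"), bounds=(0, 0, 2000, 1500))
    hot = select_hot_spots(m, k=5)
    counts = [
        int(table.cells.loc[f.contains(table.cells.x_um, table.cells.y_um)].shape[0])
        for f in hot
    ]
    assert counts[0] == 20
    assert all(c == 0 for c in counts[1:])


def test_uniform_zero_map_selects_by_tie_break():
    table = make_panel(Panel.A_CCR8_FOXP3, [])
    m = density_map(table, ("CCR8", "FOXP3"), stride_um=90, bounds=(0, 0, 1440, 1080))
    hot = select_hot_spots(m, k=5)
    # ties resolve by (count desc, y0 asc, x0 asc) with non-overlap
    assert [(f.x0_um, f.y0_um) for f in hot] == [
        (0, 0), (360, 0), (720, 0), (1080, 0), (0, 270),
    ]


def test_hot_selection_invariant_to_candidate_order():
    s = simulate_slide(small_sim_config(seed=3), patient_seed=11)
    m = density_map(s.panel_a, ("CCR8", "FOXP3"), bounds=s.mask.bounds)
    shuffled = m.sample(frac=1.0, random_state=0).reset_index(drop=True)
    shuffled.attrs = dict(m.attrs)
    assert select_hot_spots(m, k=5) == select_hot_spots(shuffled, k=5)


@pytest.mark.parametrize("seed", range(25))
def test_hot_and_cold_selection_match_exhaustive_oracle(seed):
    s = simulate_slide(small_sim_config(seed=seed), patient_seed=seed)
    params = RoiParams()
    bounds = s.mask.bounds
    m_treg = density_map(s.panel_a, ("CCR8", "FOXP3"), bounds=bounds)
    m_fox = density_map(s.panel_a, ("FOXP3",), bounds=bounds)
    m_cd8 = density_map(s.panel_b, ("CD8",), bounds=bounds)
    hot = select_hot_spots(m_treg, k=5)
    cands = list(zip(m_treg.x0_um, m_treg.y0_um, m_treg["count"]))
    assert [(f.x0_um, f.y0_um) for f in hot] == oracle_greedy(cands, 5, 360, 270, True)
    cold = select_cold_spots(m_treg, m_cd8, m_fox, k=5, min_lymph=10)
    merged = m_treg.merge(m_cd8, on=["x0_um", "y0_um"], suffixes=("", "_cd8")).merge(
        m_fox, on=["x0_um", "y0_um"], suffixes=("", "_fox")
    )
    eligible = merged[~((merged.count_cd8 < 10) & (merged.count_fox < 10))]
    ecands = list(zip(eligible.x0_um, eligible.y0_um, eligible["count"]))
    assert [(f.x0_um, f.y0_um) for f in cold] == oracle_greedy(ecands, 5, 360, 270, False)


# ---------- cold spots ----------


def _const_map(entries):
    df = pd.DataFrame(entries, columns=["x0_um", "y0_um", "count"])
    df.attrs["field_w"] = 360.0
    df.attrs["field_h"] = 270.0
    return df


def test_cold_spot_eligibility_rule():
    grid = [(0, 0), (360, 0), (720, 0)]
    treg = _const_map([(x, y, c) for (x, y), c in zip(grid, [0, 0, 5])])
    cd8 = _const_map([(x, y, c) for (x, y), c in zip(grid, [3, 12, 40])])
    fox = _const_map([(x, y, c) for (x, y), c in zip(grid, [2, 0, 20])])
    cold = select_cold_spots(treg, cd8, fox, k=5, min_lymph=10)
    origins = [(f.x0_um, f.y0_um) for f in cold]
    # (0,0): cd8=3<10 AND fox=2<10 -> excluded (lymphocyte-free)
    # (360,0): cd8=12 clears the threshold -> eligible, treg=0 -> ranked first
    assert origins == [(360, 0), (720, 0)]


def test_hot_cold_separation_invariant():
    """With enough candidates, min Hot-Spot treg count >= max Cold-Spot treg count."""
    for seed in range(5):
        s = simulate_slide(small_sim_config(seed=100 + seed), patient_seed=seed)
        _, fields = analyze_patient("P", s.panel_a, s.panel_b, s.mask)
        hot = fields[fields.spot_class == "HOT"]
        cold = fields[fields.spot_class == "COLD"]
        if len(hot) == 5 and len(cold) == 5:
            assert hot.ccr8_treg_count.min() >= cold.ccr8_treg_count.max()


# ---------- field metrics and patient summary ----------


def test_empty_field_metrics():
    pa = make_panel(Panel.A_CCR8_FOXP3, [])
    pb = make_panel(Panel.B_CD8_GZMB, [])
    fm = field_metrics(Field(0, 0), pa, pb)
    assert fm.ccr8_treg_count == fm.cd8_count == 0
    assert math.isnan(fm.pct_gzmb_in_cd8)


def test_zero_gzmb_is_zero_pct_not_undefined():
    pb = make_panel(Panel.B_CD8_GZMB, [{"x": 10 + i, "y": 10, "CD8": True} for i in range(20)])
    pa = make_panel(Panel.A_CCR8_FOXP3, [])
    fm = field_metrics(Field(0, 0), pa, pb)
    assert fm.cd8_count == 20
    assert fm.pct_gzmb_in_cd8 == 0.0


def test_field_metrics_match_recount(slide):
    fld = Field(360, 270)
    fm = field_metrics(fld, slide.panel_a, slide.panel_b)
    a, b = slide.panel_a.cells, slide.panel_b.cells
    in_a = fld.contains(a.x_um, a.y_um)
    in_b = fld.contains(b.x_um, b.y_um)
    assert fm.ccr8_treg_count == int((a.CCR8 & a.FOXP3 & in_a).sum())
    assert fm.foxp3_count == int((a.FOXP3 & in_a).sum())
    assert fm.cd8_count == int((b.CD8 & in_b).sum())
    assert fm.gzmb_cd8_count == int((b.CD8 & b.GZMB & in_b).sum())


def test_patient_summary_means_and_ratio():
    from tilspot.roi import FieldMetrics

    hot = [
        FieldMetrics(Field(0, 0), ccr8_treg_count=15, foxp3_count=20, cd8_count=50,
                     gzmb_cd8_count=15, pct_gzmb_in_cd8=30.0, spot_class="HOT")
        for _ in range(5)
    ]
    s = patient_roi_summary("P1", hot, [], wta=None)
    assert s.hot_mean_ccr8_treg == 15
    assert s.hot_mean_pct_gzmb == 30.0
    assert s.gzmb_ccr8_ratio == pytest.approx(2.0)
    assert s.cd8_ccr8_ratio == pytest.approx(50 / 15)
    assert s.cd8_foxp3_ratio == pytest.approx(2.5)


def test_undefined_pct_fields_excluded_from_mean():
    from tilspot.roi import FieldMetrics

    hot = [
        FieldMetrics(Field(0, 0), 5, 5, 10, 5, 50.0, "HOT"),
        FieldMetrics(Field(360, 0), 5, 5, 0, 0, math.nan, "HOT"),
    ]
    s = patient_roi_summary("P1", hot, [])
    assert s.hot_mean_pct_gzmb == 50.0  # undefined field dropped from pct mean only
    assert s.hot_mean_cd8 == 5.0  # but kept in the count means


def test_zero_hot_fields_is_patient_level_error():
    with pytest.raises(ValueError):
        patient_roi_summary("P1", [], [])


def test_zero_denominator_ratio_is_undefined():
    from tilspot.roi import FieldMetrics

    hot = [FieldMetrics(Field(0, 0), 0, 0, 10, 2, 20.0, "HOT")]
    s = patient_roi_summary("P1", hot, [])
    assert math.isnan(s.gzmb_ccr8_ratio)
    assert math.isnan(s.cd8_foxp3_ratio)
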