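"""Whole-Tumor-Area (WTA) protocol: marker densities over the full tumor region.

Quantities per patient, all denominated by the pathologist-annotated tumor
area in mm²:

* ``CCR8⁺ Treg`` — CCR8⁺Foxp3⁺ double-positive cells per mm² (CCR8⁺ Tregs are
  counted strictly as double positives; Foxp3⁺CCR8⁻ cells contribute to the
  total-Treg density only, CCR8⁺Foxp3⁻ cells to neither).
* ``Total CD8⁺ T`` — CD8⁺ cells per mm².
* ``GzmB⁺ CD8⁺ T`` — GzmB⁺CD8⁺ double positives per mm² (GzmB⁺CD8⁻ records
  are ignored by every CD8-denominated metric).
* ``%GzmB⁺ in CD8⁺ T`` — 100 × GzmB⁺CD8⁺ / CD8⁺, undefined when no CD8⁺ cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from tilspot.io import Panel, PanelTable, TumorMask


class ConfigurationError(ValueError):
    pass


@dataclass
class WtaMetrics:
    """Whole-tumor densities (cells/mm²) and %GzmB for one patient."""

    ccr8_treg_per_mm2: float
    foxp3_per_mm2: float
    cd8_per_mm2: float
    gzmb_cd8_per_mm2: float
    pct_gzmb_in_cd8: float  # NaN when CD8 count is zero
    area_mm2: float

    @property
    def pct_gzmb_defined(self) -> bool:
        return not math.isnan(self.pct_gzmb_in_cd8)


def pct_gzmb(cd8_count: int, gzmb_cd8_count: int) -> float:
    """%GzmB⁺ among CD8⁺ cells; NaN when the denominator is zero."""
    if gzmb_cd8_count > cd8_count:
        raise ValueError("GzmB+CD8+ count exceeds CD8+ count")
    if cd8_count == 0:
        return math.nan
    return 100.0 * gzmb_cd8_count / cd8_count


def wta_metrics(panel_a: PanelTable, panel_b: PanelTable, mask: TumorMask) -> WtaMetrics:
    """Compute whole-tumor-area metrics from tumor-restricted panel tables.

    Both panels must already be filtered to the tumor mask and share one
    coordinate frame.
    """
    if panel_a.panel is not Panel.A_CCR8_FOXP3 or panel_b.panel is not Panel.B_CD8_GZMB:
        raise ConfigurationError("wta_metrics expects (CCR8/Foxp3 panel, CD8/GzmB panel)")
    if panel_a.frame != panel_b.frame:
        raise ConfigurationError("panel frames differ; co-register before analysis")
    area = mask.area_mm2
    if area <= 0:
        raise ConfigurationError("zero-area tumor mask")
    n_ccr8_treg = len(panel_a.positive("CCR8", "FOXP3"))
    n_foxp3 = len(panel_a.positive("FOXP3"))
    n_cd8 = len(panel_b.positive("CD8"))
    n_gzmb_cd8 = len(panel_b.positive("CD8", "GZMB"))
    return WtaMetrics(
        ccr8_treg_per_mm2=n_ccr8_treg / area,
        foxp3_per_mm2=n_foxp3 / area,
        cd8_per_mm2=n_cd8 / area,
        gzmb_cd8_per_mm2=n_gzmb_cd8 / area,
        pct_gzmb_in_cd8=pct_gzmb(n_cd8, n_gzmb_cd8),
        area_mm2=area,
    )
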