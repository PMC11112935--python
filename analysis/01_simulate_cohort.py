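#!/usr/bin/env python
"""Simulate the 81-patient synthetic cohort and write its input files.

Writes the per-patient cell tables and tumor masks (large, regenerable) to
scratch/cohort/ and the clinical table to results/cohort/. Downstream
analysis scripts (02-05) consume these files exactly as they would consume
an external image-analysis export.
"""

from pathlib import Path

from tilspot.pipeline import write_cohort_inputs
from tilspot.simulate import SimConfig, simulate_cohort

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimConfig(seed=SEED)
    print(f"simulating {cfg.n_patients} patients (seed {SEED}) ...")
    cohort = simulate_cohort(cfg)
    out = write_cohort_inputs(cohort, ROOT / "scratch" / "cohort")
    results = ROOT / "results" / "cohort"
    results.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(results / "clinical.csv", index=False)
    n_cells = sum(len(s.panel_a) + len(s.panel_b) for s in cohort.slides)
    print(f"wrote {len(cohort.slides)} slide pairs ({n_cells} cells) to {out}")
    print(f"events: {int(cohort.clinical.event.sum())}/{len(cohort.clinical)}")


if __name__ == "__main__":
    main()
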