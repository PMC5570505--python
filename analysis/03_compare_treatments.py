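#!/usr/bin/env python
"""Treated vs untreated ratios for every kinetics metric.

Reproduces the ratio-style readout of the study design on the simulated
conditions: each damage regime is compared to the untreated control by the
ratio of dataset means with Welch t-tests on per-fiber values (per-sample
for fork rate).  Expected qualitative signatures: the frequent-mild-lesion
regime slows forks and multiplies stalls; the rare-severe regimes leave
fork rate untouched but cut origin firing (checkpoint emulation) and raise
the per-fork stall rate.

Run after 01:  python analysis/03_compare_treatments.py
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from forkcomb.fiber_io import DatasetMeta, read_fiber_table
from forkcomb.pipeline import comparison_frame, run_analysis, run_comparison

SCRATCH = Path("scratch/datasets")
RESULTS = Path("results")
TREATMENTS = ("mms", "nqo", "bleo")
SHOW = ("origin_rate_total", "fork_density_p1", "fork_density_p2", "fork_rate", "stalls_per_kb", "stall_rate")


def main() -> None:
    untreated = run_analysis(
        read_fiber_table(SCRATCH / "untreated.tsv", DatasetMeta()), dataset_id="untreated"
    )
    frames = []
    for name in TREATMENTS:
        treated = run_analysis(
            read_fiber_table(SCRATCH / f"{name}.tsv", DatasetMeta()), dataset_id=name
        )
        frame = comparison_frame(run_comparison(treated, untreated))
        frame.insert(0, "treatment", name)
        frames.append(frame)
        shown = frame.set_index("metric").loc[list(SHOW)]
        print(f"\n{name} / untreated:")
        for metric, row in shown.iterrows():
            star = " *" if row["p_value"] < 0.01 else ""
            print(f"  {metric:18s} ratio {row['ratio']:5.2f}  (p={row['p_value']:.2e}){star}")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(RESULTS / "treatment_ratios.tsv", sep="\t", index=False)
    print(f"\nfull ratio table -> {RESULTS}/treatment_ratios.tsv")


if __name__ == "__main__":
    main()
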