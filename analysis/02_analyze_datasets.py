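#!/usr/bin/env python
"""Analyze each simulated dataset into a replication-kinetics summary.

For every condition simulated by 01_simulate_datasets.py this estimates the
apparent stall rate, stall-corrected origin firing rate, per-pulse fork
densities, Gaussian-fit fork rate and per-fiber stall metrics, and checks
the untreated estimates against the simulator's ground truth.

Run after 01:  python analysis/02_analyze_datasets.py
"""

from __future__ import annotations

import json
from pathlib import Path

from forkcomb.fiber_io import DatasetMeta, read_fiber_table
from forkcomb.pipeline import run_analysis

SCRATCH = Path("scratch/datasets")
RESULTS = Path("results")


def main() -> None:
    truth = json.loads((RESULTS / "simulated_ground_truth.json").read_text())
    for path in sorted(SCRATCH.glob("*.tsv")):
        name = path.stem
        fibers = read_fiber_table(path, DatasetMeta())
        summary = run_analysis(fibers, mode="probabilistic", dataset_id=name)
        (RESULTS / f"summary_{name}.json").write_text(summary.to_json() + "\n")
        summary.to_frame().to_csv(RESULTS / f"summary_{name}.tsv", sep="\t", index=False)
        o = summary.metrics["origin_rate_total"]["mean"] * 1e3
        print(
            f"{name:10s} s_app={summary.s_apparent:.3f} | "
            f"origin rate {o:.2f} origins/Mb/min | "
            f"fork rate {summary.fork_rate_fit.mean:.3f} kb/min (fit, "
            f"{summary.fork_rate_fit.sample_mean:.3f} sample) | "
            f"stall rate {summary.metrics['stall_rate']['mean']:.3f}"
        )
        if name in truth:
            print(
                f"{'':10s} ground truth: detectable stall fraction "
                f"{truth[name]['detectable_stall_fraction']:.3f}"
            )
    print(f"\nsummaries -> {RESULTS}/summary_<condition>.json/.tsv")


if __name__ == "__main__":
    main()
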