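#!/usr/bin/env python
"""Simulate the four study conditions as dual-pulse combing datasets.

Generates ~25 Mb of labeled fibers per condition — untreated, plus the
three damage regimes (frequent mild alkylation lesions, rare severe bulky
adducts, rare strand breaks) — with full ground truth.  Fiber tables (large)
go to scratch/, ground-truth event summaries to results/.

Run from the repository root:  python analysis/01_simulate_datasets.py
"""

from __future__ import annotations

import json
from pathlib import Path

from forkcomb.fiber_io import write_fiber_table
from forkcomb.simulate import SimulationConfig, bleo_like, mms_like, nqo_like, simulate

SEED = 20240 + 1
SCRATCH = Path("scratch/datasets")
RESULTS = Path("results")

CONDITIONS = {
    "untreated": lambda base: base,
    "mms": mms_like,
    "nqo": nqo_like,
    "bleo": bleo_like,
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    truth_summary = {}
    for i, (name, preset) in enumerate(CONDITIONS.items()):
        cfg = preset(SimulationConfig(genome_mb=25.0, seed=SEED + i))
        fibers, truth = simulate(cfg, dataset_id=name)
        write_fiber_table(fibers, SCRATCH / f"{name}.tsv")
        truth_summary[name] = {
            "seed": cfg.seed,
            "lesion_density_per_kb": cfg.lesion_density_per_kb,
            "p_stall_per_lesion": cfg.p_stall_per_lesion,
            "pause_min_per_lesion": cfg.pause_min_per_lesion,
            "origin_rate_per_mb_min": cfg.origin_rate_per_mb_min,
            "n_fibers": len(fibers),
            "n_analyzable": sum(not f.excluded for f in fibers),
            "total_mb": round(sum(f.total_length_kb for f in fibers) / 1000, 2),
            "n_origins": len(truth.origins),
            "n_stalls": len(truth.stalls),
            "detectable_stalls": truth.detectable_stalls,
            "n_forks_p1": truth.n_forks_p1,
            "detectable_stall_fraction": round(truth.detectable_stall_fraction, 4),
            "replicated_fraction_at_harvest": round(truth.replicated_fraction_at_harvest, 3),
        }
        t = truth_summary[name]
        print(
            f"{name:10s} {t['total_mb']:6.1f} Mb in {t['n_fibers']:3d} fibers | "
            f"{t['n_origins']:4d} origins, {t['n_stalls']:4d} stalls "
            f"({t['detectable_stall_fraction']:.1%} of pulse-1 forks detectable)"
        )
    (RESULTS / "simulated_ground_truth.json").write_text(
        json.dumps(truth_summary, indent=2) + "\n"
    )
    print(f"\nfiber tables -> {SCRATCH}/, ground truth -> {RESULTS}/simulated_ground_truth.json")


if __name__ == "__main__":
    main()
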