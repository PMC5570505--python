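#!/usr/bin/env python
"""Lesion densities from intact-fragment fractions, and what forks meet.

Works through the Poisson inference that turns gel-quantified intact-band
fractions into lesion densities, the nick-spacing arithmetic for
strand-break agents, and the expected lesion encounters per fork during the
10-minute chase.  The intact fractions used here are synthetic
illustrations chosen to land on the three studied lesion regimes (one
lesion per ~1, ~25 and ~50 kb); real inputs would come from densitometry.

Run:  python analysis/04_lesion_density.py
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from forkcomb.lesions import (
    GelLaneQuant,
    lesions_encountered,
    nick_spacing_range,
    poisson_lesion_density,
)

RESULTS = Path("results")

# Synthetic intact fractions for 20-kb restriction fragments, chosen to
# reproduce the three lesion-density regimes under the Poisson model.
LANES = {
    "alkylation (frequent, mild)": GelLaneQuant(math.exp(-20.0), 20.0),
    "bulky adduct (rare, severe)": GelLaneQuant(math.exp(-0.8), 20.0),
    "strand break (rare)": GelLaneQuant(math.exp(-0.4), 20.0),
}

FORK_RATE = 0.91  # kb/min, untreated Gaussian-fit value
CHASE_MIN = 10.0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {}
    print("Poisson lesion densities from intact 20-kb fragment fractions:")
    for name, lane in LANES.items():
        lam = poisson_lesion_density(lane)
        enc = lesions_encountered(FORK_RATE, CHASE_MIN, lam)
        out[name] = {
            "intact_fraction": round(lane.intact_fraction, 6),
            "fragment_kb": lane.fragment_length_kb,
            "lesions_per_kb": round(lam, 4),
            "kb_per_lesion": round(1 / lam, 1),
            "lesions_per_fork_per_chase": round(enc, 2),
        }
        print(
            f"  {name:28s} intact={lane.intact_fraction:.3g} -> "
            f"{lam:.3f}/kb (one per {1/lam:.0f} kb); "
            f"a fork meets {enc:.2f} per chase"
        )

    lo, hi = nick_spacing_range(dsb_spacing_kb=50.0, excess_low=6.0, excess_high=20.0)
    out["nick_spacing_kb"] = {"min": round(lo, 2), "max": round(hi, 2)}
    print(
        f"\nStrand-break agent: one DSB per 50 kb with a 6-20x nick excess "
        f"puts one nick every {lo:.1f}-{hi:.1f} kb."
    )

    (RESULTS / "lesion_densities.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"\ntable -> {RESULTS}/lesion_densities.json")


if __name__ == "__main__":
    main()
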