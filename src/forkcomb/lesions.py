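"""Poisson inference of DNA lesion densities from gel quantifications.

Damage that nicks or breaks DNA fragments a restriction digest: if lesions
fall as a Poisson process with density ``lam`` per kb, a fragment of length
``L`` kb survives intact with probability ``exp(-lam * L)``.  Inverting the
observed intact fraction of a band therefore gives the lesion density, and
simple arithmetic turns it into nick spacings and expected per-fork lesion
encounters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Default fragment length (kb) for gel bands pooled at the exclusion volume.
DEFAULT_FRAGMENT_KB = 20.0


@dataclass(frozen=True)
class GelLaneQuant:
    """Quantified gel lane: surviving intact fraction at a fragment length."""

    intact_fraction: float
    fragment_length_kb: float = DEFAULT_FRAGMENT_KB

    def __post_init__(self) -> None:
        if not 0.0 < self.intact_fraction <= 1.0:
            raise ValueError(f"intact_fraction must be in (0, 1], got {self.intact_fraction}")
        if not self.fragment_length_kb > 0:
            raise ValueError(f"fragment_length_kb must be positive, got {self.fragment_length_kb}")


def poisson_lesion_density(q: GelLaneQuant) -> float:
    """Lesions per kb from the intact fraction of fragments of known length.

    lam = -ln(intact_fraction) / fragment_length_kb.
    """
    return -math.log(q.intact_fraction) / q.fragment_length_kb


def nick_spacing_range(
    dsb_spacing_kb: float, excess_low: float, excess_high: float
) -> tuple[float, float]:
    """Single-strand nick spacing implied by a nick:DSB excess range.

    Given one double-strand break every ``dsb_spacing_kb`` and a reported
    ``excess_low``- to ``excess_high``-fold excess of nicks over breaks,
    nicks fall every ``dsb_spacing_kb / excess`` kb; the larger excess gives
    the tighter spacing.
    """
    if not dsb_spacing_kb > 0:
        raise ValueError(f"dsb_spacing_kb must be positive, got {dsb_spacing_kb}")
    if not (excess_high >= excess_low > 0):
        raise ValueError(
            f"need excess_high >= excess_low > 0, got ({excess_low}, {excess_high})"
        )
    return dsb_spacing_kb / excess_high, dsb_spacing_kb / excess_low


def lesions_encountered(
    fork_rate_kb_min: float, duration_min: float, density_per_kb: float
) -> float:
    """Expected lesions a fork meets: speed x duration x lesion density."""
    if fork_rate_kb_min < 0 or duration_min < 0 or density_per_kb < 0:
        raise ValueError("all inputs must be non-negative")
    return fork_rate_kb_min * duration_min * density_per_kb
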