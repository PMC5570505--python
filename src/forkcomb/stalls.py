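"""Dataset apparent stall rate and per-fiber stall metrics.

The apparent stall rate ``s`` is estimated once per dataset from the
unambiguous junctions alone: every red/green (RUG or GUR) gap is a definite
stall, every green/green (GUG) gap a definite non-stall, and

    s = (RUG + GUR) / (RUG + GUR + GUG).

``s`` then serves as the per-fork stall probability when resolving the
ambiguous red/red and fiber-end patterns, giving each fiber an expected
stall count.  Two per-fiber normalizations are reported: stalls per kb of
unlabeled DNA (the contribution of stalling to total replication slowing)
and the stall rate, expected stalls divided by expected first-pulse forks
with stalled forks kept in the denominator (an origin with one stalled fork
has a 50% stall rate: one stalled out of the two forks there should be).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from forkcomb.fiber_io import Fiber
from forkcomb.patterns import JunctionClass, expected_event_counts, segment_fiber


class InsufficientJunctionsError(ValueError):
    """No informative junctions in the dataset."""


def junction_class_counts(
    fibers: list[Fiber], exclude_ends: bool = False, skip_excluded: bool = True
) -> dict[JunctionClass, int]:
    """Pooled junction-class counts across a dataset."""
    counts = {k: 0 for k in JunctionClass}
    for fiber in fibers:
        if skip_excluded and fiber.excluded:
            continue
        _, junctions = segment_fiber(fiber, exclude_ends=exclude_ends)
        for j in junctions:
            counts[j.klass] += 1
    return counts


def apparent_stall_rate(fibers: list[Fiber], exclude_ends: bool = False) -> float:
    """Dataset apparent stall rate from unambiguous junctions.

    Pools RUG/GUR (definite stall) and GUG (definite non-stall) gap counts
    over all analyzable fibers.  Raises
    :class:`InsufficientJunctionsError` when the dataset contains no
    informative junction at all.
    """
    counts = junction_class_counts(fibers, exclude_ends=exclude_ends)
    definite = counts[JunctionClass.DEFINITE_STALL]
    informative = definite + counts[JunctionClass.NO_STALL]
    if informative == 0:
        raise InsufficientJunctionsError(
            "no RUG/GUR/GUG junctions in the dataset; the apparent stall rate "
            "needs neighboring-fork context (collect more or longer fibers)"
        )
    return definite / informative


def stalls_per_kb(fiber: Fiber, s: float, exclude_ends: bool = False) -> float | None:
    """Expected stalls per kb of unlabeled DNA for one fiber.

    Returns None (with a warning) when the fiber carries no unlabeled DNA,
    in which case the metric is undefined and the fiber is skipped.
    """
    unrep = fiber.unreplicated_kb
    if unrep <= 0:
        warnings.warn(
            f"fiber {fiber.fiber_id!r} has no unlabeled DNA; stalls/kb undefined",
            stacklevel=2,
        )
        return None
    counts = expected_event_counts(fiber, s, mode="probabilistic", exclude_ends=exclude_ends)
    return counts.stalls / unrep


def stall_rate(fiber: Fiber, s: float, exclude_ends: bool = False) -> float | None:
    """Expected stalls over expected ongoing first-pulse forks for one fiber.

    Stalled forks count in the denominator.  Returns None (with a warning)
    when the fiber has no first-pulse forks.
    """
    counts = expected_event_counts(fiber, s, mode="probabilistic", exclude_ends=exclude_ends)
    if counts.forks_p1 <= 0:
        warnings.warn(
            f"fiber {fiber.fiber_id!r} has no first-pulse forks; stall rate undefined",
            stacklevel=2,
        )
        return None
    return counts.stalls / counts.forks_p1


@dataclass
class StallSummary:
    """Dataset-level stall estimates."""

    s_apparent: float
    n_definite_stalls: int
    n_gug: int
    n_ambiguous: int
    stalls_per_kb_values: np.ndarray = field(repr=False)
    stall_rate_values: np.ndarray = field(repr=False)
    expected_stalls_values: np.ndarray = field(repr=False)

    @property
    def mean_stalls_per_kb(self) -> float:
        return float(np.mean(self.stalls_per_kb_values)) if self.stalls_per_kb_values.size else math.nan

    @property
    def sd_stalls_per_kb(self) -> float:
        return float(np.std(self.stalls_per_kb_values, ddof=1)) if self.stalls_per_kb_values.size > 1 else 0.0

    @property
    def mean_stall_rate(self) -> float:
        return float(np.mean(self.stall_rate_values)) if self.stall_rate_values.size else math.nan

    @property
    def sd_stall_rate(self) -> float:
        return float(np.std(self.stall_rate_values, ddof=1)) if self.stall_rate_values.size > 1 else 0.0


def stall_summary(
    fibers: list[Fiber],
    s: float | None = None,
    exclude_ends: bool = False,
) -> StallSummary:
    """Per-fiber stall metrics pooled into a dataset summary.

    ``s`` defaults to the apparent stall rate estimated from this dataset.
    Fiber means are unweighted across fibers; fibers on which a metric is
    undefined are dropped from that metric only.
    """
    if s is None:
        s = apparent_stall_rate(fibers, exclude_ends=exclude_ends)
    counts = junction_class_counts(fibers, exclude_ends=exclude_ends)
    spk, rate, exp_stalls = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fiber in fibers:
            if fiber.excluded:
                continue
            c = expected_event_counts(fiber, s, mode="probabilistic", exclude_ends=exclude_ends)
            exp_stalls.append(c.stalls)
            if fiber.unreplicated_kb > 0:
                spk.append(c.stalls / fiber.unreplicated_kb)
            if c.forks_p1 > 0:
                rate.append(c.stalls / c.forks_p1)
    return StallSummary(
        s_apparent=s,
        n_definite_stalls=counts[JunctionClass.DEFINITE_STALL],
        n_gug=counts[JunctionClass.NO_STALL],
        n_ambiguous=counts[JunctionClass.AMBIGUOUS_RR],
        stalls_per_kb_values=np.asarray(spk, dtype=float),
        stall_rate_values=np.asarray(rate, dtype=float),
        expected_stalls_values=np.asarray(exp_stalls, dtype=float),
    )
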