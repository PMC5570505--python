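"""Pattern engine: junction classes, segmentation, interpretation weights."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fiber_from_pattern, oracle_expected_counts
from forkcomb.patterns import (
    Flank,
    JunctionClass,
    classify_junction,
    enumerate_interpretations,
    expected_event_counts,
    parse_segment,
    segment_fiber,
)


@pytest.mark.parametrize(
    "left,right,expected",
    [
        (Flank.GREEN, Flank.GREEN, JunctionClass.NO_STALL),
        (Flank.RED, Flank.GREEN, JunctionClass.DEFINITE_STALL),
        (Flank.GREEN, Flank.RED, JunctionClass.DEFINITE_STALL),
        (Flank.RED, Flank.RED, JunctionClass.AMBIGUOUS_RR),
        (Flank.FIBER_END, Flank.RED, JunctionClass.UNINFORMATIVE),
        (Flank.GREEN, Flank.FIBER_END, JunctionClass.UNINFORMATIVE),
        (Flank.FIBER_END, Flank.FIBER_END, JunctionClass.UNINFORMATIVE),
    ],
)
def test_junction_classification(left, right, expected):
    assert classify_junction(left, right) is expected


@pytest.mark.parametrize(
    "pattern,states,expected",
    [
        # (origins_p1, origins_p2, terms_p1, terms_p2, forks_p1, forks_p2, forks_total, stalls)
        ("G", (True, True), (0, 1, 0, 0, 0, 2, 2, 0)),  # second-pulse origin
        ("R", (False, False), (0, 0, 1, 0, 2, 0, 2, 0)),  # first-pulse termination
        ("R", (True, False), (0, 0, 0, 0, 1, 0, 1, 1)),  # stalled elongating fork
        ("R", (True, True), (1, 0, 0, 0, 2, 0, 2, 2)),  # origin, both forks stalled
        ("RG", (False, True), (0, 0, 0, 0, 1, 1, 1, 0)),  # rightward fork
        ("RG", (True, True), (1, 0, 0, 0, 2, 1, 2, 1)),  # origin, left fork stalled
        ("GR", (True, False), (0, 0, 0, 0, 1, 1, 1, 0)),  # leftward fork
        ("GRG", (True, True), (1, 0, 0, 0, 2, 2, 2, 0)),  # first-pulse origin
        ("RGR", (False, False), (0, 0, 0, 1, 2, 2, 2, 0)),  # second-pulse termination
        ("RGR", (True, False), (1, 0, 0, 1, 3, 2, 3, 1)),  # termination + stalled-side origin
        ("GRGRG", (True, True), (2, 0, 0, 1, 4, 4, 4, 0)),  # origin/termination chain
    ],
)
def test_segment_taxonomy(pattern, states, expected):
    """Each labeled-segment pattern resolves to its replication-event reading."""
    c = parse_segment(pattern, *states)
    assert c.as_tuple() == pytest.approx(expected)


def test_rightward_fork_fiber():
    """U-R-G-U reads as a single rightward fork with two end junctions."""
    f = fiber_from_pattern("URGU")
    groups, junctions = segment_fiber(f)
    assert [g.code for g in groups] == ["RG"]
    assert [j.klass for j in junctions] == [JunctionClass.UNINFORMATIVE] * 2
    c = expected_event_counts(f, s=0.0)
    assert (c.forks_p1, c.forks_p2, c.stalls) == (1, 1, 0)


def test_double_definite_stall_fiber():
    """Interior G-U-R-U-G: an origin with both forks stalled, pinned by context."""
    f = fiber_from_pattern("UGURUGU")
    groups, junctions = segment_fiber(f)
    assert [g.code for g in groups] == ["G", "R", "G"]
    interior = [j.klass for j in junctions if j.klass is not JunctionClass.UNINFORMATIVE]
    assert interior == [JunctionClass.DEFINITE_STALL] * 2
    c = expected_event_counts(f, s=0.0)
    assert c.stalls == 2
    assert c.origins_p1 == 1
    assert c.forks_p1 == 2  # both stalled forks stay in the first-pulse count
    assert c.forks_p2 == 4  # the two flanking second-pulse origins only


def test_composite_rur_group():
    """G-R-U-R-G fuses into one composite group with a shared red-red gap."""
    f = fiber_from_pattern("UGRURGU")
    groups, _ = segment_fiber(f)
    assert [g.code for g in groups] == ["GRURG"]
    assert groups[0].n_vars == 1


class TestEnumerateInterpretations:
    def rur_group(self):
        groups, _ = segment_fiber(fiber_from_pattern("UGRURGU"))
        return groups[0]

    def test_rur_two_stall_weight_is_s_squared(self):
        """At s=0.10 the two-origins-with-stalled-forks reading carries 1%."""
        iset = enumerate_interpretations(self.rur_group(), s=0.10)
        by_stalls = {it.counts.stalls: it for it in iset.interpretations}
        assert set(by_stalls) == {0, 2}
        assert by_stalls[2].weight == pytest.approx(0.01)
        assert by_stalls[0].weight == pytest.approx(0.99)
        # interpretation 2: two origins, 4 expected forks of which 2 stalled
        assert by_stalls[2].counts.origins_p1 == 2
        assert by_stalls[2].counts.forks_p1 == 4
        assert by_stalls[2].counts.forks_p2 == 2

    def test_rur_limit_s_zero(self):
        """s=0 collapses RUR onto forks moving apart from a pre-pulse origin."""
        iset = enumerate_interpretations(self.rur_group(), s=0.0)
        live = [it for it in iset.interpretations if it.weight > 0]
        assert len(live) == 1
        assert live[0].counts.stalls == 0
        assert live[0].counts.forks_p1 == 2  # two elongating forks, no visible origin

    def test_isolated_red_three_readings(self):
        """U-R-U enumerates termination / stalled fork / doubly-stalled origin."""
        groups, _ = segment_fiber(fiber_from_pattern("URU"))
        iset = enumerate_interpretations(groups[0], s=0.2)
        w = {it.counts.stalls: it.weight for it in iset.interpretations}
        assert w[1] == pytest.approx(0.2)
        assert w[2] == pytest.approx(0.04)
        assert w[0] == pytest.approx(1 - 0.2 - 0.04)

    def test_weights_renormalize_when_overflowing(self):
        """Large s cannot push the minimal-stall weight below zero."""
        groups, _ = segment_fiber(fiber_from_pattern("URURURU"))
        iset = enumerate_interpretations(groups[0], s=1.0)
        weights = [it.weight for it in iset.interpretations]
        assert min(weights) >= 0
        assert sum(weights) == pytest.approx(1.0)

    def test_rejects_invalid_stall_rate(self):
        with pytest.raises(ValueError):
            enumerate_interpretations(self.rur_group(), s=1.5)


def test_fixed_taxonomy_counts():
    """A fiber with one GRG and one isolated G needs no enumeration."""
    f = fiber_from_pattern("UGRGUGU")
    c = expected_event_counts(f, s=0.5)
    assert (c.origins_p1, c.origins_p2, c.stalls) == (1, 1, 0)
    assert (c.forks_p1, c.forks_p2) == (2, 4)


def test_zero_labeled_tracks_is_valid():
    f = fiber_from_pattern("U", [300.0])
    groups, junctions = segment_fiber(f)
    assert groups == []
    assert len(junctions) == 1
    c = expected_event_counts(f, s=0.1)
    assert c.as_tuple() == pytest.approx((0,) * 8)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

def _random_pattern(rng: np.random.Generator, max_segments: int = 6) -> str:
    """Random no-equal-neighbor track string with <= max_segments labeled runs."""
    while True:
        n = int(rng.integers(1, 12))
        out = []
        for _ in range(n):
            choices = [c for c in "RGU" if not out or c != out[-1]]
            out.append(choices[int(rng.integers(len(choices)))])
        pat = "".join(out)
        if sum(1 for i, c in enumerate(pat) if c != "U" and (i == 0 or pat[i - 1] == "U")) <= max_segments:
            return pat


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.0, 0.6))
def test_expected_counts_match_bruteforce_oracle(seed, s):
    """Weighted expected counts equal exhaustive enumeration over gap states."""
    rng = np.random.default_rng(seed)
    f = fiber_from_pattern(_random_pattern(rng))
    got = expected_event_counts(f, s).as_tuple()
    want = oracle_expected_counts(f, s)
    assert got == pytest.approx(want, abs=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_weights_always_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    f = fiber_from_pattern(_random_pattern(rng))
    for s in (0.0, 0.1, 0.37, 0.9, 1.0):
        for group in segment_fiber(f)[0]:
            iset = enumerate_interpretations(group, s)
            assert sum(it.weight for it in iset.interpretations) == pytest.approx(1.0, abs=1e-9)
            assert all(it.weight >= -1e-12 for it in iset.interpretations)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_expected_stalls_monotone_in_s(seed):
    """More per-fork stall probability never predicts fewer stalls."""
    rng = np.random.default_rng(seed)
    f = fiber_from_pattern(_random_pattern(rng))
    grid = [0.0, 0.1, 0.2, 0.4, 0.8]
    stalls = [expected_event_counts(f, s).stalls for s in grid]
    assert all(b >= a - 1e-9 for a, b in zip(stalls, stalls[1:]))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_s_zero_resolves_to_minimal_stalls(seed):
    """At s=0 every ambiguous group collapses onto its minimal-stall reading."""
    rng = np.random.default_rng(seed)
    f = fiber_from_pattern(_random_pattern(rng))
    for group in segment_fiber(f)[0]:
        iset = enumerate_interpretations(group, 0.0)
        live = [it for it in iset.interpretations if it.weight > 0]
        assert len(live) == 1
        assert live[0].counts.stalls == min(it.counts.stalls for it in iset.interpretations)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_no_stall_on_green_edges(seed):
    """Fibers without red tracks never produce stall mass at any s."""
    rng = np.random.default_rng(seed)
    pat = _random_pattern(rng).replace("R", "G")
    pat = "".join(c for i, c in enumerate(pat) if i == 0 or c != pat[i - 1])
    f = fiber_from_pattern(pat)
    assert expected_event_counts(f, 1.0).stalls == 0
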