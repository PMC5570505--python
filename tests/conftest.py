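"""Shared fixtures and the independent brute-force interpretation oracle."""

from __future__ import annotations

import itertools

import pytest

from forkcomb.fiber_io import Fiber, Label, LabelTrack, make_fiber


def fiber_from_pattern(
    pattern: str,
    lengths: list[float] | None = None,
    fiber_id: str = "f",
    dataset_id: str = "d",
    min_fiber_kb: float = 0.0,
) -> Fiber:
    """Build a fiber from a compact track-pattern string like ``"URGU"``."""
    if lengths is None:
        lengths = [10.0] * len(pattern)
    tracks = [LabelTrack(Label(c), ln) for c, ln in zip(pattern, lengths)]
    return make_fiber(fiber_id, tracks, dataset_id=dataset_id, min_fiber_kb=min_fiber_kb)


@pytest.fixture
def make_pattern_fiber():
    return fiber_from_pattern


# ---------------------------------------------------------------------------
# Brute-force oracle.
#
# Enumerates, directly on the fiber's track string, every consistent
# assignment of unlabeled-gap states (pre-pulse replicated vs unreplicated),
# counts events per labeled segment from first principles, collapses
# count-identical assignments, and applies the s**excess weighting.  Written
# independently of forkcomb.patterns so the two can disagree.
# ---------------------------------------------------------------------------


def _oracle_segment_counts(seg: str, left_n: bool, right_n: bool) -> tuple:
    """(origins_p1, origins_p2, terms_p1, terms_p2, forks_p1, forks_p2, forks_total, stalls).

    Derivation: interior red tracks are flanked by green on both sides, so
    their DNA must have been replicated by two forks diverging inside them
    (a first-pulse origin); interior green tracks by two forks converging
    (a second-pulse termination).  A red edge next to unreplicated DNA is a
    stalled head, which forces an origin split inside the edge track.  Fork
    chains are delimited by those split points; a chain is in pulse 1 if it
    covers any red, pulse 2 if any green.
    """
    n = len(seg)
    if n == 1:
        if seg == "G":
            return (0, 1, 0, 0, 0, 2, 2, 0)
        both = left_n + right_n
        if both == 0:
            return (0, 0, 1, 0, 2, 0, 2, 0)
        if both == 2:
            return (1, 0, 0, 0, 2, 0, 2, 2)
        return (0, 0, 0, 0, 1, 0, 1, 1)
    o1 = o2 = t1 = t2 = stalls = 0
    splits = []
    for i, c in enumerate(seg):
        if 0 < i < n - 1:
            splits.append(i)
            if c == "R":
                o1 += 1
            else:
                t2 += 1
        elif c == "R" and (left_n if i == 0 else right_n):
            splits.append(i)
            o1 += 1
            stalls += 1
    bounds = [0] + sorted(splits) + [n - 1]
    f1 = f2 = ftot = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = seg[a : b + 1]
        ftot += 1
        f1 += "R" in chunk
        f2 += "G" in chunk
    return (o1, o2, t1, t2, f1, f2, ftot, stalls)


def oracle_expected_counts(fiber: Fiber, s: float) -> tuple:
    """Expected event counts by exhaustive enumeration over gap states.

    Works on the raw track string: free binary states are interior red-red
    gaps (one shared state) and red edges facing fiber-end unlabeled gaps
    (one state per edge); green-flanked gaps are forced unreplicated;
    labeled tracks at the physical fiber end contribute no stall state.
    Groups of segments sharing red-red gaps are enumerated jointly;
    assignments with equal counts merge; weight s**(stalls - min_stalls),
    minimal interpretation takes the remainder.
    """
    pattern = fiber.pattern()
    # Split into labeled segments with their edge context.
    segs: list[dict] = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "U":
            i += 1
            continue
        j = i
        while j < len(pattern) and pattern[j] != "U":
            j += 1
        segs.append({"s": pattern[i:j], "start": i, "end": j})
        i = j

    # Edge states: False = forced tail, True = forced unreplicated, or
    # ("free", key) with the key shared across an interior red-red gap.
    def edge_state(k: int, side: str):
        seg = segs[k]
        color = seg["s"][0] if side == "left" else seg["s"][-1]
        if side == "left":
            at_end = seg["start"] == 0
            neighbor = segs[k - 1]["s"][-1] if k > 0 else None
        else:
            at_end = seg["end"] == len(pattern)
            neighbor = segs[k + 1]["s"][0] if k + 1 < len(segs) else None
        if color == "G":
            return True
        if at_end:
            return False  # physical break: no stall inference
        if neighbor == "G":
            return True  # green head opposite: gap unreplicated, red edge stalled
        if neighbor == "R":
            return ("free", ("gap", k - 1 if side == "left" else k))
        # Fiber-end unlabeled gap: independent state for this red edge.
        return ("free", ("edge", k, side))

    edges = [(edge_state(k, "left"), edge_state(k, "right")) for k in range(len(segs))]

    # Group segments connected through shared gap keys.
    parent = list(range(len(segs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(len(segs) - 1):
        right = edges[k][1]
        left = edges[k + 1][0]
        if isinstance(right, tuple) and isinstance(left, tuple) and right[1] == left[1]:
            parent[find(k + 1)] = find(k)

    groups: dict[int, list[int]] = {}
    for k in range(len(segs)):
        groups.setdefault(find(k), []).append(k)

    total = [0.0] * 8
    for members in groups.values():
        keys = []
        for k in members:
            for st in edges[k]:
                if isinstance(st, tuple) and st[1] not in keys:
                    keys.append(st[1])
        outcomes = {}
        for bits in itertools.product([False, True], repeat=len(keys)):
            env = dict(zip(keys, bits))

            def resolve(st):
                return env[st[1]] if isinstance(st, tuple) else st

            counts = [0] * 8
            for k in members:
                c = _oracle_segment_counts(segs[k]["s"], resolve(edges[k][0]), resolve(edges[k][1]))
                counts = [a + b for a, b in zip(counts, c)]
            outcomes[tuple(counts)] = counts
        outs = sorted(outcomes.values(), key=lambda c: (c[7], tuple(c)))
        kmin = outs[0][7]
        raw = [None if c[7] == kmin else s ** (c[7] - kmin) for c in outs]
        extra = sum(w for w in raw if w is not None)
        if extra <= 1.0:
            weights = [1.0 - extra if w is None else w for w in raw]
        else:
            unnorm = [1.0 if w is None else w for w in raw]
            z = sum(unnorm)
            weights = [w / z for w in unnorm]
        for c, w in zip(outs, weights):
            total = [t + w * x for t, x in zip(total, c)]
    return tuple(total)
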