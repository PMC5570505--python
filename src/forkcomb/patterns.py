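"""Event segmentation, junction classification and probabilistic interpretation.

A dual-pulse fiber alternates labeled segments (maximal runs of red/green
tracks) with unlabeled gaps.  An unlabeled gap is either DNA replicated
before the first pulse or DNA still unreplicated at harvest; which of the two
decides whether the labeled edges facing it are fork tails or stalled fork
heads.  The flanking label colors constrain the answer:

* a green edge is always an active fork head moving into the gap, so the gap
  must contain unreplicated DNA;
* a red edge is either a tail (gap replicated pre-pulse) or the head of a
  fork that stalled before the second pulse (gap unreplicated).

Hence a green-unlabeled-green (GUG) gap is two unstalled forks, a
red-unlabeled-green (RUG/GUR) gap pins exactly one stalled fork on the red
side, and a red-unlabeled-red (RUR) gap is ambiguous: both edges are tails
(forks moving apart from an earlier origin) or both are stalled heads
converging on unreplicated DNA.  Mixed readings of a shared RUR gap are
geometrically impossible, so the two red edges are coupled.

Ambiguity is resolved probabilistically: every consistent assignment of gap
states is enumerated, assignments are collapsed into interpretations by
their event counts, and an interpretation requiring ``k`` stalls beyond the
forced minimum carries unnormalized weight ``s**k`` where ``s`` is the
dataset's apparent stall rate; the minimal-stall interpretation absorbs the
remaining probability.  With ``s = 0.10`` an RUR event is therefore read as
two stalled forks with probability 0.01.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, fields
from typing import Sequence

from forkcomb.fiber_io import Fiber, Label, LabelTrack

#: Enumeration guard: interpretation groups with more free gap states than
#: this are pathological for combing data and are refused rather than
#: silently truncated.
MAX_FREE_EDGES = 20


class Flank(enum.Enum):
    """What borders an unlabeled gap on one side."""

    RED = "R"
    GREEN = "G"
    FIBER_END = "E"


class JunctionClass(enum.Enum):
    NO_STALL = "no_stall"
    DEFINITE_STALL = "definite_stall"
    AMBIGUOUS_RR = "ambiguous_rr"
    UNINFORMATIVE = "uninformative"


def classify_junction(left_flank: Flank, right_flank: Flank) -> JunctionClass:
    """Classify an unlabeled gap from its flanking label colors.

    Green on both sides: two converging unstalled forks.  Red and green:
    the red-side fork must have stalled (two forks moving the same
    direction imply the one between them, moving oppositely, stopped).
    Red on both sides: ambiguous.  A fiber end on either side gives no
    context.
    """
    if left_flank is Flank.FIBER_END or right_flank is Flank.FIBER_END:
        return JunctionClass.UNINFORMATIVE
    if left_flank is Flank.GREEN and right_flank is Flank.GREEN:
        return JunctionClass.NO_STALL
    if left_flank is Flank.RED and right_flank is Flank.RED:
        return JunctionClass.AMBIGUOUS_RR
    return JunctionClass.DEFINITE_STALL


@dataclass(frozen=True)
class Junction:
    """An unlabeled gap with its flanking colors and stall classification."""

    gap_length_kb: float
    left_flank: Flank
    right_flank: Flank
    klass: JunctionClass

    @staticmethod
    def make(gap_length_kb: float, left_flank: Flank, right_flank: Flank) -> "Junction":
        return Junction(gap_length_kb, left_flank, right_flank, classify_junction(left_flank, right_flank))


@dataclass
class Counts:
    """Replication-event counts for a fiber, a segment or an interpretation.

    Fork counts follow the dataset conventions: ``forks_p1`` are forks
    ongoing during the first pulse (stalled forks included), ``forks_p2``
    forks ongoing during the second, ``forks_total`` distinct forks.  Under
    probabilistic interpretation the fields are expectations and fractional.
    """

    origins_p1: float = 0.0
    origins_p2: float = 0.0
    terms_p1: float = 0.0
    terms_p2: float = 0.0
    forks_p1: float = 0.0
    forks_p2: float = 0.0
    forks_total: float = 0.0
    stalls: float = 0.0

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(*(getattr(self, f.name) + getattr(other, f.name) for f in fields(Counts)))

    def scaled(self, w: float) -> "Counts":
        return Counts(*(w * getattr(self, f.name) for f in fields(Counts)))

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f.name) for f in fields(Counts))

    @property
    def origins(self) -> float:
        return self.origins_p1 + self.origins_p2


def parse_segment(pattern: str, left_unreplicated: bool, right_unreplicated: bool) -> Counts:
    """Count events in one labeled segment given the state of its outer gaps.

    ``pattern`` is the alternating color string of the segment (e.g. ``"RG"``,
    ``"GRG"``).  The two booleans say whether the DNA beyond each end is
    unreplicated (``True``) or replicated before the first pulse (``False``);
    they only matter for red edges.  The parse is forced everywhere else:
    every interior red track is a first-pulse origin, every interior green
    track a second-pulse termination, and a red edge facing unreplicated DNA
    is a stalled fork head (splitting an origin off the edge track).
    """
    n = len(pattern)
    c = Counts()
    if n == 1:
        if pattern == "G":
            # Isolated green: an origin fired during the second pulse.
            c.origins_p2 = 1
            c.forks_p2 = 2
            c.forks_total = 2
        elif not left_unreplicated and not right_unreplicated:
            # Two forks converged here during the first pulse.
            c.terms_p1 = 1
            c.forks_p1 = 2
            c.forks_total = 2
        elif left_unreplicated and right_unreplicated:
            # First-pulse origin whose two forks both stalled.
            c.origins_p1 = 1
            c.stalls = 2
            c.forks_p1 = 2
            c.forks_total = 2
        else:
            # A single elongating fork that stalled during the first pulse.
            c.stalls = 1
            c.forks_p1 = 1
            c.forks_total = 1
        return c

    # Track indices at which the fork path splits (origin or termination
    # inside that track); edge tracks split only when a stalled head is
    # forced onto their outer side.
    split_tracks: list[int] = []
    for i, col in enumerate(pattern):
        if 0 < i < n - 1:
            if col == "R":
                c.origins_p1 += 1
            else:
                c.terms_p2 += 1
            split_tracks.append(i)
        else:
            unrep = left_unreplicated if i == 0 else right_unreplicated
            if col == "R" and unrep:
                # Stalled head at the outer edge; the rest of the red track
                # belongs to the sister fork of an origin inside it.
                c.origins_p1 += 1
                c.stalls += 1
                split_tracks.append(i)

    # Fork chains span consecutive tracks between split points; a split
    # track contributes its color to the chains on both sides.
    bounds = [0] + sorted(split_tracks) + [n - 1]
    for a, b in zip(bounds[:-1], bounds[1:]):
        colors = set(pattern[a : b + 1])
        c.forks_total += 1
        if "R" in colors:
            c.forks_p1 += 1
        if "G" in colors:
            c.forks_p2 += 1
    return c


@dataclass(frozen=True)
class Segment:
    """A maximal run of labeled tracks on a fiber."""

    tracks: tuple[LabelTrack, ...]
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def pattern(self) -> str:
        return "".join(t.label.value for t in self.tracks)

    @property
    def span_kb(self) -> float:
        return sum(t.length_kb for t in self.tracks)


# Edge specifications for enumeration: a fixed gap state or a free variable.
_FIXED_P = ("fixed", False)
_FIXED_N = ("fixed", True)


@dataclass(frozen=True)
class EventGroup:
    """Labeled segments coupled through shared ambiguous (red-red) gaps.

    ``edge_specs`` holds, per segment, the (left, right) resolution of its
    outer gap state: a fixed boolean or a reference to one of ``n_vars``
    free binary gap states.  A shared red-red gap is a single variable
    referenced from both of its flanking segments, which is what couples
    their stall readings.
    """

    segments: tuple[Segment, ...]
    edge_specs: tuple[tuple[tuple, tuple], ...]
    n_vars: int
    code: str
    gap_lengths_kb: tuple[float, ...] = ()

    @property
    def span_kb(self) -> float:
        return sum(s.span_kb for s in self.segments) + sum(self.gap_lengths_kb)

    @property
    def at_fiber_end(self) -> bool:
        return self.segments[0].left_truncated or self.segments[-1].right_truncated


@dataclass(frozen=True)
class Interpretation:
    """One count-distinct reading of an event group."""

    counts: Counts
    weight: float

    @property
    def n_stalls(self) -> float:
        return self.counts.stalls


@dataclass(frozen=True)
class InterpretationSet:
    group: EventGroup
    interpretations: tuple[Interpretation, ...]

    def expected_counts(self) -> Counts:
        total = Counts()
        for it in self.interpretations:
            total = total + it.counts.scaled(it.weight)
        return total


def _build_segments(fiber: Fiber) -> tuple[list[Segment], list[int], list[Junction]]:
    """Segment a fiber's track list.

    Returns ``(segments, inner_gap_idx, junctions)``: ``junctions`` lists
    every unlabeled gap in fiber order (fiber-end gaps included), and
    ``inner_gap_idx[k]`` is the index into ``junctions`` of the single gap
    separating ``segments[k]`` from ``segments[k+1]``.
    """
    tracks = fiber.tracks
    n = len(tracks)
    segments: list[Segment] = []
    junctions: list[Junction] = []
    inner_gap_idx: list[int] = []
    i = 0
    while i < n:
        if tracks[i].label is Label.UNLABELED:
            left = Flank.FIBER_END if i == 0 else Flank(tracks[i - 1].label.value)
            right = Flank.FIBER_END if i == n - 1 else Flank(tracks[i + 1].label.value)
            if left is not Flank.FIBER_END and right is not Flank.FIBER_END:
                inner_gap_idx.append(len(junctions))
            junctions.append(Junction.make(tracks[i].length_kb, left, right))
            i += 1
        else:
            j = i
            while j < n and tracks[j].label is not Label.UNLABELED:
                j += 1
            segments.append(
                Segment(tuple(tracks[i:j]), left_truncated=(i == 0), right_truncated=(j == n))
            )
            i = j
    return segments, inner_gap_idx, junctions


def segment_fiber(fiber: Fiber, exclude_ends: bool = False) -> tuple[list[EventGroup], list[Junction]]:
    """Parse a fiber into event groups and junctions.

    Labeled segments linked through shared ambiguous red-red gaps are fused
    into composite event groups; every unlabeled gap (fiber-end gaps
    included) appears once in the junction list.  With ``exclude_ends``,
    labeled segments touching a physical fiber end are dropped from the
    event list and the gaps next to them are downgraded to uninformative,
    mirroring the end-artifact re-analysis of combing data.
    """
    segments, inner_gap_idx, junctions = _build_segments(fiber)
    inner_gaps: list[Junction] = [junctions[k] for k in inner_gap_idx]

    keep = [not (exclude_ends and (seg.left_truncated or seg.right_truncated)) for seg in segments]
    if exclude_ends:
        for gi in range(len(inner_gaps)):
            if not keep[gi] or not keep[gi + 1]:
                gap = inner_gaps[gi]
                demoted = Junction(
                    gap.gap_length_kb, gap.left_flank, gap.right_flank, JunctionClass.UNINFORMATIVE
                )
                junctions[inner_gap_idx[gi]] = demoted
                inner_gaps[gi] = demoted

    groups: list[EventGroup] = []
    i = 0
    while i < len(segments):
        if not keep[i]:
            i += 1
            continue
        chain = [i]
        while (
            chain[-1] + 1 < len(segments)
            and keep[chain[-1] + 1]
            and inner_gaps[chain[-1]].klass is JunctionClass.AMBIGUOUS_RR
        ):
            chain.append(chain[-1] + 1)
        groups.append(_make_group(segments, inner_gaps, chain))
        i = chain[-1] + 1
    return groups, junctions


def _edge_spec(seg: Segment, side: str, gap: Junction | None, var_alloc: list[int]) -> tuple:
    """Resolve one outer edge of a segment to a fixed state or a new variable.

    ``gap`` is the junction beyond this edge (None when the segment is
    truncated by the physical fiber end).  Green edges always face
    unreplicated DNA; truncated edges carry no stall information and are
    read as continuations.
    """
    color = seg.pattern[0] if side == "left" else seg.pattern[-1]
    if color == "G":
        return _FIXED_N
    if gap is None:
        return _FIXED_P  # physical break: no inference at truncations
    if gap.klass is JunctionClass.DEFINITE_STALL:
        return _FIXED_N
    if gap.klass is JunctionClass.UNINFORMATIVE:
        idx = var_alloc[0]
        var_alloc[0] += 1
        return ("var", idx)
    raise AssertionError(f"unexpected outer gap class {gap.klass}")


def _make_group(segments: list[Segment], inner_gaps: list[Junction], chain: list[int]) -> EventGroup:
    """Assemble an event group from a chain of ambiguously-linked segments.

    Each shared red-red gap inside the chain becomes one free variable
    referenced from both flanking segments; outer edges are resolved
    through :func:`_edge_spec` (a fiber-end unlabeled gap counts as
    uninformative and yields an independent variable on red edges).
    """
    var_alloc = [0]
    specs: list[tuple[tuple, tuple]] = []
    gap_lengths: list[float] = []
    pending_shared: tuple | None = None

    for pos, si in enumerate(chain):
        seg = segments[si]
        if pos > 0:
            left = pending_shared
        elif seg.left_truncated:
            left = _edge_spec(seg, "left", None, var_alloc)
        elif si > 0:
            # The preceding gap exists but is not ambiguous (else this
            # segment would not start the chain).
            left = _edge_spec(seg, "left", inner_gaps[si - 1], var_alloc)
        else:
            # Leading unlabeled gap at the fiber start: uninformative.
            left = _edge_spec(
                seg, "left", Junction.make(1.0, Flank.FIBER_END, Flank(seg.pattern[0])), var_alloc
            )
        if pos < len(chain) - 1:
            idx = var_alloc[0]
            var_alloc[0] += 1
            right = ("var", idx)
            pending_shared = right
            gap_lengths.append(inner_gaps[si].gap_length_kb)
        elif seg.right_truncated:
            right = _edge_spec(seg, "right", None, var_alloc)
        elif si < len(inner_gaps):
            right = _edge_spec(seg, "right", inner_gaps[si], var_alloc)
        else:
            right = _edge_spec(
                seg, "right", Junction.make(1.0, Flank(seg.pattern[-1]), Flank.FIBER_END), var_alloc
            )
        specs.append((left, right))

    return EventGroup(
        segments=tuple(segments[si] for si in chain),
        edge_specs=tuple(specs),
        n_vars=var_alloc[0],
        code="U".join(segments[si].pattern for si in chain),
        gap_lengths_kb=tuple(gap_lengths),
    )


def _resolve(spec: tuple, assignment: Sequence[bool]) -> bool:
    kind, val = spec
    return assignment[val] if kind == "var" else val


def group_counts(group: EventGroup, assignment: Sequence[bool]) -> Counts:
    """Event counts of a group under one assignment of its free gap states."""
    total = Counts()
    for seg, (left, right) in zip(group.segments, group.edge_specs):
        total = total + parse_segment(seg.pattern, _resolve(left, assignment), _resolve(right, assignment))
    return total


def enumerate_interpretations(group: EventGroup, s: float) -> InterpretationSet:
    """Enumerate the count-distinct interpretations of an event group.

    Every assignment of the group's free gap states is evaluated;
    assignments with identical event counts collapse into one
    interpretation.  An interpretation requiring ``k`` stalls beyond the
    group's forced minimum gets unnormalized weight ``s**k``; the
    minimal-stall interpretation absorbs the remainder so weights sum to 1.
    If the remainder would be negative (large ``s``), all weights are
    renormalized proportionally.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"apparent stall rate must be in [0, 1], got {s}")
    if group.n_vars > MAX_FREE_EDGES:
        raise ValueError(
            f"event group {group.code!r} has {group.n_vars} free gap states; "
            f"refusing to enumerate more than {MAX_FREE_EDGES}"
        )

    by_counts: dict[tuple, Counts] = {}
    for assignment in itertools.product((False, True), repeat=group.n_vars):
        c = group_counts(group, assignment)
        by_counts.setdefault(c.as_tuple(), c)

    counts_list = sorted(by_counts.values(), key=lambda c: (c.stalls,) + c.as_tuple())
    k_min = counts_list[0].stalls
    raw = [s ** (c.stalls - k_min) if c.stalls > k_min else None for c in counts_list]
    extra = sum(w for w in raw if w is not None)
    if extra <= 1.0:
        weights = [1.0 - extra if w is None else w for w in raw]
    else:
        unnorm = [1.0 if w is None else w for w in raw]
        z = sum(unnorm)
        weights = [w / z for w in unnorm]

    interps = tuple(
        Interpretation(counts=c, weight=w) for c, w in zip(counts_list, weights)
    )
    return InterpretationSet(group=group, interpretations=interps)


def expected_event_counts(
    fiber: Fiber,
    s: float,
    mode: str = "probabilistic",
    exclude_ends: bool = False,
) -> Counts:
    """Expected replication-event counts for one fiber.

    ``mode='naive'`` applies the simple single-reading taxonomy (isolated
    red = first-pulse termination; no stalls anywhere).  ``mode=
    'probabilistic'`` fixes the stalls pinned by definite red/green
    junctions and weight-averages every ambiguous event group using the
    apparent stall rate ``s``.
    """
    if mode not in ("naive", "probabilistic"):
        raise ValueError(f"mode must be 'naive' or 'probabilistic', got {mode!r}")
    groups, _ = segment_fiber(fiber, exclude_ends=exclude_ends)
    total = Counts()
    for group in groups:
        if mode == "naive":
            for seg in group.segments:
                total = total + parse_segment(seg.pattern, False, False)
        else:
            total = total + enumerate_interpretations(group, s).expected_counts()
    return total
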