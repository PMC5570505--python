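"""Stochastic simulator of dual-pulse-labeled combing fibers with ground truth.

The model is 1-D nucleation and growth on a linear chromosome: origins fire
as a Poisson process at a constant rate per unreplicated length per minute,
each origin launches two forks with a per-fork speed drawn from a truncated
normal, and forks terminate on meeting converging forks or replicated DNA.
Lesions are placed by a Poisson process; a fork reaching a lesion stalls
permanently with probability ``p_stall_per_lesion`` and otherwise pauses
for ``pause_min_per_lesion`` (the local-slowing mechanism).  Spontaneous
permanent stalls occur with a constant hazard per kb traversed.  Stalled
forks never resume.

Replication begins ``sim_start_to_pulse1_min`` before labeling so that
pre-pulse replicated DNA exists (the source of ambiguous red/red patterns);
DNA replicated during the first pulse is labeled red, during the second
green, everything else unlabeled.  The molecule is then fragmented by
Poisson cutting, tracks below optical resolution are merged into their
neighbors, multiplicative measurement noise is applied, and fibers below
the minimum analyzable length are flagged excluded.

The ground truth records every origin, lesion and stall.  A stall is
flagged detectable when it begins during the first pulse (so the fork has a
red track but no green) and its head still borders unreplicated DNA at
harvest — a stalled head later reached by a converging fork leaves no
unlabeled gap and no longer looks like a stall on the fiber.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from forkcomb.fiber_io import Fiber, Label, LabelTrack, make_fiber

#: Spontaneous permanent-stall hazard per kb traversed.  The default puts
#: the untreated operating point at a detectable stall fraction near 0.14,
#: the level reported for unperturbed fission-yeast S phase.
DEFAULT_SPONTANEOUS_STALL_PER_KB = 0.0225

_MOVING, _PAUSED, _STALLED, _DONE = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated dataset.

    Defaults emulate the untreated mid-S-phase fission-yeast labeling
    design: 5-min first pulse, 10-min chase, ~2.3 origins/Mb/min, ~0.91
    kb/min forks, ~25 Mb of DNA in fibers averaging ~450 kb.
    """

    genome_mb: float = 25.0
    origin_rate_per_mb_min: float = 2.3
    fork_speed_kb_min: float = 0.91
    fork_speed_cv: float = 0.1
    lesion_density_per_kb: float = 0.0
    p_stall_per_lesion: float = 0.0
    pause_min_per_lesion: float = 0.0
    spontaneous_stall_per_kb: float = DEFAULT_SPONTANEOUS_STALL_PER_KB
    sim_start_to_pulse1_min: float = 10.0
    pulse1_min: float = 5.0
    pulse2_min: float = 10.0
    fragment_mean_kb: float = 450.0
    min_fiber_kb: float = 120.0
    resolution_kb: float = 2.0
    length_noise_cv: float = 0.02
    fragile_lesions: bool = False
    time_step_min: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        positives = {
            "genome_mb": self.genome_mb,
            "fork_speed_kb_min": self.fork_speed_kb_min,
            "pulse1_min": self.pulse1_min,
            "pulse2_min": self.pulse2_min,
            "fragment_mean_kb": self.fragment_mean_kb,
            "time_step_min": self.time_step_min,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        non_negative = {
            "origin_rate_per_mb_min": self.origin_rate_per_mb_min,
            "fork_speed_cv": self.fork_speed_cv,
            "lesion_density_per_kb": self.lesion_density_per_kb,
            "pause_min_per_lesion": self.pause_min_per_lesion,
            "spontaneous_stall_per_kb": self.spontaneous_stall_per_kb,
            "sim_start_to_pulse1_min": self.sim_start_to_pulse1_min,
            "min_fiber_kb": self.min_fiber_kb,
            "resolution_kb": self.resolution_kb,
            "length_noise_cv": self.length_noise_cv,
        }
        for name, v in non_negative.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not 0.0 <= self.p_stall_per_lesion <= 1.0:
            raise ValueError(f"p_stall_per_lesion must be a probability, got {self.p_stall_per_lesion}")

    @property
    def pulse1_start(self) -> float:
        return self.sim_start_to_pulse1_min

    @property
    def pulse2_start(self) -> float:
        return self.sim_start_to_pulse1_min + self.pulse1_min

    @property
    def harvest(self) -> float:
        return self.sim_start_to_pulse1_min + self.pulse1_min + self.pulse2_min


@dataclass
class StallEvent:
    position_kb: float
    time_min: float
    cause: Literal["lesion", "spontaneous"]
    detectable: bool = False
    covered: bool = False  # a converging fork later replicated the adjacent gap


@dataclass
class GroundTruth:
    """True event log of one simulated dataset."""

    origins: list[tuple[float, float]]  # (position_kb, time_min)
    stalls: list[StallEvent]
    lesion_positions_kb: np.ndarray
    n_forks_p1: int
    n_forks_p2: int
    replicated_fraction_at_harvest: float
    config: SimulationConfig

    @property
    def detectable_stalls(self) -> int:
        return sum(1 for st in self.stalls if st.detectable)

    @property
    def detectable_stall_fraction(self) -> float:
        return self.detectable_stalls / self.n_forks_p1 if self.n_forks_p1 else math.nan


class _Fork:
    __slots__ = (
        "direction",
        "speed",
        "pos",
        "state",
        "resume_t",
        "spont_remaining",
        "lesion_i",
        "pieces",
        "piece_open",
        "stall",
    )

    def __init__(self, pos: float, direction: int, speed: float, t: float, spont: float, lesion_i: int):
        self.pos = pos
        self.direction = direction
        self.speed = speed
        self.state = _MOVING
        self.resume_t = 0.0
        self.spont_remaining = spont
        self.lesion_i = lesion_i
        self.pieces: list[tuple[float, float, float]] = []  # (t_start, x_start, x_end)
        self.piece_open = False
        self.stall: StallEvent | None = None

    def _move(self, d: float, t: float) -> None:
        """Record d kb of movement beginning at time t."""
        if d <= 0:
            return
        new = self.pos + d * self.direction
        if self.piece_open:
            t0, x0, _ = self.pieces[-1]
            self.pieces[-1] = (t0, x0, new)
        else:
            self.pieces.append((t, self.pos, new))
            self.piece_open = True
        self.pos = new


def _advance(
    fork: _Fork,
    t_now: float,
    dt: float,
    max_dist: float,
    lesions: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    """Advance one fork by up to dt minutes and max_dist kb; return kb moved."""
    t = t_now
    t_end = t_now + dt
    moved = 0.0
    while t < t_end - 1e-12 and fork.state in (_MOVING, _PAUSED):
        if fork.state == _PAUSED:
            if fork.resume_t >= t_end:
                break
            t = fork.resume_t
            fork.state = _MOVING
            fork.piece_open = False
            continue
        d_time = fork.speed * (t_end - t)
        d_cap = max_dist - moved
        d_spont = fork.spont_remaining
        if 0 <= fork.lesion_i < lesions.size:
            d_lesion = (lesions[fork.lesion_i] - fork.pos) * fork.direction
        else:
            d_lesion = math.inf
        d = min(d_time, d_cap, d_spont, d_lesion)
        fork._move(d, t)
        moved += d
        fork.spont_remaining -= d
        t += d / fork.speed
        if d >= d_cap - 1e-12 and d_cap <= min(d_time, d_spont, d_lesion) + 1e-12:
            break  # reached the gap boundary; caller resolves the meeting
        if d == d_spont and d_spont <= min(d_time, d_lesion):
            fork.state = _STALLED
            fork.stall = StallEvent(position_kb=fork.pos, time_min=t, cause="spontaneous")
            fork.piece_open = False
            break
        if d == d_lesion and d_lesion <= d_time:
            fork.lesion_i += fork.direction
            if rng.random() < cfg.p_stall_per_lesion:
                fork.state = _STALLED
                fork.stall = StallEvent(position_kb=fork.pos, time_min=t, cause="lesion")
                fork.piece_open = False
                break
            if cfg.pause_min_per_lesion > 0:
                fork.state = _PAUSED
                fork.resume_t = t + cfg.pause_min_per_lesion
                fork.piece_open = False
        if d == d_time:
            break
    return moved


class _Gap:
    """An unreplicated interval with the forks (or dead ends) at its boundaries."""

    __slots__ = ("left", "right", "lfork", "rfork", "lstall", "rstall")

    def __init__(self, left, right, lfork=None, rfork=None, lstall=None, rstall=None):
        self.left = left
        self.right = right
        self.lfork = lfork  # rightward fork eating the gap from the left
        self.rfork = rfork  # leftward fork eating the gap from the right
        self.lstall = lstall  # stalled head exposed at the left boundary
        self.rstall = rstall

    @property
    def width(self) -> float:
        return self.right - self.left


def _draw_speed(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    v = rng.normal(cfg.fork_speed_kb_min, cfg.fork_speed_cv * cfg.fork_speed_kb_min)
    return max(v, 0.05 * cfg.fork_speed_kb_min)


def _draw_spont(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.spontaneous_stall_per_kb <= 0:
        return math.inf
    return rng.exponential(1.0 / cfg.spontaneous_stall_per_kb)


def simulate(config: SimulationConfig, dataset_id: str = "sim") -> tuple[list[Fiber], GroundTruth]:
    """Run the replication, labeling and combing model for one dataset."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_mb * 1000.0
    rate_per_kb_min = cfg.origin_rate_per_mb_min / 1000.0

    n_lesions = rng.poisson(cfg.lesion_density_per_kb * L) if cfg.lesion_density_per_kb > 0 else 0
    lesions = np.sort(rng.uniform(0.0, L, size=n_lesions))

    gaps: list[_Gap] = [_Gap(0.0, L)]
    all_forks: list[_Fork] = []
    origins: list[tuple[float, float]] = []
    dt = cfg.time_step_min
    n_steps = int(math.ceil(cfg.harvest / dt))

    for step in range(n_steps):
        t = step * dt
        step_dt = min(dt, cfg.harvest - t)
        if step_dt <= 0:
            break
        # Move boundary forks; alternate which side goes first to avoid a
        # systematic meeting-point bias.
        surviving: list[_Gap] = []
        for gap in gaps:
            order = (("l", "r") if step % 2 == 0 else ("r", "l"))
            for side in order:
                fork = gap.lfork if side == "l" else gap.rfork
                if fork is None or fork.state not in (_MOVING, _PAUSED):
                    pass
                else:
                    moved = _advance(fork, t, step_dt, gap.width, lesions, cfg, rng)
                    if side == "l":
                        gap.left += moved
                    else:
                        gap.right -= moved
                # A fork that stalled becomes an exposed dead end.
                if fork is not None and fork.state == _STALLED:
                    if side == "l":
                        gap.lfork, gap.lstall = None, fork.stall
                    else:
                        gap.rfork, gap.rstall = None, fork.stall
            if gap.width <= 1e-9:
                # Gap consumed: whatever still moves here terminates, and a
                # stalled head at either boundary is now covered by
                # replicated DNA.
                for fork in (gap.lfork, gap.rfork):
                    if fork is not None:
                        fork.state = _DONE
                        fork.piece_open = False
                for st in (gap.lstall, gap.rstall):
                    if st is not None:
                        st.covered = True
            else:
                surviving.append(gap)
        gaps = surviving

        # Origin firing over the remaining unreplicated DNA.
        U = sum(g.width for g in gaps)
        if U > 0 and rate_per_kb_min > 0:
            n_fire = rng.poisson(rate_per_kb_min * U * step_dt)
            for _ in range(n_fire):
                widths = np.array([g.width for g in gaps])
                gi = int(rng.choice(len(gaps), p=widths / widths.sum()))
                g = gaps[gi]
                margin = min(1e-6, g.width / 4)
                pos = rng.uniform(g.left + margin, g.right - margin)
                t_fire = t + step_dt
                origins.append((pos, t_fire))
                li = int(np.searchsorted(lesions, pos))
                fr = _Fork(pos, +1, _draw_speed(cfg, rng), t_fire, _draw_spont(cfg, rng), li)
                fl = _Fork(pos, -1, _draw_speed(cfg, rng), t_fire, _draw_spont(cfg, rng), li - 1)
                all_forks.extend((fl, fr))
                right_part = _Gap(pos, g.right, lfork=fr, rfork=g.rfork, rstall=g.rstall)
                g.right, g.rfork, g.rstall = pos, fl, None
                gaps.insert(gi + 1, right_part)

    # --- ground truth bookkeeping -----------------------------------------
    t1, t2, t3 = cfg.pulse1_start, cfg.pulse2_start, cfg.harvest
    stalls: list[StallEvent] = []
    n_p1 = n_p2 = 0
    for fork in all_forks:
        spans_p1 = any(_piece_overlaps(p, fork.speed, t1, t2) for p in fork.pieces)
        spans_p2 = any(_piece_overlaps(p, fork.speed, t2, t3) for p in fork.pieces)
        if fork.stall is not None:
            st = fork.stall
            # Detectable: the stall begins before the second pulse (so the
            # fork shows no green) and, being permanent, persists through
            # labeling.  Stalls from before labeling qualify: the unlabeled
            # gap they leave is revealed by the neighboring-fork context.
            # ``covered`` records the subset whose head was later reached by
            # a converging fork and thus left no unlabeled gap after all.
            st.detectable = st.time_min < t2
            stalls.append(st)
        # Ongoing first-pulse forks: anything replicating during the first
        # pulse, plus earlier-stalled forks, which the fiber analysis keeps
        # in the first-pulse denominator.
        n_p1 += spans_p1 or (fork.stall is not None and fork.stall.detectable)
        n_p2 += spans_p2

    # --- painting ----------------------------------------------------------
    labeled: list[tuple[float, float, str]] = []
    for fork in all_forks:
        for piece in fork.pieces:
            labeled.extend(_paint_piece(piece, fork.speed, t1, t2, t3))
    labeled.sort()
    replicated_kb = sum(abs(p[2] - p[1]) for f in all_forks for p in f.pieces)

    truth = GroundTruth(
        origins=origins,
        stalls=stalls,
        lesion_positions_kb=lesions,
        n_forks_p1=int(n_p1),
        n_forks_p2=int(n_p2),
        replicated_fraction_at_harvest=replicated_kb / L,
        config=cfg,
    )

    # --- fragmentation and measurement -------------------------------------
    n_cuts = rng.poisson(L / cfg.fragment_mean_kb)
    cuts = np.sort(rng.uniform(0.0, L, size=n_cuts))
    if cfg.fragile_lesions and lesions.size:
        cuts = np.sort(np.concatenate([cuts, lesions]))
    bounds = np.concatenate([[0.0], cuts, [L]])

    fibers: list[Fiber] = []
    for fi in range(len(bounds) - 1):
        a, b = float(bounds[fi]), float(bounds[fi + 1])
        if b - a <= 0:
            continue
        tracks = _tracks_for_fragment(labeled, a, b)
        tracks = _merge_below_resolution(tracks, cfg.resolution_kb)
        if cfg.length_noise_cv > 0:
            noisy = []
            for lab, ln in tracks:
                factor = max(0.05, rng.normal(1.0, cfg.length_noise_cv))
                noisy.append((lab, ln * factor))
            tracks = noisy
        if not tracks:
            continue
        fibers.append(
            make_fiber(
                f"{dataset_id}_{fi:05d}",
                [LabelTrack(Label(lab), round(ln, 3)) for lab, ln in tracks if ln > 5e-4],
                dataset_id=dataset_id,
                min_fiber_kb=cfg.min_fiber_kb,
            )
        )
    return fibers, truth


def _piece_time_range(piece: tuple[float, float, float], speed: float) -> tuple[float, float]:
    t0, x0, x1 = piece
    return t0, t0 + abs(x1 - x0) / speed


def _piece_overlaps(piece, speed, ta, tb) -> bool:
    p0, p1 = _piece_time_range(piece, speed)
    return p0 < tb and p1 > ta


def _paint_piece(piece, speed, t1, t2, t3) -> list[tuple[float, float, str]]:
    """Split one fork trajectory piece into labeled intervals (R/G only)."""
    t0, x0, x1 = piece
    tend = t0 + abs(x1 - x0) / speed
    direction = 1.0 if x1 >= x0 else -1.0
    out = []
    for ta, tb, lab in ((t1, t2, "R"), (t2, t3, "G")):
        lo_t, hi_t = max(t0, ta), min(tend, tb)
        if hi_t <= lo_t:
            continue
        xa = x0 + direction * speed * (lo_t - t0)
        xb = x0 + direction * speed * (hi_t - t0)
        lo, hi = (xa, xb) if xa <= xb else (xb, xa)
        if hi > lo:
            out.append((lo, hi, lab))
    return out


def _tracks_for_fragment(labeled: list[tuple[float, float, str]], a: float, b: float) -> list[tuple[str, float]]:
    """Clip sorted labeled intervals to [a, b] and fill gaps with U tracks."""
    tracks: list[tuple[str, float]] = []
    cursor = a

    def push(lab: str, length: float) -> None:
        if length <= 1e-9:
            return
        if tracks and tracks[-1][0] == lab:
            tracks[-1] = (lab, tracks[-1][1] + length)
        else:
            tracks.append((lab, length))

    # labeled is sorted by start; a linear scan per fragment is fine at the
    # dataset sizes used here.
    for lo, hi, lab in labeled:
        if hi <= a or lo >= b:
            continue
        lo, hi = max(lo, a), min(hi, b)
        if lo > cursor:
            push("U", lo - cursor)
        elif lo < cursor:
            lo = cursor  # clip sliver overlaps from meeting-point rounding
        if hi > lo:
            push(lab, hi - lo)
            cursor = hi
    if cursor < b:
        push("U", b - cursor)
    return tracks


def _merge_below_resolution(tracks: list[tuple[str, float]], resolution_kb: float) -> list[tuple[str, float]]:
    """Absorb tracks below optical resolution into their neighbors.

    A sub-resolution track between two same-label neighbors bridges them; at
    an edge, or between unlike neighbors, it is absorbed into the longer
    neighbor.  Iterates until every remaining track resolves.
    """
    if resolution_kb <= 0:
        return tracks
    tracks = list(tracks)
    while len(tracks) > 1:
        idx = min(range(len(tracks)), key=lambda i: tracks[i][1])
        lab, ln = tracks[idx]
        if ln >= resolution_kb:
            break
        if idx == 0:
            nb = 1
        elif idx == len(tracks) - 1:
            nb = idx - 1
        else:
            left_lab, left_len = tracks[idx - 1]
            right_lab, right_len = tracks[idx + 1]
            if left_lab == right_lab:
                tracks[idx - 1] = (left_lab, left_len + ln + right_len)
                del tracks[idx : idx + 2]
                continue
            nb = idx - 1 if left_len >= right_len else idx + 1
        nb_lab, nb_len = tracks[nb]
        tracks[nb] = (nb_lab, nb_len + ln)
        del tracks[idx]
        # Re-merge neighbors that may now share a label.
        merged: list[tuple[str, float]] = []
        for lab2, ln2 in tracks:
            if merged and merged[-1][0] == lab2:
                merged[-1] = (lab2, merged[-1][1] + ln2)
            else:
                merged.append((lab2, ln2))
        tracks = merged
    return tracks


def mms_like(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Frequent mild alkylation lesions: ~1 lesion/kb, rare stalls, short pauses.

    Forks meet many lesions, pause briefly at each (reducing net fork rate)
    and stall at a small fraction; checkpoint inhibition of origin firing is
    delayed for this damage class, so the firing rate is left unchanged.
    """
    cfg = base or SimulationConfig()
    params = dict(lesion_density_per_kb=1.0, p_stall_per_lesion=0.005, pause_min_per_lesion=0.35)
    params.update(overrides)
    return replace(cfg, **params)


def nqo_like(
    base: SimulationConfig | None = None,
    checkpoint_origin_factor: float = 0.47,
    **overrides,
) -> SimulationConfig:
    """Rare bulky adducts: ~1 lesion/25 kb, severe (5% stall per lesion).

    Few forks meet a lesion, so net fork rate is unchanged; the checkpoint
    response is emulated by scaling the origin firing rate down.
    """
    cfg = base or SimulationConfig()
    params = dict(
        lesion_density_per_kb=0.04,
        p_stall_per_lesion=0.05,
        pause_min_per_lesion=0.0,
        origin_rate_per_mb_min=cfg.origin_rate_per_mb_min * checkpoint_origin_factor,
    )
    params.update(overrides)
    return replace(cfg, **params)


def bleo_like(
    base: SimulationConfig | None = None,
    checkpoint_origin_factor: float = 0.58,
    **overrides,
) -> SimulationConfig:
    """Rare strand breaks: ~1 per 50 kb; every break stops the incoming fork."""
    cfg = base or SimulationConfig()
    params = dict(
        lesion_density_per_kb=0.02,
        p_stall_per_lesion=1.0,
        pause_min_per_lesion=0.0,
        origin_rate_per_mb_min=cfg.origin_rate_per_mb_min * checkpoint_origin_factor,
    )
    params.update(overrides)
    return replace(cfg, **params)
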