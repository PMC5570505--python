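"""Fork rate, origin firing rate, fork density and dataset comparison.

Fork rate comes from second-pulse (green) tracks that continue from a
first-pulse (red) track — the RG, GR and outer tracks of GRG events — each
divided by the chase duration.  The per-dataset rate is the mean of a
Gaussian least-squares fit to the binned rate histogram, which is robust to
the low-side pedestal contributed by forks that stalled or broke during the
second pulse; the plain sample mean and SD are reported alongside.

Origin firing rate divides the origin events on a fiber (GRG for the first
pulse, isolated green for the second) by the fiber's unlabeled DNA length
and by the pulse duration.  Fork density counts the forks ongoing in each
pulse per kb of unlabeled DNA.  In probabilistic mode both use the
stall-corrected expected counts, which credit origins whose forks stalled
(RG/GR with a stalled sister, isolated red with both forks stalled).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from forkcomb.fiber_io import DatasetMeta, Fiber
from forkcomb.patterns import expected_event_counts, segment_fiber

#: Default histogram bin width for the Gaussian fork-rate fit (kb/min).
DEFAULT_BIN_WIDTH = 0.1

#: Minimum number of rate samples for a histogram fit.
MIN_SAMPLES_FOR_FIT = 30


@dataclass(frozen=True)
class ForkRateSample:
    """One fork-rate measurement from a qualifying green track."""

    rate_kb_per_min: float
    event_code: str
    fiber_id: str
    at_fiber_end: bool


def fork_rates(
    fiber: Fiber, meta: DatasetMeta | None = None, exclude_ends: bool = False
) -> list[ForkRateSample]:
    """Fork-rate samples from one fiber.

    Qualifying green tracks sit at the edge of a labeled segment next to a
    red track (so RG and GR give one sample, GRG two); isolated green
    events carry no direction or red continuation and give none.  Samples
    whose green track is cut by the physical fiber end are flagged and,
    with ``exclude_ends``, dropped.
    """
    meta = meta or DatasetMeta()
    groups, _ = segment_fiber(fiber, exclude_ends=exclude_ends)
    samples: list[ForkRateSample] = []
    for group in groups:
        for seg in group.segments:
            pattern = seg.pattern
            if len(pattern) < 2:
                continue
            edges = [(0, seg.left_truncated)]
            if len(pattern) > 1:
                edges.append((len(pattern) - 1, seg.right_truncated))
            for idx, truncated in edges:
                if pattern[idx] != "G":
                    continue
                if exclude_ends and truncated:
                    continue
                samples.append(
                    ForkRateSample(
                        rate_kb_per_min=seg.tracks[idx].length_kb / meta.pulse2_min,
                        event_code=pattern,
                        fiber_id=fiber.fiber_id,
                        at_fiber_end=truncated,
                    )
                )
    return samples


@dataclass(frozen=True)
class GaussianFit:
    """Result of the histogram Gaussian fit, with sample statistics."""

    mean: float
    sd: float
    fitted: bool
    sample_mean: float
    sample_sd: float
    n: int
    message: str = ""


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_fork_rate_gaussian(
    samples: "list[float] | np.ndarray", bin_width: float = DEFAULT_BIN_WIDTH
) -> GaussianFit:
    """Least-squares Gaussian fit to the binned fork-rate histogram.

    Falls back to the sample mean/SD (``fitted=False``) below
    ``MIN_SAMPLES_FOR_FIT`` samples or on non-convergence.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("no fork-rate samples")
    sample_mean = float(np.mean(x))
    sample_sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    def fallback(msg: str) -> GaussianFit:
        warnings.warn(f"fork-rate Gaussian fit unavailable ({msg}); using sample statistics")
        return GaussianFit(sample_mean, sample_sd, False, sample_mean, sample_sd, x.size, msg)

    if x.size < MIN_SAMPLES_FOR_FIT:
        return fallback(f"only {x.size} samples")
    lo = 0.0
    hi = math.ceil(float(np.max(x)) / bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    p0 = (float(hist.max()), sample_mean, max(sample_sd, bin_width / 2))
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers,
            hist.astype(float),
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        return fallback(str(exc))
    return GaussianFit(float(popt[1]), float(popt[2]), True, sample_mean, sample_sd, x.size)


@dataclass(frozen=True)
class OriginRates:
    """Origin firing rates for one fiber (origins per kb unlabeled per min)."""

    total: float
    p1: float
    p2: float


def origin_firing_rate(
    fiber: Fiber,
    s: float = 0.0,
    mode: str = "probabilistic",
    meta: DatasetMeta | None = None,
    exclude_ends: bool = False,
) -> OriginRates | None:
    """Per-fiber origin firing rate, overall and per pulse.

    The overall rate divides total origin events by unlabeled DNA length
    and the summed pulse durations; per-pulse rates use the matching pulse
    duration.  Probabilistic mode replaces raw counts with stall-corrected
    expectations.  Returns None (with a warning) when the fiber carries no
    unlabeled DNA.
    """
    meta = meta or DatasetMeta()
    unrep = fiber.unreplicated_kb
    if unrep <= 0:
        warnings.warn(f"fiber {fiber.fiber_id!r} has no unlabeled DNA; origin rate undefined")
        return None
    c = expected_event_counts(fiber, s, mode=mode, exclude_ends=exclude_ends)
    return OriginRates(
        total=(c.origins_p1 + c.origins_p2) / unrep / meta.total_pulse_min,
        p1=c.origins_p1 / unrep / meta.pulse1_min,
        p2=c.origins_p2 / unrep / meta.pulse2_min,
    )


@dataclass(frozen=True)
class ForkDensities:
    """Forks per kb of unlabeled DNA, per pulse and overall."""

    p1: float
    p2: float
    total: float


def fork_density(
    fiber: Fiber,
    s: float = 0.0,
    mode: str = "probabilistic",
    exclude_ends: bool = False,
) -> ForkDensities | None:
    """Per-fiber fork density for each pulse and overall.

    Naive mode reproduces the direct event counting (origins and
    terminations twice, unidirectional forks once); probabilistic mode uses
    expected fork counts with stalled forks kept in the first pulse.
    Returns None when the fiber carries no unlabeled DNA.
    """
    unrep = fiber.unreplicated_kb
    if unrep <= 0:
        warnings.warn(f"fiber {fiber.fiber_id!r} has no unlabeled DNA; fork density undefined")
        return None
    c = expected_event_counts(fiber, s, mode=mode, exclude_ends=exclude_ends)
    return ForkDensities(p1=c.forks_p1 / unrep, p2=c.forks_p2 / unrep, total=c.forks_total / unrep)


def sister_fork_asymmetry(fiber: Fiber, exclude_ends: bool = False) -> list[float]:
    """Longer/shorter green-track ratios of sister fork pairs.

    Sister pairs come from plain GRG events (one origin, both forks
    continuing into the second pulse); each ratio is >= 1.
    """
    groups, _ = segment_fiber(fiber, exclude_ends=exclude_ends)
    ratios = []
    for group in groups:
        for seg in group.segments:
            if seg.pattern == "GRG":
                g1 = seg.tracks[0].length_kb
                g2 = seg.tracks[2].length_kb
                ratios.append(max(g1, g2) / min(g1, g2))
    return ratios


@dataclass(frozen=True)
class Comparison:
    """Treated/untreated comparison of one metric."""

    metric: str
    ratio: float
    p_value: float
    mean_treated: float
    mean_untreated: float
    sd_treated: float
    sd_untreated: float
    n_treated: int
    n_untreated: int

    @property
    def ratio_sd(self) -> float:
        """First-order (delta-method) SD of the ratio of means."""
        if self.mean_untreated == 0 or self.n_treated == 0 or self.n_untreated == 0:
            return math.nan
        se_t = self.sd_treated / math.sqrt(self.n_treated)
        se_u = self.sd_untreated / math.sqrt(self.n_untreated)
        return abs(self.ratio) * math.sqrt(
            (se_t / self.mean_treated) ** 2 + (se_u / self.mean_untreated) ** 2
        )


def compare_datasets(treated, untreated, metric: str) -> Comparison:
    """Ratio of dataset means and Welch t-test for one metric.

    ``treated`` and ``untreated`` are dataset summaries exposing a
    ``samples`` mapping of metric name to per-fiber values (per-sample
    values for ``fork_rate``).
    """
    try:
        a = np.asarray(treated.samples[metric], dtype=float)
        b = np.asarray(untreated.samples[metric], dtype=float)
    except KeyError as exc:
        raise KeyError(f"metric {metric!r} missing from a dataset summary") from exc
    if a.size == 0 or b.size == 0:
        raise ValueError(f"metric {metric!r} has no values in one dataset")
    t = stats.ttest_ind(a, b, equal_var=False)
    mean_t, mean_u = float(np.mean(a)), float(np.mean(b))
    return Comparison(
        metric=metric,
        ratio=mean_t / mean_u if mean_u != 0 else math.nan,
        p_value=float(t.pvalue),
        mean_treated=mean_t,
        mean_untreated=mean_u,
        sd_treated=float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
        sd_untreated=float(np.std(b, ddof=1)) if b.size > 1 else 0.0,
        n_treated=int(a.size),
        n_untreated=int(b.size),
    )
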