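"""Dataset-level analysis: summaries and treated/untreated comparisons."""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forkcomb.fiber_io import DatasetMeta, Fiber
from forkcomb.kinetics import (
    Comparison,
    GaussianFit,
    compare_datasets,
    fit_fork_rate_gaussian,
    fork_density,
    fork_rates,
    origin_firing_rate,
)
from forkcomb.patterns import expected_event_counts
from forkcomb.stalls import apparent_stall_rate

logger = logging.getLogger("forkcomb")

#: Metrics carried per fiber in a dataset summary, in reporting order.
FIBER_METRICS = (
    "origin_rate_total",
    "origin_rate_p1",
    "origin_rate_p2",
    "fork_density_p1",
    "fork_density_p2",
    "fork_density_total",
    "stalls_per_kb",
    "stall_rate",
)


@dataclass
class DatasetSummary:
    """Pooled estimates for one dataset.

    ``samples`` maps each metric to its per-fiber values (per-sample values
    for ``fork_rate``), which is what dataset comparisons test on.
    Rates are reported in the units used throughout: origins per kb
    unlabeled per minute, forks per kb unlabeled, stalls per kb unlabeled,
    and kb per minute for fork rate.
    """

    dataset_id: str
    mode: str
    exclude_ends: bool
    n_fibers: int
    n_excluded: int
    total_mb: float
    mean_fiber_kb: float
    s_apparent: float
    fork_rate_fit: GaussianFit
    metrics: dict[str, dict[str, float]]
    samples: dict[str, np.ndarray] = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            "dataset_id": self.dataset_id,
            "mode": self.mode,
            "exclude_ends": self.exclude_ends,
            "n_fibers": self.n_fibers,
            "n_excluded": self.n_excluded,
            "total_mb": round(self.total_mb, 6),
            "mean_fiber_kb": round(self.mean_fiber_kb, 3),
            "s_apparent": round(self.s_apparent, 6),
            "fork_rate": {
                "fit_mean_kb_min": round(self.fork_rate_fit.mean, 6),
                "fit_sd_kb_min": round(self.fork_rate_fit.sd, 6),
                "fitted": self.fork_rate_fit.fitted,
                "sample_mean_kb_min": round(self.fork_rate_fit.sample_mean, 6),
                "sample_sd_kb_min": round(self.fork_rate_fit.sample_sd, 6),
                "n_samples": self.fork_rate_fit.n,
            },
            "metrics": {
                name: {k: (None if v is None or (isinstance(v, float) and math.isnan(v)) else round(v, 9)) for k, v in vals.items()}
                for name, vals in self.metrics.items()
            },
        }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.metrics.items():
            rows.append({"metric": name, **vals})
        return pd.DataFrame(rows)


def _mean_sd(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"mean": math.nan, "sd": math.nan, "n": 0}
    return {
        "mean": float(np.mean(arr)),
        "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }


def run_analysis(
    fibers: list[Fiber],
    meta: DatasetMeta | None = None,
    mode: str = "probabilistic",
    exclude_ends: bool = False,
    s: float | None = None,
    dataset_id: str | None = None,
) -> DatasetSummary:
    """Analyze one dataset of fibers into a :class:`DatasetSummary`.

    The apparent stall rate is estimated from the dataset unless ``s`` is
    given.  Fibers flagged excluded (below the minimum length) are skipped
    and counted; fibers on which a metric is undefined (no unlabeled DNA,
    no first-pulse forks) are skipped for that metric with a log entry.
    Deterministic: identical inputs and options give identical summaries.
    """
    meta = meta or DatasetMeta()
    included = [f for f in fibers if not f.excluded]
    n_excluded = len(fibers) - len(included)
    if not included:
        raise ValueError("no analyzable fibers after exclusions")
    if dataset_id is None:
        dataset_id = included[0].dataset_id or "dataset"
    logger.info("%s: %d fibers analyzed, %d excluded (<%g kb)", dataset_id, len(included), n_excluded, meta.min_fiber_kb)

    if s is None:
        s = apparent_stall_rate(included, exclude_ends=exclude_ends)
    logger.info("%s: apparent stall rate s = %.4f", dataset_id, s)

    per_fiber: dict[str, list[float]] = {name: [] for name in FIBER_METRICS}
    rate_samples: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fiber in included:
            c = expected_event_counts(fiber, s, mode=mode, exclude_ends=exclude_ends)
            unrep = fiber.unreplicated_kb
            orates = origin_firing_rate(fiber, s, mode=mode, meta=meta, exclude_ends=exclude_ends)
            dens = fork_density(fiber, s, mode=mode, exclude_ends=exclude_ends)
            if orates is None or dens is None:
                logger.info("%s: fiber %s has no unlabeled DNA; rate metrics skipped", dataset_id, fiber.fiber_id)
            else:
                per_fiber["origin_rate_total"].append(orates.total)
                per_fiber["origin_rate_p1"].append(orates.p1)
                per_fiber["origin_rate_p2"].append(orates.p2)
                per_fiber["fork_density_p1"].append(dens.p1)
                per_fiber["fork_density_p2"].append(dens.p2)
                per_fiber["fork_density_total"].append(dens.total)
                per_fiber["stalls_per_kb"].append(c.stalls / unrep)
            if mode == "probabilistic" and c.forks_p1 > 0:
                per_fiber["stall_rate"].append(c.stalls / c.forks_p1)
            elif mode == "probabilistic":
                logger.info("%s: fiber %s has no first-pulse forks; stall rate skipped", dataset_id, fiber.fiber_id)
            for smp in fork_rates(fiber, meta=meta, exclude_ends=exclude_ends):
                rate_samples.append(smp.rate_kb_per_min)

        if rate_samples:
            fit = fit_fork_rate_gaussian(rate_samples)
        else:
            fit = GaussianFit(math.nan, math.nan, False, math.nan, math.nan, 0, "no samples")
            logger.info("%s: no fork-rate samples", dataset_id)
    if not fit.fitted and fit.n:
        logger.info("%s: fork-rate Gaussian fit fell back to sample statistics (%s)", dataset_id, fit.message)

    total_kb = sum(f.total_length_kb for f in included)
    metrics = {name: _mean_sd(vals) for name, vals in per_fiber.items()}
    samples = {name: np.asarray(vals, dtype=float) for name, vals in per_fiber.items()}
    samples["fork_rate"] = np.asarray(rate_samples, dtype=float)
    metrics["fork_rate"] = _mean_sd(rate_samples)

    return DatasetSummary(
        dataset_id=dataset_id,
        mode=mode,
        exclude_ends=exclude_ends,
        n_fibers=len(included),
        n_excluded=n_excluded,
        total_mb=total_kb / 1000.0,
        mean_fiber_kb=total_kb / len(included),
        s_apparent=s,
        fork_rate_fit=fit,
        metrics=metrics,
        samples=samples,
    )


DEFAULT_COMPARE_METRICS = FIBER_METRICS + ("fork_rate",)


def run_comparison(
    treated: DatasetSummary,
    untreated: DatasetSummary,
    metrics: tuple[str, ...] = DEFAULT_COMPARE_METRICS,
) -> list[Comparison]:
    """Treated/untreated ratios with Welch t-tests for the given metrics.

    Refuses to compare summaries computed under different options, which
    would silently bias every ratio.
    """
    if (treated.mode, treated.exclude_ends) != (untreated.mode, untreated.exclude_ends):
        raise ValueError(
            "dataset summaries were computed with different options: "
            f"({treated.mode}, exclude_ends={treated.exclude_ends}) vs "
            f"({untreated.mode}, exclude_ends={untreated.exclude_ends})"
        )
    return [compare_datasets(treated, untreated, m) for m in metrics]


def comparison_frame(comparisons: list[Comparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "ratio": c.ratio,
                "ratio_sd": c.ratio_sd,
                "p_value": c.p_value,
                "mean_treated": c.mean_treated,
                "mean_untreated": c.mean_untreated,
                "sd_treated": c.sd_treated,
                "sd_untreated": c.sd_untreated,
                "n_treated": c.n_treated,
                "n_untreated": c.n_untreated,
            }
            for c in comparisons
        ]
    )
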