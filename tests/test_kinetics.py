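"""Fork rate, origin rate, fork density, asymmetry and comparisons."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import fiber_from_pattern
from forkcomb.fiber_io import DatasetMeta
from forkcomb.kinetics import (
    compare_datasets,
    fit_fork_rate_gaussian,
    fork_density,
    fork_rates,
    origin_firing_rate,
    sister_fork_asymmetry,
)


class TestForkRates:
    def test_rg_sample(self):
        f = fiber_from_pattern("URGU", lengths=[50, 5, 9.1, 50])
        samples = fork_rates(f)
        assert len(samples) == 1
        assert samples[0].rate_kb_per_min == pytest.approx(0.91)
        assert not samples[0].at_fiber_end

    def test_grg_yields_two_samples(self):
        f = fiber_from_pattern("UGRGU", lengths=[50, 8, 5, 10, 50])
        rates = sorted(s.rate_kb_per_min for s in fork_rates(f))
        assert rates == pytest.approx([0.8, 1.0])

    def test_isolated_green_yields_none(self):
        assert fork_rates(fiber_from_pattern("UGU")) == []

    def test_interior_green_of_termination_excluded(self):
        # RGR: the green is bounded by the meeting point, not the chase time.
        assert fork_rates(fiber_from_pattern("URGRU")) == []

    def test_truncated_green_flagged_and_excludable(self):
        f = fiber_from_pattern("URG", lengths=[50, 5, 7])  # green cut by fiber end
        samples = fork_rates(f)
        assert len(samples) == 1 and samples[0].at_fiber_end
        assert fork_rates(f, exclude_ends=True) == []

    def test_custom_chase_time(self):
        f = fiber_from_pattern("URGU", lengths=[50, 5, 9.1, 50])
        meta = DatasetMeta(pulse2_min=7.0)
        assert fork_rates(f, meta)[0].rate_kb_per_min == pytest.approx(9.1 / 7.0)


class TestGaussianFit:
    def test_recovers_seeded_normal_mean(self):
        rng = np.random.default_rng(42)
        samples = rng.normal(0.9, 0.15, size=1000)
        fit = fit_fork_rate_gaussian(samples)
        assert fit.fitted
        assert fit.mean == pytest.approx(0.9, abs=0.02)

    def test_robust_to_low_side_pedestal(self):
        """A uniform pedestal (stalled-in-chase forks) barely moves the fit."""
        rng = np.random.default_rng(7)
        peak = rng.normal(0.9, 0.1, size=800)
        pedestal = rng.uniform(0.0, 0.9, size=200)
        fit = fit_fork_rate_gaussian(np.concatenate([peak, pedestal]))
        assert fit.fitted
        assert fit.mean == pytest.approx(0.9, abs=0.03)
        assert fit.sample_mean < fit.mean  # the plain mean is dragged down

    def test_small_samples_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="sample statistics"):
            fit = fit_fork_rate_gaussian([0.8, 0.9, 1.0])
        assert not fit.fitted
        assert fit.mean == pytest.approx(0.9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_fork_rate_gaussian([])


class TestOriginFiringRate:
    def test_naive_counting(self):
        # 2 GRG + 1 isolated G over 1000 kb unlabeled, 15 min of pulses.
        f = fiber_from_pattern(
            "UGRGUGRGUGU", lengths=[250, 5, 5, 5, 250, 5, 5, 5, 250, 10, 250]
        )
        rates = origin_firing_rate(f, mode="naive")
        assert rates.total == pytest.approx(3 / 1000 / 15)
        assert rates.total * 1e3 == pytest.approx(0.2)  # origins/Mb/min
        assert rates.p1 == pytest.approx(2 / 1000 / 5)
        assert rates.p2 == pytest.approx(1 / 1000 / 10)

    def test_probabilistic_equals_naive_at_s_zero(self):
        # No definite (red/green) junctions: s=0 must reproduce naive exactly,
        # ambiguous fiber-end red edges included.
        for pattern in ("UGRGUGU", "URGUGRU", "URURU"):
            f = fiber_from_pattern(pattern)
            naive = origin_firing_rate(f, mode="naive")
            prob = origin_firing_rate(f, s=0.0, mode="probabilistic")
            assert prob == naive, pattern

    def test_undefined_without_unlabeled(self):
        with pytest.warns(UserWarning):
            assert origin_firing_rate(fiber_from_pattern("GRG")) is None


class TestForkDensity:
    def test_naive_first_pulse_counting(self):
        # {1 GRG, 1 RGR, 2 RG} over 500 kb unlabeled: (2+2+2)/500.
        f = fiber_from_pattern(
            "UGRGURGRURGURGU",
            lengths=[100, 5, 5, 5, 100, 5, 5, 5, 100, 5, 5, 100, 5, 5, 100],
        )
        dens = fork_density(f, mode="naive")
        assert dens.p1 == pytest.approx(6 / 500)
        assert dens.p2 == pytest.approx(6 / 500)  # GRG x2 + RGR x2 + RG x1 x2
        assert dens.total == pytest.approx(6 / 500)  # every fork spans both pulses

    def test_naive_density_with_pulse_specific_events(self):
        # {GRG, R, G, RG}: p1 = 2+2+1, p2 = 2+2+1, total = 2+2+2+1.
        f = fiber_from_pattern(
            "UGRGURUGURGU",
            lengths=[100, 5, 5, 5, 100, 5, 100, 5, 100, 5, 5, 100],
        )
        dens = fork_density(f, mode="naive")
        assert dens.p1 == pytest.approx(5 / 500)
        assert dens.p2 == pytest.approx(5 / 500)
        assert dens.total == pytest.approx(7 / 500)

    def test_total_bounds_per_pulse_densities(self):
        for pattern in ("UGRGUGU", "URGURU", "UGRURGU", "URGRU"):
            dens = fork_density(fiber_from_pattern(pattern), mode="naive")
            assert dens.total >= max(dens.p1, dens.p2) - 1e-12


class TestSisterForkAsymmetry:
    def test_ratio_is_longer_over_shorter(self):
        f = fiber_from_pattern("UGRGU", lengths=[50, 8, 5, 10, 50])
        assert sister_fork_asymmetry(f) == pytest.approx([1.25])

    def test_equal_sisters_give_one(self):
        f = fiber_from_pattern("UGRGU", lengths=[50, 9, 5, 9, 50])
        assert sister_fork_asymmetry(f) == pytest.approx([1.0])

    def test_constant_speed_simulation_is_nearly_symmetric(self):
        from forkcomb.simulate import SimulationConfig, simulate

        cfg = SimulationConfig(
            genome_mb=15, seed=5, fork_speed_cv=0.0, spontaneous_stall_per_kb=0.0,
            length_noise_cv=0.0,
        )
        fibers, _ = simulate(cfg)
        ratios = [r for f in fibers for r in sister_fork_asymmetry(f, exclude_ends=True)]
        assert ratios, "expected GRG events in the simulation"
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)


class _Summary:
    def __init__(self, **samples):
        self.samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}


class TestCompareDatasets:
    def test_identical_datasets(self):
        a = _Summary(stall_rate=[0.1, 0.2, 0.3])
        c = compare_datasets(a, _Summary(stall_rate=[0.1, 0.2, 0.3]), "stall_rate")
        assert c.ratio == pytest.approx(1.0)
        assert c.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        # {1,2,3} vs {2,3,4}: equal variances 1, t = -1/sqrt(2/3), df = 4.
        c = compare_datasets(_Summary(m=[1, 2, 3]), _Summary(m=[2, 3, 4]), "m")
        t_stat = (2 - 3) / math.sqrt(1 / 3 + 1 / 3)
        from scipy import stats

        assert c.p_value == pytest.approx(2 * stats.t.sf(abs(t_stat), df=4))
        assert c.ratio == pytest.approx(2 / 3)

    def test_missing_metric_raises(self):
        with pytest.raises(KeyError, match="missing"):
            compare_datasets(_Summary(a=[1.0]), _Summary(b=[1.0]), "a")
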