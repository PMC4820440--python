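"""Fitting and inference: closed-form MLE oracle, early-component EM,
reciprobit coordinates, latency classes, swivel/shift comparison and the
bootstrap."""

import numpy as np
import pytest

from timerrider import (
    DomainError,
    EarlyComponent,
    InsufficientDataError,
    SimulationConfig,
    bin_proportions,
    bootstrap_ci,
    classify_latency,
    compare_conditions,
    fit_early_mixture,
    fit_recinormal,
    perturb_unit,
    reciprobit_coordinates,
    simulate_trials,
)

from conftest import make_trialset


class TestFitRecinormal:
    def test_uncensored_mle_equals_promptness_moments(self):
        rng = np.random.default_rng(0)
        lat_ms = 1000.0 / rng.normal(5.0, 1.0, size=500)
        lat_ms = lat_ms[lat_ms > 0]
        ts = make_trialset(lat_ms)
        fit = fit_recinormal(ts)
        # independent closed-form oracle: sample moments of 1/latency
        p = 1000.0 / lat_ms
        assert fit.params.m == pytest.approx(np.mean(p), abs=1e-10)
        assert fit.params.s == pytest.approx(np.std(p), abs=1e-10)
        assert fit.converged and fit.n_used == len(lat_ms)

    def test_parameter_recovery_at_n_1000(self, pure_cfg):
        cfg = pure_cfg.model_copy(update={"n_trials": 1000})
        fit = fit_recinormal(simulate_trials(cfg, seed=21))
        assert fit.params.m == pytest.approx(5.0, rel=0.05)
        assert fit.params.s == pytest.approx(1.0, rel=0.05)

    def test_too_few_trials(self):
        with pytest.raises(InsufficientDataError):
            fit_recinormal(make_trialset([200.0, 210.0]))

    def test_censored_likelihood_corrects_window_truncation(self, pure_cfg):
        cfg = pure_cfg.model_copy(
            update={"response_window_ms": 220.0, "n_trials": 5000}
        )
        ts = simulate_trials(cfg, seed=22)
        assert ts.n_censored > 100
        naive = fit_recinormal(ts, censoring="exclude")
        corrected = fit_recinormal(ts, censoring="likelihood", window_ms=220.0)
        assert corrected.converged
        # excluding the slow (right) tail biases mean promptness upward;
        # the censored likelihood should land closer to the true m = 5
        assert abs(corrected.params.m - 5.0) < abs(naive.params.m - 5.0)
        assert corrected.params.m == pytest.approx(5.0, rel=0.05)


class TestEarlyMixture:
    def test_zero_early_weight_recovered_as_zero(self, pure_cfg):
        cfg = pure_cfg.model_copy(update={"n_trials": 2000})
        fit = fit_early_mixture(simulate_trials(cfg, seed=23))
        assert fit.early is not None
        assert fit.early.weight < 0.02

    def test_mixture_likelihood_dominates_single(self, pure_cfg):
        for seed in (31, 32, 33):
            cfg = SimulationConfig(
                n_trials=1000,
                early=EarlyComponent(weight=0.15, sigma_prime=15.0),
                p_express=0.0,
            )
            ts = simulate_trials(cfg, seed=seed)
            single = fit_recinormal(ts)
            mixture = fit_early_mixture(ts)
            assert mixture.log_likelihood >= single.log_likelihood - 1e-9

    def test_weight_recovery_against_realized_fraction(self):
        # Oracle: the simulator's own subpopulation labels. About half the
        # zero-mean early promptness mass censors, so the comparison is to
        # the realized early fraction among responses, not the attempt rate.
        cfg = SimulationConfig(
            n_trials=4000,
            early=EarlyComponent(weight=0.2, sigma_prime=15.0),
            p_express=0.0,
        )
        ts = simulate_trials(cfg, seed=24)
        responded = ts.data[ts.data["subpopulation"] != "censored"]
        realized = (responded["subpopulation"] == "early").mean()
        fit = fit_early_mixture(ts)
        assert fit.early.weight == pytest.approx(realized, abs=0.05)
        assert fit.early.sigma_prime == pytest.approx(15.0, rel=0.25)

    def test_requires_ten_trials(self):
        with pytest.raises(InsufficientDataError):
            fit_early_mixture(make_trialset(np.linspace(150, 300, 9)))


class TestReciprobitCoordinates:
    def test_median_probit_near_zero(self, pure_cfg):
        ts = simulate_trials(pure_cfg.model_copy(update={"n_trials": 1001}), seed=25)
        coords = reciprobit_coordinates(ts)
        median_idx = len(coords) // 2
        assert abs(coords[median_idx, 1]) < 0.01

    def test_monotone_in_latency(self, pure_cfg):
        coords = reciprobit_coordinates(simulate_trials(pure_cfg, seed=26))
        # rows sorted by ascending latency: promptness falls, probit rises
        assert np.all(np.diff(coords[:, 0]) <= 0)
        assert np.all(np.diff(coords[:, 1]) > 0)

    def test_recinormal_sample_is_linear(self, pure_cfg):
        cfg = pure_cfg.model_copy(update={"n_trials": 10_000})
        coords = reciprobit_coordinates(simulate_trials(cfg, seed=27))
        r = np.corrcoef(coords[:, 0], coords[:, 1])[0, 1]
        assert r**2 > 0.99

    def test_blom_rule_available(self, pure_cfg):
        ts = simulate_trials(pure_cfg, seed=28)
        cw = reciprobit_coordinates(ts, "weibull")
        cb = reciprobit_coordinates(ts, "blom")
        assert cw.shape == cb.shape
        assert not np.allclose(cw[:, 1], cb[:, 1])
        with pytest.raises(DomainError):
            reciprobit_coordinates(ts, "hazen")


class TestCompareConditions:
    def test_identical_datasets_give_none(self, pure_cfg):
        a = simulate_trials(pure_cfg, seed=29)
        cmp = compare_conditions(a, a)
        assert cmp.verdict == "none"
        assert cmp.p_values["same"] == pytest.approx(1.0)

    def test_nested_loglik_ordering(self, pure_cfg):
        for seed in (41, 42, 43, 44):
            a = simulate_trials(pure_cfg, seed=seed)
            b = simulate_trials(pure_cfg, seed=seed + 100)
            lls = {k: f.log_likelihood for k, f in compare_conditions(a, b).fits.items()}
            assert lls["same"] <= lls["swivel"] + 1e-8
            assert lls["same"] <= lls["shift"] + 1e-8
            assert lls["swivel"] <= lls["full"] + 1e-8
            assert lls["shift"] <= lls["full"] + 1e-8

    def test_threshold_change_detected_as_swivel(self, pure_cfg):
        cfg_b = pure_cfg.model_copy(
            update={"unit": perturb_unit(pure_cfg.unit, "threshold_change", 0.7)}
        )
        hits = 0
        for rep in range(20):
            a = simulate_trials(pure_cfg, seed=1000 + 2 * rep)
            b = simulate_trials(cfg_b, seed=1001 + 2 * rep)
            hits += compare_conditions(a, b).verdict == "swivel"
        assert hits >= 18

    def test_gain_change_detected_as_shift(self, pure_cfg):
        cfg_b = pure_cfg.model_copy(
            update={"unit": perturb_unit(pure_cfg.unit, "gain_change", 1.3)}
        )
        hits = 0
        for rep in range(20):
            a = simulate_trials(pure_cfg, seed=2000 + 2 * rep)
            b = simulate_trials(cfg_b, seed=2001 + 2 * rep)
            hits += compare_conditions(a, b).verdict == "shift"
        assert hits >= 18

    def test_swivel_fit_shares_intercept(self, pure_cfg):
        a = simulate_trials(pure_cfg, seed=45)
        b = simulate_trials(pure_cfg, seed=46)
        sw = compare_conditions(a, b).fits["swivel"]
        assert sw.a.infinite_time_intercept == pytest.approx(
            sw.b.infinite_time_intercept, abs=1e-6
        )

    def test_shift_fit_shares_slope(self, pure_cfg):
        a = simulate_trials(pure_cfg, seed=47)
        b = simulate_trials(pure_cfg, seed=48)
        sh = compare_conditions(a, b).fits["shift"]
        assert sh.a.s == sh.b.s

    def test_bonferroni_option(self, pure_cfg):
        a = simulate_trials(pure_cfg, seed=49)
        b = simulate_trials(pure_cfg, seed=50)
        cmp = compare_conditions(a, b, correction="bonferroni")
        assert cmp.correction == "bonferroni"

    def test_invalid_alpha(self, pure_cfg):
        a = simulate_trials(pure_cfg, seed=51)
        with pytest.raises(DomainError):
            compare_conditions(a, a, alpha=1.5)


class TestLatencyClasses:
    @pytest.mark.parametrize(
        "latency,label",
        [
            (70, "anticipatory"),
            (79.9, "anticipatory"),
            (80, "express"),
            (100, "express"),
            (134, "express"),
            (134.5, "express"),
            (135, "fast_regular"),
            (179, "fast_regular"),
            (180, "slow_regular"),
            (250, "slow_regular"),
            (399, "slow_regular"),
            (400, "late"),
            (1200, "late"),
        ],
    )
    def test_classify(self, latency, label):
        assert classify_latency(latency) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            classify_latency(0.0)

    def test_single_class_proportion(self):
        props = bin_proportions(make_trialset([100.0] * 50))
        assert props["express"] == 1.0

    def test_proportions_sum_to_one(self, pure_cfg):
        props = bin_proportions(simulate_trials(pure_cfg, seed=52))
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            bin_proportions(make_trialset([], n_censored=3))

    def test_express_mixture_lands_in_express_class(self):
        # Gate open at rest (theta at the ceiling) so the main population
        # stays unmodulated at ~200 ms, outside the express class.
        from timerrider import CouplingConfig

        cfg = SimulationConfig(
            n_trials=10_000,
            p_express=0.3,
            early=EarlyComponent(weight=0.0),
            coupling=CouplingConfig(theta_express=1.0),
        )
        props = bin_proportions(simulate_trials(cfg, seed=53))
        assert props["express"] == pytest.approx(0.3, abs=0.03)


class TestBootstrap:
    def test_deterministic_given_seed(self, pure_cfg):
        ts = simulate_trials(pure_cfg, seed=54)
        stat = lambda t: fit_recinormal(t).params.m
        ci1 = bootstrap_ci(ts, stat, n_boot=200, seed=7)
        ci2 = bootstrap_ci(ts, stat, n_boot=200, seed=7)
        assert ci1 == ci2

    def test_point_estimate_inside_interval(self, pure_cfg):
        ts = simulate_trials(pure_cfg, seed=55)
        stat = lambda t: fit_recinormal(t).params.m
        lo, hi = bootstrap_ci(ts, stat, n_boot=300, seed=8)
        assert lo < stat(ts) < hi

    def test_small_n_boot_warns_but_computes(self, pure_cfg, caplog):
        import logging

        ts = simulate_trials(pure_cfg, seed=56)
        with caplog.at_level(logging.WARNING):
            lo, hi = bootstrap_ci(ts, lambda t: float(np.median(t.latencies_ms)),
                                  n_boot=50, seed=9)
        assert lo <= hi
        assert any("n_boot" in r.message for r in caplog.records)

    def test_coverage_of_mean_promptness(self, pure_cfg):
        # 95% percentile interval for m should cover the truth ~95% of the
        # time; binomial 3-sigma band around 0.95 at 200 replicates.
        cfg = pure_cfg.model_copy(update={"n_trials": 200})
        stat = lambda t: fit_recinormal(t).params.m
        covered = 0
        for rep in range(200):
            ts = simulate_trials(cfg, seed=60_000 + rep)
            lo, hi = bootstrap_ci(ts, stat, n_boot=199, seed=rep)
            covered += lo <= 5.0 <= hi
        rate = covered / 200
        assert abs(rate - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / 200) + 0.01
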