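"""Model fits, BIC selection, thresholds, acceleration, increments, regressions."""

import numpy as np
import pytest

from mupool.ratecoding import (
    ModelFit,
    RampObservation,
    RateCodingProfile,
    bic,
    fit_candidates,
    initial_acceleration,
    instantaneous_rates,
    plateau_mean_rate,
    pool_regressions,
    pooled_thresholds,
    rate_increments,
    select_best,
    threshold_group,
    thresholds,
)
from mupool.synth import ForceProtocol, build_force_profile, generate_spike_trains

from conftest import make_pool

FS = 2048.0


class TestInstantaneousRates:
    def test_constant_isi_gives_constant_rate(self):
        t, r = instantaneous_rates(np.arange(0, 4096, 205), FS)
        np.testing.assert_allclose(r, FS / 205)

    def test_two_discharges_one_rate(self):
        t, r = instantaneous_rates(np.array([100, 300]), FS)
        assert r.size == 1 and t[0] == 300

    def test_fewer_than_two_discharges_empty(self):
        t, r = instantaneous_rates(np.array([42]), FS)
        assert r.size == 0

    def test_mean_rate_close_to_count_rate_under_jitter(self):
        pool = make_pool(rt=5.0, a=4.0, b=8.0, isi_cov=0.15)
        force = np.full(int(30 * FS), 25.0)
        (train,) = generate_spike_trains(pool, force, FS, seed=21)
        _, r = instantaneous_rates(train, FS)
        count_rate = (train.size - 1) / ((train[-1] - train[0]) / FS)
        assert np.mean(r) == pytest.approx(count_rate, rel=0.03)


class TestBIC:
    def test_printed_formula(self):
        assert bic(100.0, 100, 2) == pytest.approx(2 * np.log(100), abs=1e-12)

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sse = float(rng.uniform(0.1, 1e4))
            n = int(rng.integers(1, 5000))
            p = int(rng.integers(1, 5))
            assert bic(sse, n, p) == pytest.approx(
                n * np.log(sse / n) + p * np.log(n), abs=1e-12
            )

    def test_n_equal_one_reduces_to_log_sse(self):
        assert bic(7.5, 1, 3) == pytest.approx(np.log(7.5), abs=1e-12)

    def test_parameter_penalty_is_log_n_per_parameter(self):
        base = bic(50.0, 200, 2)
        assert bic(50.0, 200, 4) - base == pytest.approx(2 * np.log(200), abs=1e-12)

    def test_zero_sse_sentinel(self):
        assert bic(0.0, 10, 2) == float("-inf")


class TestFitCandidates:
    def test_exact_log_data_recovered(self):
        f = np.linspace(5, 60, 200)
        obs = RampObservation(force=f, rate=3.0 * np.log(f) + 7.0)
        fits = fit_candidates(obs)
        a, b = fits["natural_log"].params
        assert a == pytest.approx(3.0, abs=1e-6)
        assert b == pytest.approx(7.0, abs=1e-6)
        assert fits["natural_log"].sse < fits["linear"].sse

    def test_exact_linear_data_recovered(self):
        f = np.linspace(5, 60, 200)
        obs = RampObservation(force=f, rate=0.5 * f + 2.0)
        fits = fit_candidates(obs)
        a, b = fits["linear"].params
        assert a == pytest.approx(0.5, abs=1e-9)
        assert b == pytest.approx(2.0, abs=1e-9)
        assert fits["linear"].sse < fits["natural_log"].sse

    def test_constant_rate_degenerates_gracefully(self):
        f = np.linspace(5, 60, 50)
        obs = RampObservation(force=f, rate=np.full(50, 12.0))
        fits = fit_candidates(obs)
        assert fits["linear"].params[0] == pytest.approx(0.0, abs=1e-9)
        assert "rising_exponential" in fits  # present, possibly flagged

    def test_nonpositive_forces_rejected(self):
        obs = RampObservation(force=np.array([0.0, 1, 2, 3, 4]), rate=np.ones(5))
        with pytest.raises(ValueError):
            fit_candidates(obs)


class TestSelectBest:
    def test_log_generated_data_selects_log(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(20):
            f = np.linspace(5, 70, 500)
            r = 4.0 * np.log(f) + 8.0 + rng.normal(0, 0.5, 500)
            if select_best(fit_candidates(RampObservation(f, r))) == "natural_log":
                wins += 1
        assert wins >= 19

    def test_linear_generated_data_selects_linear(self):
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(20):
            f = np.linspace(5, 70, 500)
            r = 0.3 * f + 6.0 + rng.normal(0, 0.5, 500)
            if select_best(fit_candidates(RampObservation(f, r))) == "linear":
                wins += 1
        assert wins >= 19

    def test_single_converged_fit_wins(self):
        lone = ModelFit("linear", (1.0, 0.0), 10.0, 50, 2, True)
        dead = ModelFit("rising_exponential", (np.nan,) * 3, np.inf, 50, 3, False)
        assert select_best({"linear": lone, "rising_exponential": dead}) == "linear"

    def test_no_converged_fit_sentinel(self):
        dead = ModelFit("linear", (np.nan, np.nan), np.inf, 50, 2, False)
        assert select_best({"linear": dead}) is None


class TestInitialAcceleration:
    def test_direct_evaluation(self):
        fit = ModelFit("natural_log", (5.0, 2.0), 1.0, 100, 2, True)
        force_domain, time_domain = initial_acceleration(fit, rt=10.0, ramp_rate=5.0)
        assert force_domain == pytest.approx(0.5)
        assert time_domain == pytest.approx(2.5)

    def test_matches_analytic_derivative_of_fit(self):
        fit = ModelFit("natural_log", (3.7, 1.1), 1.0, 100, 2, True)
        rt = 17.3
        force_domain, _ = initial_acceleration(fit, rt)
        eps = 1e-7
        hi = fit.predict(np.array([rt + eps]))[0]
        lo = fit.predict(np.array([rt - eps]))[0]
        numeric = (hi - lo) / (2 * eps)
        assert abs(force_domain - numeric) < 1e-6

    def test_zero_a_gives_zero(self):
        fit = ModelFit("natural_log", (0.0, 9.0), 1.0, 100, 2, True)
        assert initial_acceleration(fit, 20.0) == (0.0, 0.0)

    def test_invalid_rt(self):
        fit = ModelFit("natural_log", (5.0, 2.0), 1.0, 100, 2, True)
        with pytest.raises(ValueError):
            initial_acceleration(fit, 0.0)


class TestThresholds:
    def test_noise_free_thresholds_match_generator(self):
        pool = make_pool(rt=30.0, a=4.0, b=8.0, isi_cov=0.0)
        force = build_force_profile(50.0, ForceProtocol(target=50.0, fs=FS))
        (train,) = generate_spike_trains(pool, force, FS, seed=0)
        rt, drt = thresholds(train, force, 50.0)
        # within one traversal ISI of the true threshold
        isi_pct = 5.0 / pool.rate_at(0, 30.0)
        assert rt == pytest.approx(30.0, abs=5 * isi_pct)
        assert drt == pytest.approx(30.0, abs=5 * isi_pct)

    def test_negative_drt_offset_creates_positive_hysteresis(self):
        pool = make_pool(rt=30.0, a=4.0, b=8.0, isi_cov=0.0, drt_offset=-5.0)
        force = build_force_profile(50.0, ForceProtocol(target=50.0, fs=FS))
        (train,) = generate_spike_trains(pool, force, FS, seed=0)
        rt, drt, hyst = pooled_thresholds([thresholds(train, force, 50.0)])
        assert hyst == pytest.approx(5.0, abs=1.0)

    def test_unit_never_recruited_flagged(self):
        force = build_force_profile(20.0, ForceProtocol(target=20.0, fs=FS))
        rt, drt = thresholds(np.array([], dtype=int), force, 20.0)
        assert np.isnan(rt) and np.isnan(drt)

    def test_plateau_only_unit_flagged(self):
        force = build_force_profile(20.0, ForceProtocol(target=20.0, fs=FS))
        plat = np.flatnonzero(force >= 20.0 - 1e-9)
        train = plat[::300][:10]
        rt, drt = thresholds(train, force, 20.0)
        assert np.isnan(rt) and np.isnan(drt)


class TestPlateauAndIncrements:
    def test_constant_train_rate(self):
        spikes = np.arange(0, 40960, int(FS / 12))
        assert plateau_mean_rate(spikes, FS, (0, 40960)) == pytest.approx(12.0, rel=0.01)

    def test_empty_plateau_sentinel(self):
        assert np.isnan(plateau_mean_rate(np.array([5]), FS, (0, 100)))

    def test_generator_plateau_rate_matches_formula(self):
        rng_rates = []
        f0 = 30.0
        pool = make_pool(rt=5.0, a=4.0, b=8.0, isi_cov=0.15)
        force = np.full(int(20 * FS), f0)
        for seed in range(100):
            (train,) = generate_spike_trains(pool, force, FS, seed=seed)
            rng_rates.append(plateau_mean_rate(train, FS, (0, force.size)))
        assert np.mean(rng_rates) == pytest.approx(4.0 * np.log(f0) + 8.0, rel=0.03)

    def test_increment_arithmetic(self):
        incs, mean = rate_increments({10.0: 10.0, 20.0: 13.0, 30.0: 16.0})
        assert [d for _, d in incs] == [pytest.approx(3.0), pytest.approx(3.0)]
        assert mean == pytest.approx(3.0)

    def test_single_level_no_increment(self):
        incs, mean = rate_increments({10.0: 10.0})
        assert incs == [] and np.isnan(mean)

    def test_gap_in_tracking_skipped(self):
        incs, _ = rate_increments({10.0: 10.0, 30.0: 16.0})
        assert incs == []


def _profile(uid, rt, accel=None, inc=None, drt=None):
    return RateCodingProfile(
        unit_id=uid,
        rt=rt,
        drt=rt if drt is None else drt,
        hysteresis=0.0 if drt is None else rt - drt,
        group=threshold_group(rt),
        best_model_up="natural_log",
        best_model_down=None,
        fits_up={},
        init_accel_force=np.nan if accel is None else accel / 5.0,
        init_accel_time=np.nan if accel is None else accel,
        plateau_rates={},
        increments=[],
        mean_increment=np.nan if inc is None else inc,
    )


class TestPoolRegressions:
    def test_exact_inverse_relation_fits_perfectly(self):
        rts = np.linspace(2, 70, 40)
        profiles = [_profile(i, rt, accel=12.0 / rt, inc=0.1 * rt) for i, rt in enumerate(rts)]
        pools = pool_regressions(profiles)
        assert not pools.skipped
        assert pools.accel_vs_rt["adjusted_r2"] > 0.99
        assert pools.accel_vs_rt["c"] == pytest.approx(12.0, rel=1e-6)

    def test_null_increments_show_no_correlation(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            rts = rng.uniform(2, 70, 120)
            profiles = [
                _profile(i, rt, accel=12.0 / rt, inc=float(rng.normal(3.0, 1.0)))
                for i, rt in enumerate(rts)
            ]
            pools = pool_regressions(profiles)
            if abs(pools.increment_vs_rt["pearson_r"]) < 0.2:
                hits += 1
        assert hits >= 90

    def test_equal_thresholds_give_identity_line(self):
        rts = np.linspace(2, 70, 25)
        profiles = [_profile(i, rt, accel=12.0 / rt, inc=1.0) for i, rt in enumerate(rts)]
        pools = pool_regressions(profiles)
        slope, intercept = pools.rt_vs_drt["linear"]
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-7)

    def test_undersized_pool_skipped(self):
        pools = pool_regressions([_profile(0, 10.0, accel=1.0, inc=1.0)])
        assert pools.skipped


class TestGrouping:
    @pytest.mark.parametrize(
        "rt,group", [(5.0, "low"), (25.0, "low"), (30.0, "medium"), (60.0, "high")]
    )
    def test_threshold_groups(self, rt, group):
        assert threshold_group(rt) == group
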