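"""MSD/diffusion estimation, salt slope, behavior calls, survival fits."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize

from curtainkit.dynamics import (
    classify_behavior,
    classify_behaviors,
    compute_msd,
    estimate_d,
    fit_survival,
    salt_slope,
)
from curtainkit.presets import get_preset
from curtainkit.simulate import (
    DwellSample,
    make_behavior_fixtures,
    simulate_dwell_times,
    simulate_trajectory,
)

DT = 0.05


def brute_force_msd(y, n_max, dt):
    """Independent oracle: literal double loop over (i, n) pairs."""
    y = np.asarray(y, float)
    big_n = len(y)
    out = []
    for n in range(1, n_max + 1):
        acc = 0.0
        for i in range(big_n - n):
            acc += (y[i + n] - y[i]) ** 2
        out.append(acc / (big_n - n))
    return np.array(out)


class TestComputeMSD:
    def test_constant_trajectory_zero_msd(self):
        msd = compute_msd(np.full(50, 3.0), n_max=10, dt_s=DT)
        assert np.all(msd.msd_um2 == 0.0)

    def test_hand_evaluated_three_point_example(self):
        msd = compute_msd(np.array([0.0, 1.0, 2.0]), n_max=2, dt_s=DT)
        assert msd.msd_um2[0] == pytest.approx(1.0)
        assert msd.msd_um2[1] == pytest.approx(4.0)

    def test_time_reversal_symmetry(self, rng):
        y = rng.standard_normal(200).cumsum()
        a = compute_msd(y, 10, dt_s=DT).msd_um2
        b = compute_msd(y[::-1], 10, dt_s=DT).msd_um2
        assert np.allclose(a, b, rtol=0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            y = rng.standard_normal(rng.integers(15, 60)).cumsum()
            fast = compute_msd(y, 10, dt_s=DT).msd_um2
            assert np.allclose(fast, brute_force_msd(y, 10, DT), rtol=0, atol=1e-10)

    def test_short_trajectory_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="at least 11"):
            compute_msd(np.zeros(10), n_max=10, dt_s=DT)


class TestEstimateD:
    def test_exact_line_recovers_d(self):
        t = DT * np.arange(1, 11)
        msd = compute_msd(np.zeros(20), 10, dt_s=DT)
        msd = dataclasses.replace(msd, msd_um2=2 * 0.5 * t)
        est = estimate_d(msd)
        assert est.d_um2_s == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_flat_msd_clipped_to_zero(self):
        msd = compute_msd(np.zeros(20), 10, dt_s=DT)
        msd = dataclasses.replace(msd, msd_um2=np.full(10, 0.3))
        est = estimate_d(msd)
        assert est.d_um2_s == 0.0
        # a perfectly flat curve fits slope 0, which is reported as D=0
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_nmax_beyond_available_intervals(self):
        msd = compute_msd(np.zeros(20), 5, dt_s=DT)
        with pytest.raises(ValueError):
            estimate_d(msd, n_max=10)

    def test_fixed_intercept_mode(self):
        t = DT * np.arange(1, 11)
        msd = compute_msd(np.zeros(20), 10, dt_s=DT)
        msd = dataclasses.replace(msd, msd_um2=2 * 0.3 * t)
        est = estimate_d(msd, fit_intercept=False)
        assert est.d_um2_s == pytest.approx(0.3, abs=1e-12)
        assert est.intercept == 0.0


class TestDiffusionRecovery:
    def test_noise_free_bias_below_5pct(self, diffusion_preset):
        rng = np.random.default_rng(21)
        ds = []
        for _ in range(200):
            t = simulate_trajectory(diffusion_preset, 0.1, 2000, 6.5, rng,
                                    localization_noise=False)
            ds.append(estimate_d(compute_msd(t, 10)).d_um2_s)
        assert abs(np.mean(ds) / 0.1 - 1.0) < 0.05

    def test_localization_noise_absorbed_by_intercept(self, diffusion_preset):
        rng = np.random.default_rng(22)
        slopes, intercepts = [], []
        for _ in range(200):
            t = simulate_trajectory(diffusion_preset, 0.1, 2000, 6.5, rng,
                                    localization_noise=True)
            est = estimate_d(compute_msd(t, 10))
            slopes.append(est.slope)
            intercepts.append(est.intercept)
        assert abs(np.mean(slopes) / (2 * 0.1) - 1.0) < 0.10
        sigma = diffusion_preset.optics.loc_sigma_um
        assert np.mean(intercepts) == pytest.approx(2 * sigma**2, rel=0.5)

    def test_mean_fitted_d_within_3se(self, diffusion_preset):
        ds = []
        for seed in range(50):
            t = simulate_trajectory(diffusion_preset, 0.1, 2000, 6.5, seed,
                                    localization_noise=False)
            ds.append(estimate_d(compute_msd(t, 10)).d_um2_s)
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - 0.1) < 3 * se


class TestSaltSlope:
    def test_constant_d_gives_zero_slope(self):
        series = {50.0: np.full(30, 0.5), 75.0: np.full(30, 0.5),
                  100.0: np.full(30, 0.5)}
        slope, _ = salt_slope(series)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_means_recovered(self):
        spread = np.linspace(-0.01, 0.01, 31)
        series = {c: 0.2 + 0.1 * (c - 50.0) + spread for c in (50.0, 60.0, 70.0)}
        slope, se = salt_slope(series)
        assert slope == pytest.approx(0.1, abs=1e-10)
        assert se > 0

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            salt_slope({50.0: np.full(30, 0.5)})

    def test_small_groups_warn(self):
        with pytest.warns(UserWarning):
            salt_slope({50.0: np.full(5, 0.4), 60.0: np.full(5, 0.5)})


SITE = 21.3


class TestClassifyBehavior:
    # 12-case golden fixture set with hand labels
    GOLDEN = [
        (np.full(120, SITE + 10.0), "no_encounter"),
        (np.full(120, SITE) + 0.05 * np.sin(np.arange(120) / 5), "captured"),
        (np.linspace(SITE - 5, SITE + 5, 120), "bypass"),
        (np.linspace(SITE + 5, SITE - 5, 120), "bypass"),
        (np.concatenate([np.linspace(SITE - 5, SITE - 0.5, 60),
                         np.linspace(SITE - 0.5, SITE - 5, 60)]), "blocked"),
        (np.concatenate([np.linspace(SITE + 5, SITE + 0.5, 60),
                         np.linspace(SITE + 0.5, SITE + 5, 60)]), "blocked"),
        (np.concatenate([np.full(10, SITE), np.linspace(SITE, SITE + 4, 55),
                         np.linspace(SITE + 4, SITE - 4, 55)]), "bypass"),
        (np.concatenate([np.full(10, SITE), np.linspace(SITE, SITE + 4, 110)]),
         "blocked"),
        (np.full(120, SITE + 1.4), "captured"),
        (np.concatenate([np.linspace(SITE - 4, SITE - 1, 40),
                         np.linspace(SITE - 1, SITE - 3, 40),
                         np.linspace(SITE - 3, SITE - 1, 40)]), "blocked"),
        (np.full(120, SITE - 1.6), "no_encounter"),
        (np.linspace(SITE - 1.0, SITE + 5, 120), "blocked"),
    ]

    @pytest.mark.parametrize("y,expected", GOLDEN,
                             ids=[f"case{i}" for i in range(len(GOLDEN))])
    def test_golden_fixture_labels(self, y, expected):
        call = classify_behavior(y, SITE)
        assert call.label == expected

    def test_flap_fixture_percentages(self):
        p = get_preset("yPCNA_flap_dynamics")
        fixtures = make_behavior_fixtures(p)
        stats = classify_behaviors([t for t, _ in fixtures], SITE)
        assert stats["n_total"] == 40
        assert stats["pct_blocked"] == pytest.approx(90.0)
        assert stats["pct_captured"] == pytest.approx(5.0)
        assert stats["pct_bypass"] == pytest.approx(5.0)

    def test_classifier_agrees_with_fixture_labels(self):
        for name in ("yPCNA_flap_dynamics", "yPCNA_cag13_dynamics",
                     "yPCNA_homoduplex_dynamics"):
            for traj, truth in make_behavior_fixtures(get_preset(name)):
                assert classify_behavior(traj, SITE).label == truth


class TestFitSurvival:
    def test_identical_uncensored_dwells_exact(self):
        s = DwellSample(np.full(20, 7.0), np.zeros(20, bool))
        fit = fit_survival(s, n_resamples=200, seed=1)
        assert fit.t_half_s == pytest.approx(7.0 * np.log(2), rel=1e-12)

    def test_uncensored_mle_is_log2_times_mean(self):
        s = simulate_dwell_times(21.0, 500, np.inf, seed=4)
        fit = fit_survival(s, n_resamples=0)
        assert fit.t_half_s == pytest.approx(np.log(2) * s.times_s.mean(), rel=1e-12)

    def test_censored_mle_is_total_time_over_events(self):
        s = simulate_dwell_times(327.0, 100, 600.0, seed=5)
        fit = fit_survival(s, n_resamples=0)
        expected = np.log(2) * s.times_s.sum() / s.n_events
        assert fit.t_half_s == pytest.approx(expected, rel=1e-12)

    def test_censored_mle_matches_numerical_likelihood_optimum(self):
        # independent oracle: direct minimization of the censored
        # exponential negative log-likelihood
        s = simulate_dwell_times(50.0, 200, 80.0, seed=6)

        def nll(log_tau):
            tau = np.exp(log_tau)
            ll = -s.times_s.sum() / tau - s.n_events * np.log(tau)
            return -ll

        res = optimize.minimize_scalar(nll, bounds=(0.0, 10.0), method="bounded")
        tau_hat = np.exp(res.x)
        fit = fit_survival(s, n_resamples=0)
        assert fit.t_half_s == pytest.approx(np.log(2) * tau_hat, rel=1e-5)

    def test_all_censored_raises(self):
        s = DwellSample(np.full(10, 5.0), np.ones(10, bool))
        with pytest.raises(ValueError, match="censored"):
            fit_survival(s)

    def test_bootstrap_ci_contains_point(self):
        s = simulate_dwell_times(21.0, 63, 600.0, seed=7)
        fit = fit_survival(s, n_resamples=500, seed=7)
        assert fit.ci_low_s < fit.t_half_s < fit.ci_high_s

    def test_lsq_method_close_to_mle_on_clean_data(self):
        s = simulate_dwell_times(21.0, 2000, np.inf, seed=8)
        mle = fit_survival(s, n_resamples=0, method="mle")
        lsq = fit_survival(s, n_resamples=0, method="lsq")
        assert lsq.t_half_s == pytest.approx(mle.t_half_s, rel=0.1)
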