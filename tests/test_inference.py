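import numpy as np
import pytest

from ppas.exposure import cs_from_extraction
from ppas.inference import (
    changepoint_check,
    estimate_capacity,
    fit_uptake,
    linear_phase_slope,
    recovery_study,
    slope_to_air_concentration,
)
from ppas.sampler_model import simulate_uptake
from ppas.synthetic import ScenarioConfig, emission_profile, generate_experiment
from ppas.units import ppbv_to_molar


def saturating_observations(params, n=12, end_h=6.0, ppbv=2000.0):
    """Noise-free C_s observations spanning the linear and plateau phases."""
    from ppas.ptrms import AirConcentrationSeries

    air = AirConcentrationSeries(np.array([0.0, end_h * 60]), np.array([ppbv, ppbv]))
    times = np.linspace(0.5, end_h, n)
    traj = simulate_uptake(params, air, duration_h=end_h, t_eval=np.concatenate(([0.0], times)))
    return times, traj.cs_at(times), air


class TestFitUptake:
    def test_self_consistency_from_truth(self, params):
        times, cs, air = saturating_observations(params)
        fit = fit_uptake(times, cs, air, params)
        assert fit.residual_rms < 1e-6
        assert fit.estimates["k_O"] == pytest.approx(params.k_O, rel=1e-3)
        assert fit.estimates["C_cap"] == pytest.approx(params.C_cap, rel=1e-3)

    def test_recovers_truth_from_perturbed_init(self, params):
        """Identifiable noise-free problem: 3x-perturbed start returns to truth."""
        times, cs, air = saturating_observations(params)
        init = params.with_(k_O=3 * params.k_O, C_cap=params.C_cap / 3)
        fit = fit_uptake(times, cs, air, init)
        assert fit.estimates["k_O"] == pytest.approx(params.k_O, rel=0.01)
        assert fit.estimates["C_cap"] == pytest.approx(params.C_cap, rel=0.01)
        assert fit.convergence_flag == "converged"

    def test_zero_observations_drive_k_O_to_lower_bound(self, params):
        times, _, air = saturating_observations(params, n=6)
        fit = fit_uptake(times, np.zeros_like(times), air, params, free=("k_O",))
        assert fit.convergence_flag == "boundary"
        assert fit.estimates["k_O"] <= 0.02

    def test_estimates_stay_positive_and_fixed_recorded(self, params):
        times, cs, air = saturating_observations(params, n=8)
        fit = fit_uptake(times, cs, air, params)
        assert all(v > 0 for v in fit.estimates.values())
        assert "K_SA" in fit.fixed_params and "k_reac" in fit.fixed_params

    def test_too_few_observations_rejected(self, params):
        times, cs, air = saturating_observations(params, n=3)
        with pytest.raises(ValueError, match="at least 4"):
            fit_uptake(times, cs, air, params)


class TestEstimateCapacity:
    def test_flat_tail_mean(self):
        t = np.array([10.0, 11.0, 12.0, 13.0])
        c = np.array([1.7, 1.79, 1.80, 1.81])
        assert estimate_capacity(t, c) == pytest.approx(1.80, rel=1e-9)

    def test_strictly_rising_series_not_plateaued(self):
        t = np.linspace(0, 5, 10)
        assert estimate_capacity(t, 0.5 * t) is None

    def test_constant_series_returns_constant(self):
        t = np.linspace(0, 5, 6)
        assert estimate_capacity(t, np.full(6, 1.3)) == pytest.approx(1.3)

    def test_model_plateau_recovered_within_tolerance(self, params):
        times, cs, _ = saturating_observations(params, n=20, end_h=10.0, ppbv=4000.0)
        cap = estimate_capacity(times, cs)
        assert cap is not None
        assert cap == pytest.approx(params.C_cap, rel=0.02)

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(ValueError):
            estimate_capacity([1.0, 0.5, 2.0], [1, 2, 3])


class TestLinearPhaseSlope:
    def test_exact_line(self):
        t = np.linspace(0, 4, 9)
        fit = linear_phase_slope(t, 2.0 * t)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        fit = linear_phase_slope([1.0, 2.0], [3.0, 5.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == 1.0

    def test_slope_maps_to_air_concentration(self, params, cond):
        """Linear-regime identity: dC_s/dt = R_s·C_A/V_s."""
        from ppas.ptrms import AirConcentrationSeries

        air = AirConcentrationSeries(np.array([0.0, 120.0]), np.array([500.0, 500.0]))
        times = np.linspace(0.1, 0.6, 6)
        traj = simulate_uptake(params, air, duration_h=0.6,
                               t_eval=np.concatenate(([0.0], times)))
        fit = linear_phase_slope(times, traj.cs_at(times))
        implied = slope_to_air_concentration(fit.slope, params, cond)
        assert implied == pytest.approx(500.0, rel=0.01)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            linear_phase_slope([1.0, 2.0, 3.0], [1, 2, 3], window=(5.0, 6.0))


class TestChangepoint:
    def test_gel_profile_split_near_lag(self):
        sc = ScenarioConfig(product_type="gel", plateau_ppbv=1000.0, seed=0)
        air = emission_profile(sc, duration_h=3.0, dt_min=1.0)
        rng = np.random.default_rng(0)
        noisy = np.maximum(air.ppbv * (1 + 0.05 * rng.standard_normal(air.ppbv.size)), 0)
        result = changepoint_check(air.time_min / 60.0, noisy)
        assert result.found
        assert abs(result.split_time - 1.5) <= 1.0 / 60 + 1e-9
        assert result.slope_late > result.slope_early

    def test_exact_line_reports_no_changepoint(self):
        t = np.linspace(0, 3, 20)
        result = changepoint_check(t, 5.0 + 2.0 * t)
        assert not result.found

    def test_matches_brute_force_enumeration(self):
        """The scan must equal independent exhaustive enumeration at small n."""
        rng = np.random.default_rng(4)
        t = np.linspace(0, 3, 15)
        c = np.where(t < 1.2, t, 1.2 + 5 * (t - 1.2)) * (1 + 0.03 * rng.standard_normal(15))

        w = 1.0 / np.maximum(np.abs(c), 0.05 * np.max(np.abs(c)))

        def wsse(ts, cs, ws):
            coef = np.polyfit(ts, cs, 1, w=ws)
            return np.sum((ws * (cs - np.polyval(coef, ts))) ** 2)

        best_k = min(range(2, t.size - 1),
                     key=lambda k: wsse(t[:k], c[:k], w[:k]) + wsse(t[k:], c[k:], w[k:]))
        result = changepoint_check(t, c)
        assert result.found
        assert result.split_time == pytest.approx(t[best_k])

    def test_false_positive_rate_on_noisy_linear_profiles(self):
        """<= 5% spurious detections over 200 seeded linear replicates."""
        t = np.arange(0, 181) / 60.0
        line = 1000.0 * t / 3.0
        false_positives = 0
        for s in range(200):
            rng = np.random.default_rng(50_000 + s)
            noisy = np.maximum(line * (1 + 0.05 * rng.standard_normal(t.size)), 0)
            if changepoint_check(t, noisy).found:
                false_positives += 1
        assert false_positives <= 10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            changepoint_check([0, 1, 2, 3], [0, 1, 2, 3])


class TestRecoveryStudy:
    SCENARIO = ScenarioConfig(product_type="stock_solution", plateau_ppbv=2000.0,
                              rise_rate=3.0, seed=1)
    TIMES = [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0]

    def test_noise_free_biases_vanish(self, params):
        table = recovery_study(params, self.SCENARIO, n_reps=2, noise_cv=0.0,
                               seed=1, deployment_times_h=self.TIMES)
        assert (table["rel_bias"].abs() < 0.01).all()

    def test_small_noise_keeps_small_bias(self, params):
        table = recovery_study(params, self.SCENARIO, n_reps=3, noise_cv=0.01,
                               seed=2, deployment_times_h=self.TIMES)
        assert (table["rel_bias"].abs() < 0.05).all()

    def test_same_seed_gives_identical_table(self, params):
        t1 = recovery_study(params, self.SCENARIO, n_reps=2, noise_cv=0.05,
                            seed=3, deployment_times_h=self.TIMES)
        t2 = recovery_study(params, self.SCENARIO, n_reps=2, noise_cv=0.05,
                            seed=3, deployment_times_h=self.TIMES)
        assert t1.equals(t2)

    def test_rejects_single_rep(self, params):
        with pytest.raises(ValueError):
            recovery_study(params, self.SCENARIO, n_reps=1, noise_cv=0.0,
                           seed=1, deployment_times_h=self.TIMES)
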