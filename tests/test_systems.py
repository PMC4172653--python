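"""Generator correctness: maps, flows, minimum maps, noises, contamination."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from hvgchaos.systems import (
    MAP_REGISTRY,
    DivergenceError,
    SystemSpec,
    contaminate,
    fgn_autocovariance,
    generate,
    generate_fbm,
    generate_fgn,
    generate_knoise,
    integrate_flow,
    iterate_map,
    minimum_map,
    schuster_map,
)


class TestIterateMap:
    def test_logistic_single_step_by_hand(self):
        series = iterate_map(
            SystemSpec("logistic", length=1, discard=0, initial_state=(0.1,))
        )
        assert series.values[0] == pytest.approx(4 * 0.1 * 0.9)

    def test_logistic_fixed_point_stays_constant(self):
        series = iterate_map(
            SystemSpec("logistic", length=5, discard=0, initial_state=(0.75,))
        )
        np.testing.assert_allclose(series.values, 0.75)

    @pytest.mark.parametrize("name", sorted(MAP_REGISTRY))
    def test_every_registered_map_runs_bounded(self, name):
        """Every registry entry iterates 2000 kept steps without divergence."""
        series = iterate_map(SystemSpec(name, length=2000, discard=1000, seed=0))
        assert len(series) == 2000
        assert np.all(np.isfinite(series.values))
        # a chaotic orbit should not be numerically frozen
        assert np.unique(series.values).size > 10

    def test_length_contract_after_discard(self):
        series = iterate_map(SystemSpec("henon", length=1000, discard=100))
        assert len(series) == 1000

    def test_logistic_values_stay_in_invariant_interval(self):
        series = iterate_map(SystemSpec("logistic", length=5000, discard=100, seed=3))
        assert series.values.min() >= 0 and series.values.max() <= 1

    def test_unknown_map_rejected(self):
        with pytest.raises(KeyError, match="unknown map"):
            iterate_map(SystemSpec("not_a_map", length=10))

    def test_divergent_orbit_reports_iteration_index(self):
        with pytest.raises(DivergenceError, match="iteration"):
            iterate_map(
                SystemSpec("logistic", params={"a": 4.5}, length=100, discard=0,
                           initial_state=(0.5,))
            )

    def test_multidimensional_coordinate_selector(self):
        x = iterate_map(SystemSpec("henon", length=50, discard=0,
                                   initial_state=(0.0, 0.9)), coordinate="x")
        y = iterate_map(SystemSpec("henon", length=50, discard=0,
                                   initial_state=(0.0, 0.9)), coordinate="y")
        # Henon's y is the delayed x
        np.testing.assert_allclose(y.values[1:], x.values[:-1])

    def test_logistic_arcsine_invariant_density(self):
        """Fraction of orbit in [0, 0.1] matches the arcsine law."""
        series = iterate_map(SystemSpec("logistic", length=100_000, discard=1000,
                                        seed=11))
        # integral of 1/(pi sqrt(x(1-x))) over [0, 0.1]
        expected = 2.0 / math.pi * math.asin(math.sqrt(0.1))
        observed = np.mean(series.values <= 0.1)
        # orbit samples are correlated; allow 3x the iid binomial sigma
        sigma = math.sqrt(expected * (1 - expected) / len(series))
        assert abs(observed - expected) < 3 * 3 * sigma


class TestSchusterMap:
    def test_one_step_by_hand(self):
        s = schuster_map(2.0, SystemSpec("schuster", length=1, discard=0,
                                         initial_state=(0.5,)))
        assert s.values[0] == pytest.approx(0.75)

    def test_z_one_is_doubling_map(self):
        s = schuster_map(1.0, SystemSpec("schuster", length=1, discard=0,
                                         initial_state=(0.3,)))
        assert s.values[0] == pytest.approx(0.6)

    def test_laminar_phase_near_zero(self):
        """Starting at 1e-4 with z=2 the orbit creeps: 1e3 increments < 1e-7."""
        s = schuster_map(2.0, SystemSpec("schuster", length=1001, discard=0,
                                         initial_state=(1e-4,)))
        increments = np.diff(s.values)
        assert np.all(increments[:1000] < 1e-7)
        assert np.all(increments[:1000] > 0)

    def test_output_in_unit_interval_and_seeded(self):
        a = schuster_map(2.0, length=500, seed=4)
        b = schuster_map(2.0, length=500, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.min() >= 0 and a.values.max() < 1

    def test_z_below_one_rejected(self):
        with pytest.raises(ValueError):
            schuster_map(0.5, length=10)


class TestFlows:
    def test_lorenz_origin_is_fixed_point(self):
        traj = integrate_flow("lorenz", dt=0.01, n_steps=100, x0=(0, 0, 0))
        np.testing.assert_allclose(traj.states, 0.0)

    def test_linear_decay_matches_closed_form(self):
        rhs = lambda s, p: -s  # noqa: E731
        traj = integrate_flow(rhs, dt=0.01, n_steps=100, x0=(1.0,))
        assert traj.states[-1, 0] == pytest.approx(math.exp(-1), abs=1e-6)

    def test_rk4_fourth_order_convergence(self):
        """Halving dt shrinks the endpoint error by about 2^4."""
        reference = integrate_flow("lorenz", dt=0.0005, n_steps=4000,
                                   x0=(1.0, 1.0, 1.0)).states[-1]
        coarse = integrate_flow("lorenz", dt=0.004, n_steps=500,
                                x0=(1.0, 1.0, 1.0)).states[-1]
        fine = integrate_flow("lorenz", dt=0.002, n_steps=1000,
                              x0=(1.0, 1.0, 1.0)).states[-1]
        ratio = np.linalg.norm(coarse - reference) / np.linalg.norm(fine - reference)
        assert 8 < ratio < 32

    def test_unknown_flow_rejected(self):
        with pytest.raises(KeyError):
            integrate_flow("duffing", dt=0.01, n_steps=5, x0=(0, 0, 0))


class TestMinimumMap:
    def test_hand_enumerated_minima(self):
        traj = _series_traj([3, 1, 2, 0, 5])
        np.testing.assert_array_equal(minimum_map(traj).values, [1, 0])

    def test_monotone_input_yields_empty(self):
        traj = _series_traj([1, 2, 3, 4, 5])
        assert len(minimum_map(traj)) == 0

    def test_sampled_sine_minima(self):
        t = np.arange(0, 6 * 2 * math.pi, 0.01)
        traj = _series_traj(np.sin(t), times=t)
        minima = minimum_map(traj).values
        assert minima.size == 6
        np.testing.assert_allclose(minima, -1.0, atol=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            minimum_map(_series_traj([1, 2]))


def _series_traj(values, times=None):
    from hvgchaos.systems import Trajectory

    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) if times is None else times
    return Trajectory(times=times, states=values[:, None],
                      coordinate_names=("x",))


class TestKNoise:
    def test_k_zero_is_standardized_white(self):
        s = generate_knoise(0.0, length=2**12, seed=9)
        assert s.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.values.std() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0, 3.0])
    def test_periodogram_slope_recovers_k(self, k):
        s = generate_knoise(k, length=2**15, seed=9)
        freqs = np.fft.rfftfreq(len(s))[1:]
        power = np.abs(np.fft.rfft(s.values))[1:] ** 2
        slope = sps.linregress(np.log(freqs), np.log(power)).slope
        assert abs(slope + k) < 0.3

    def test_determinism(self):
        a = generate_knoise(2.0, length=2**10, seed=5)
        b = generate_knoise(2.0, length=2**10, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            generate_knoise(-1.0, length=64)


class TestFractionalProcesses:
    @pytest.mark.parametrize("H", [0.2, 0.5, 0.8])
    def test_fbm_starts_at_zero(self, H):
        assert generate_fbm(H, length=100, seed=1).values[0] == 0.0

    def test_fgn_h_half_is_uncorrelated(self):
        x = generate_fgn(0.5, length=100_000, seed=2).values
        acf1 = np.mean(x[:-1] * x[1:]) / x.var()
        assert abs(acf1) < 0.02

    def test_fgn_covariance_matches_closed_form(self):
        """Mean sample covariance at lags 1-5 within 3 SE of the fGn kernel."""
        H, n, reps = 0.8, 20_000, 20
        lags = np.arange(1, 6)
        estimates = np.empty((reps, lags.size))
        for r in range(reps):
            x = generate_fgn(H, length=n, seed=300 + r).values
            for i, lag in enumerate(lags):
                estimates[r, i] = np.mean(x[:-lag] * x[lag:])
        mean = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / math.sqrt(reps)
        theory = fgn_autocovariance(H, lags)
        assert np.all(np.abs(mean - theory) < 3 * se)

    def test_fbm_variance_scaling_recovers_hurst(self):
        """var(B(t)) ~ t^2H: log-log regression over t in 1..64."""
        H, reps = 0.7, 50
        t = np.arange(1, 65)
        paths = np.array(
            [generate_fbm(H, length=65, seed=500 + r).values for r in range(reps)]
        )
        log_second_moment = np.log((paths[:, t] ** 2).mean(axis=0))
        slope = sps.linregress(np.log(t), log_second_moment).slope
        assert abs(slope / 2 - H) < 0.05

    @pytest.mark.parametrize("H", [0.0, 1.0, -0.2, 1.3])
    def test_hurst_out_of_range_rejected(self, H):
        with pytest.raises(ValueError):
            generate_fgn(H, length=16)


class TestContaminate:
    def test_zero_amplitude_is_identity(self):
        s = generate("logistic", length=100, seed=1)
        assert contaminate(s, 0.0, seed=1) is s

    def test_noise_is_zero_mean(self):
        s = generate("logistic", length=100_000, seed=1)
        noisy = contaminate(s, 1.0, seed=1)
        assert np.mean(noisy.values - s.values) == pytest.approx(0.0, abs=0.005)

    def test_variance_additivity(self):
        s = generate("logistic", length=100_000, seed=1)
        noisy = contaminate(s, 0.8, seed=2)
        expected = s.values.var() + 0.8**2 * (1.0 / 12.0)
        assert noisy.values.var() == pytest.approx(expected, rel=0.05)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            contaminate(generate("logistic", length=10, seed=1), -0.1)


class TestDispatch:
    @pytest.mark.parametrize(
        "name,params",
        [("logistic", {}), ("schuster", {"z": 1.5}), ("knoise", {"k": 1.0}),
         ("fgn", {"hurst": 0.6}), ("fbm", {"hurst": 0.4}),
         ("logistic_noisy", {"amplitude": 0.5})],
    )
    def test_generate_is_pure_function_of_spec(self, name, params):
        a = generate(name, params, length=512, seed=42)
        b = generate(name, params, length=512, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_system_rejected(self):
        with pytest.raises(KeyError):
            generate("nope", length=10)

    def test_flow_minimum_series_lengths(self):
        s = generate("lorenz_min", length=300, discard=20, seed=0)
        assert len(s) == 300
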