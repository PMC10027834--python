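import numpy as np
import pytest

from groupsync import (
    ARParams,
    KuramotoParams,
    add_correlated_noise,
    ar_is_stationary,
    generate_ar,
    generate_ar_series,
    generate_kuramoto,
    order_parameter,
    sample_kuramoto_collection,
)


class TestGenerateAR:
    def test_zero_noise_zero_bias_stays_at_fixed_point(self, rng):
        x = generate_ar(ARParams(phi_1=0.5, phi_2=0.3, c=0.0, epsilon=0.0, length=50), rng)
        assert np.array_equal(x, np.zeros(50))

    def test_pure_bias_is_constant_after_startup(self, rng):
        x = generate_ar(ARParams(phi_1=0.0, phi_2=0.0, c=1.0, epsilon=0.0, length=20), rng)
        assert np.array_equal(x[2:], np.ones(18))

    def test_deterministic_recursion_matches_hand_iteration(self, rng):
        params = ARParams(phi_1=0.5, phi_2=-0.1, c=1.0, epsilon=0.0, length=12)
        x = generate_ar(params, rng)
        expected = np.zeros(12)
        for t in range(2, 12):
            expected[t] = 1.0 + 0.5 * expected[t - 1] - 0.1 * expected[t - 2]
        assert np.allclose(x, expected, atol=1e-15)

    def test_nonstationary_coefficients_warn(self, rng):
        assert ar_is_stationary(0.8, -0.2)
        assert not ar_is_stationary(1.2, 0.0)
        with pytest.warns(UserWarning, match="nonstationary"):
            generate_ar(ARParams(phi_1=1.2, phi_2=0.0, length=10), rng)

    def test_multivariate_stack_shape(self, rng):
        series = generate_ar_series(5, ARParams(length=300), rng)
        assert series.values.shape == (5, 300)


class TestCorrelatedNoise:
    def test_zero_sd_is_identity(self, rng, toy_series):
        assert np.array_equal(add_correlated_noise(toy_series, 0.0, rng).values, toy_series)

    def test_cross_variable_differences_unchanged(self, rng, toy_series):
        noisy = add_correlated_noise(toy_series, 2.0, rng).values
        assert np.allclose(noisy[0] - noisy[1], toy_series[0] - toy_series[1], atol=1e-12)
        assert np.allclose(noisy[1] - noisy[2], toy_series[1] - toy_series[2], atol=1e-12)

    def test_unit_noise_on_standardized_inputs_gives_half_correlation(self, rng):
        values = rng.normal(size=(2, 200_000))
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        noisy = add_correlated_noise(values, 1.0, rng).values
        r = np.corrcoef(noisy)[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)  # s^2/(s^2+1) with s=1


class TestGenerateKuramoto:
    def test_uncoupled_noiseless_phases_advance_linearly(self, rng):
        omegas = np.array([1.0, 2.0, 0.5])
        init = np.array([0.0, 1.0, -1.0])
        params = KuramotoParams(K=0.0, omegas=omegas, initial_phases=init,
                                alpha=0.0, d_t=0.05, length=100)
        _, phases = generate_kuramoto(params, rng)
        t = np.arange(100)
        expected = init[:, None] + t * 0.05 * omegas[:, None]
        unwrapped = np.unwrap(phases.angles, axis=1)
        assert np.allclose(unwrapped, expected, atol=1e-10)

    def test_identical_frequencies_lock_under_strong_coupling(self, rng):
        params = KuramotoParams(K=2.0, omegas=np.full(5, 1.0),
                                initial_phases=np.linspace(-2.5, 2.5, 5),
                                alpha=0.0, d_t=0.05, length=2000)
        _, phases = generate_kuramoto(params, rng)
        r = order_parameter(phases).r
        assert r[-1] > 0.99
        assert r[-1] > r[0]

    def test_matches_hand_coded_euler_integrator(self, rng):
        omegas = np.array([0.7, 1.3, 2.1, 0.2])
        init = np.array([0.1, -0.5, 2.0, -2.4])
        params = KuramotoParams(K=1.5, omegas=omegas, initial_phases=init,
                                alpha=0.0, d_t=0.05, length=200)
        _, phases = generate_kuramoto(params, rng)
        theta = init.astype(float).copy()
        history = [theta.copy()]
        for _ in range(199):
            z = np.mean(np.exp(1j * theta))
            r, psi = np.abs(z), np.angle(z)
            theta = theta + 0.05 * (omegas + 1.5 * r * np.sin(psi - theta))
            history.append(theta.copy())
        expected = np.array(history).T
        assert np.allclose(np.unwrap(phases.angles, axis=1), expected, atol=1e-12)

    def test_amplitudes_are_sine_of_phases(self, rng):
        params = KuramotoParams(K=0.5, omegas=np.array([1.0, 2.0]),
                                initial_phases=np.array([0.0, 1.0]),
                                alpha=0.3, d_t=0.05, length=100)
        amplitudes, phases = generate_kuramoto(params, rng)
        assert np.allclose(amplitudes.values, np.sin(phases.angles), atol=1e-12)
        assert np.all(np.abs(amplitudes.values) <= 1.0)


class TestKuramotoCollection:
    def test_shapes_and_determinism(self):
        coll_a, phases_a = sample_kuramoto_collection(
            4, K=1.0, n_osc=5, length=200, rng=np.random.default_rng(9)
        )
        coll_b, _ = sample_kuramoto_collection(
            4, K=1.0, n_osc=5, length=200, rng=np.random.default_rng(9)
        )
        assert len(coll_a) == 4 and coll_a.n_variables == 5
        assert all(s.values.shape == (5, 200) for s in coll_a)
        assert all(
            np.array_equal(a.values, b.values) for a, b in zip(coll_a, coll_b)
        )
        assert phases_a[0].angles.shape == (5, 200)

    def test_metrics_rise_toward_synchrony_pole_with_common_noise(self, rng):
        from groupsync import (
            cluster_phase_rho,
            extract_phase_hilbert,
            recurrence_matrix,
            rqa_metrics,
            sum_normalized_csd,
            symbolic_entropy,
            team_coherence,
        )

        values = rng.normal(size=(5, 1000))
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        quiet = values
        loud = add_correlated_noise(values, 3.0, rng).values

        def battery(v):
            return {
                "rho": cluster_phase_rho(extract_phase_hilbert(v)).rho_overall,
                "coherence": team_coherence(v, 256),
                "sncsd": sum_normalized_csd(v, 256),
                "rec": rqa_metrics(recurrence_matrix(v, 1.0)).rec_pct,
                "entropy": symbolic_entropy(v),
            }

        low, high = battery(quiet), battery(loud)
        for name in ["rho", "coherence", "sncsd", "rec"]:
            assert high[name] > low[name]
        assert high["entropy"] < low["entropy"]
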