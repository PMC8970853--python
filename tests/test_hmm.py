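import numpy as np
import pytest
from scipy.stats import norm

from conftest import enumerate_posteriors, random_hmm_instance
from icuprior.hmm import (
    HMMParameters,
    align_states,
    extract_parameters,
    fit_baum_welch,
    fit_cohort,
    forward_backward,
)


def _two_state_series(rng, T=5000, means=(0.0, 5.0), sds=(1.0, 1.0), stay=0.95):
    path = np.empty(T, dtype=int)
    path[0] = rng.integers(2)
    for t in range(1, T):
        path[t] = path[t - 1] if rng.random() < stay else 1 - path[t - 1]
    obs = rng.normal(np.asarray(means)[path], np.asarray(sds)[path])
    return obs[:, None], path


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            params, obs = random_hmm_instance(rng)
            expected, ll_expected = enumerate_posteriors(
                params.initial_probs, params.transition_matrix,
                params.means, params.sds, obs)
            got, ll = forward_backward(params, obs)
            assert np.max(np.abs(got - expected)) < 1e-10
            assert ll == pytest.approx(ll_expected, abs=1e-10)

    def test_single_state_posterior_is_one_and_loglik_closed_form(self):
        obs = np.array([[0.3], [1.2], [-0.7]])
        params = HMMParameters(np.array([1.0]), np.array([[1.0]]),
                               means=np.array([[0.5]]), sds=np.array([[1.3]]))
        post, ll = forward_backward(params, obs)
        np.testing.assert_allclose(post, 1.0)
        assert ll == pytest.approx(norm.logpdf(obs.ravel(), 0.5, 1.3).sum())

    def test_identical_emissions_give_uniform_posterior(self):
        params = HMMParameters(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                               means=np.zeros((2, 1)), sds=np.ones((2, 1)))
        post, _ = forward_backward(params, np.array([[0.1], [2.0], [-1.0]]))
        np.testing.assert_allclose(post, 0.5)

    def test_posterior_rows_sum_to_one(self, rng):
        for _ in range(10):
            params, obs = random_hmm_instance(rng)
            post, _ = forward_backward(params, obs)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)

    def test_no_underflow_on_long_series(self, rng):
        obs = rng.normal(0, 1, size=(100_000, 1))
        params = HMMParameters(np.array([0.5, 0.5]),
                               np.array([[0.99, 0.01], [0.01, 0.99]]),
                               means=np.array([[0.0], [1.0]]),
                               sds=np.array([[1.0], [1.0]]))
        post, ll = forward_backward(params, obs)
        assert np.isfinite(ll)
        assert np.all(np.isfinite(post))

    def test_dimension_mismatch_and_nonfinite_rejected(self):
        params = HMMParameters(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                               means=np.zeros((2, 2)), sds=np.ones((2, 2)))
        with pytest.raises(ValueError, match="dimension"):
            forward_backward(params, np.zeros((4, 1)))
        with pytest.raises(ValueError, match="finite"):
            forward_backward(params, np.array([[0.0, np.nan]]))


class TestBaumWelch:
    def test_single_state_closed_form(self, rng):
        obs = rng.normal(3.0, 2.0, size=(200, 1))
        fit = fit_baum_welch(obs, n_states=1, n_restarts=1)
        assert fit.params.means[0, 0] == pytest.approx(obs.mean(), abs=1e-9)
        assert fit.params.sds[0, 0] == pytest.approx(obs.std(ddof=0), abs=1e-9)

    def test_recovers_well_separated_state_means(self):
        rng = np.random.default_rng(5)
        obs, _ = _two_state_series(rng)
        fit = fit_baum_welch(obs, n_states=2, seed=0)
        fit = align_states(fit)  # falls back to the only variable
        means = np.sort(fit.params.means.ravel())
        assert abs(means[0] - 0.0) < 0.15
        assert abs(means[1] - 5.0) < 0.15

    def test_loglik_trace_monotone(self, rng):
        for _ in range(5):
            obs = rng.normal(0, 1, size=(80, 2)) + rng.integers(0, 2, 80)[:, None] * 2.0
            fit = fit_baum_welch(obs, n_states=2, seed=1, n_restarts=1)
            trace = np.asarray(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-6)

    def test_decoded_is_posterior_argmax(self, rng):
        obs, _ = _two_state_series(rng, T=300)
        fit = fit_baum_welch(obs, n_states=2, seed=2)
        np.testing.assert_array_equal(fit.decoded, fit.posteriors.argmax(axis=1))

    def test_full_covariance_emissions(self, rng):
        obs, _ = _two_state_series(rng, T=800)
        obs = np.hstack([obs, obs * 0.5 + rng.normal(0, 0.3, size=obs.shape)])
        fit = fit_baum_welch(obs, n_states=2, emission_kind="full", seed=3)
        assert fit.params.covariances.shape == (2, 2, 2)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_baum_welch(np.zeros((2, 1)), n_states=2)

    def test_constant_series_flagged_degenerate(self):
        fit = fit_baum_welch(np.full((50, 1), 3.0), n_states=2, n_restarts=1)
        assert fit.degenerate
        assert np.all(fit.params.sds > 0)

    def test_restarts_never_hurt(self, rng):
        obs, _ = _two_state_series(rng, T=400)
        one = fit_baum_welch(obs, n_states=2, n_restarts=1, seed=9)
        three = fit_baum_welch(obs, n_states=2, n_restarts=3, seed=9)
        assert three.loglik >= one.loglik - 1e-9

    def test_state_relabeling_preserves_likelihood(self, rng):
        params, obs = random_hmm_instance(rng, max_S=3)
        S = params.n_states
        perm = np.asarray(np.random.default_rng(1).permutation(S))
        permuted = HMMParameters(
            params.initial_probs[perm],
            params.transition_matrix[np.ix_(perm, perm)],
            means=params.means[perm], sds=params.sds[perm])
        _, ll = forward_backward(params, obs)
        _, ll_perm = forward_backward(permuted, obs)
        assert ll == pytest.approx(ll_perm, abs=1e-10)


class TestAlignStates:
    def _fit(self, means, variables=("hr", "map")):
        params = HMMParameters(
            np.array([0.5, 0.5]), np.array([[0.9, 0.1], [0.2, 0.8]]),
            means=np.asarray(means, dtype=float),
            sds=np.ones_like(np.asarray(means, dtype=float)),
            variables=tuple(variables))
        post = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        from icuprior.hmm import HMMFit
        return HMMFit(params=params, posteriors=post, decoded=post.argmax(axis=1),
                      loglik_trace=[-10.0], converged=True, n_iter=1)

    def test_swaps_states_so_low_reference_mean_is_first(self):
        fit = self._fit([[80.0, 90.0], [85.0, 70.0]])  # map means 90, 70
        aligned = align_states(fit, reference_variable="map")
        assert aligned.params.means[0, 1] == 70.0
        np.testing.assert_allclose(aligned.posteriors[:, 0], fit.posteriors[:, 1])
        np.testing.assert_array_equal(aligned.decoded, 1 - fit.decoded)
        assert aligned.aligned

    def test_already_aligned_is_unchanged(self):
        fit = self._fit([[85.0, 70.0], [80.0, 90.0]])
        aligned = align_states(fit, reference_variable="map")
        np.testing.assert_array_equal(aligned.params.means, fit.params.means)
        np.testing.assert_array_equal(aligned.decoded, fit.decoded)

    def test_equal_means_keep_original_order(self):
        fit = self._fit([[85.0, 80.0], [70.0, 80.0]])
        aligned = align_states(fit, reference_variable="map")
        np.testing.assert_array_equal(aligned.params.means, fit.params.means)

    def test_unknown_reference_variable_rejected(self):
        fit = self._fit([[80.0, 90.0], [85.0, 70.0]])
        with pytest.raises(ValueError, match="reference"):
            align_states(fit, reference_variable="temperature")


class TestExtractParameters:
    def test_cardinality_two_states_four_variables(self, rng):
        obs = rng.normal(0, 1, size=(60, 4))
        fit = fit_baum_welch(obs, n_states=2, seed=0, n_restarts=1,
                             variables=("a", "b", "c", "d"))
        records = extract_parameters(fit, patient_id=42)
        assert len(records) == 8
        assert set(records["state"]) == {1, 2}
        assert set(records["variable"]) == {"a", "b", "c", "d"}

    def test_single_state_records_match_closed_form(self, rng):
        obs = rng.normal(2.0, 1.5, size=(150, 1))
        fit = fit_baum_welch(obs, n_states=1, n_restarts=1, variables=("hr",))
        rec = extract_parameters(fit, patient_id=1)
        assert rec["mu_hat"].iloc[0] == pytest.approx(obs.mean(), abs=1e-9)
        assert rec["sigma_hat"].iloc[0] == pytest.approx(obs.std(ddof=0), abs=1e-9)

    def test_full_covariance_sigma_is_sqrt_diagonal(self, rng):
        obs = rng.normal(0, 1, size=(100, 2))
        fit = fit_baum_welch(obs, n_states=2, emission_kind="full", seed=1,
                             n_restarts=1, variables=("x", "y"))
        rec = extract_parameters(fit, patient_id=1)
        for s in (1, 2):
            for k, var in enumerate(("x", "y")):
                expected = np.sqrt(fit.params.covariances[s - 1][k, k])
                got = rec.query("state == @s and variable == @var")["sigma_hat"].iloc[0]
                assert got == pytest.approx(expected)


def test_fit_cohort_records_and_posterior_schema(small_cohort):
    cohort, _ = small_cohort
    records, posteriors, fits = fit_cohort(cohort, seed=0, n_restarts=1)
    assert len(records) == cohort.n_patients * 2 * len(cohort.monitored_variables())
    assert {"p_state1", "p_state2", "decoded"} <= set(posteriors.columns)
    assert all(fit.aligned for fit in fits.values())
    # state 1 is failure-aligned: lower fitted map mean
    for pid, fit in fits.items():
        k = fit.params.variables.index("map")
        assert fit.params.means[0, k] <= fit.params.means[1, k]
    probs = posteriors[["p_state1", "p_state2"]].to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
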