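"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from icuprior import CohortConfig, generate_cohort
from icuprior.hmm import HMMParameters


def enumerate_posteriors(pi, A, means, sds, obs):
    """Brute-force smoothed posteriors by summing over every state path.

    Independent of the dynamic-programming implementation: the joint
    probability of each of the S**T paths is accumulated directly.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    T, K = obs.shape
    S = len(pi)
    emis = np.empty((T, S))  # per-time emission density under each state
    for s in range(S):
        emis[:, s] = np.prod(norm.pdf(obs, means[s], sds[s]), axis=1)
    post = np.zeros((T, S))
    total = 0.0
    for path in product(range(S), repeat=T):
        p = pi[path[0]] * emis[0, path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * emis[t, path[t]]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total, np.log(total)


def random_hmm_instance(rng, max_T=8, max_S=3, max_K=2):
    """A random small HMM plus an observation matrix for oracle comparison."""
    S = int(rng.integers(1, max_S + 1))
    T = int(rng.integers(2, max_T + 1))
    K = int(rng.integers(1, max_K + 1))
    pi = rng.dirichlet(np.ones(S))
    A = np.vstack([rng.dirichlet(np.ones(S)) for _ in range(S)])
    means = rng.normal(0.0, 2.0, size=(S, K))
    sds = rng.uniform(0.5, 2.0, size=(S, K))
    obs = rng.normal(0.0, 2.0, size=(T, K))
    params = HMMParameters(initial_probs=pi, transition_matrix=A, means=means, sds=sds)
    return params, obs


def pair_count_auc(scores, labels):
    """Direct O(n^2) Mann-Whitney pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def make_profiles(rng, n):
    """Random covariate table with the standard basic-variable schema."""
    prof = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "sex": rng.integers(0, 2, n).astype(float),
        "age": rng.normal(60.0, 15.0, n),
        "weight": rng.normal(80.0, 15.0, n),
        "height": rng.normal(1.70, 0.10, n),
    })
    prof["bmi"] = prof["weight"] / prof["height"] ** 2
    return prof


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny well-separated labeled cohort used across modules."""
    config = CohortConfig(n_patients=6, t_range=(40, 60), seed=7)
    cohort, truth = generate_cohort(config)
    return cohort, truth
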