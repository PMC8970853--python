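"""Per-patient multivariate Gaussian hidden Markov models.

Fitting is maximum likelihood via Baum-Welch EM with scaled forward-backward
recursions (numerically safe for series up to ~1e5 time points). Emissions are
either diagonal (variables conditionally independent given the state, the
default) or full covariance. Decoding is posterior: each time point gets the
state with the highest smoothed posterior probability.

State indices are 0-based internally; user-facing records use 1..S, with
state 1 the failure-aligned state after :func:`align_states`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
#: relative floor applied to per-variable emission variances
VARIANCE_FLOOR_FRAC = 1e-6


@dataclass
class HMMParameters:
    """Initial distribution, transition matrix and Gaussian emissions."""

    initial_probs: np.ndarray          # (S,)
    transition_matrix: np.ndarray      # (S, S) row-stochastic
    means: np.ndarray                  # (S, K)
    sds: np.ndarray | None = None          # (S, K) for diagonal emissions
    covariances: np.ndarray | None = None  # (S, K, K) for full emissions
    variables: tuple[str, ...] | None = None

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_variables(self) -> int:
        return self.means.shape[1]

    @property
    def emission_kind(self) -> str:
        return "diagonal" if self.sds is not None else "full"

    def validate(self) -> None:
        S = self.n_states
        if self.initial_probs.shape != (S,) or self.transition_matrix.shape != (S, S):
            raise ValueError("initial_probs/transition_matrix shape mismatch")
        if abs(self.initial_probs.sum() - 1.0) > 1e-10:
            raise ValueError("initial_probs must sum to 1 within 1e-10")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        if self.sds is None and self.covariances is None:
            raise ValueError("either sds or covariances must be set")
        if self.sds is not None and np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if self.covariances is not None:
            for s in range(S):
                C = self.covariances[s]
                if not np.allclose(C, C.T):
                    raise ValueError(f"covariance for state {s} is not symmetric")
                if np.any(np.linalg.eigvalsh(C) <= 0):
                    raise ValueError(f"covariance for state {s} is not positive definite")

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """Log density of each observation row under each state: (T, S)."""
        obs = np.atleast_2d(np.asarray(obs, dtype=float))
        T, K = obs.shape
        if K != self.n_variables:
            raise ValueError(
                f"observation dimension {K} != emission dimension {self.n_variables}"
            )
        if not np.all(np.isfinite(obs)):
            raise ValueError("observations contain non-finite values")
        S = self.n_states
        logb = np.empty((T, S))
        if self.sds is not None:
            for s in range(S):
                z = (obs - self.means[s]) / self.sds[s]
                logb[:, s] = -0.5 * (z**2).sum(axis=1) - np.log(self.sds[s]).sum() \
                    - 0.5 * K * _LOG2PI
        else:
            for s in range(S):
                C = self.covariances[s]
                L = np.linalg.cholesky(C)
                diff = obs - self.means[s]
                sol = np.linalg.solve(L, diff.T)
                logb[:, s] = -0.5 * (sol**2).sum(axis=0) \
                    - np.log(np.diag(L)).sum() - 0.5 * K * _LOG2PI
        return logb


@dataclass
class HMMFit:
    """Fit result: parameters, smoothed posteriors and decoded states."""

    params: HMMParameters
    posteriors: np.ndarray        # (T, S)
    decoded: np.ndarray           # (T,) 0-based state indices
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    degenerate: bool = False
    aligned: bool = False
    alignment_reference: str | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _forward_backward_scaled(logb: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled recursions. Returns (gamma, xi_sum, loglik).

    ``xi_sum[i, j]`` is the expected number of i->j transitions.
    """
    T, S = logb.shape
    # scale emission rows to avoid under/overflow before the alpha recursion
    bmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - bmax)

    alpha = np.empty((T, S))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, S))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    if T > 1:
        w = b[1:] * beta[1:] / c[1:, None]
        xi_sum = A * (alpha[:-1].T @ w)
    else:
        xi_sum = np.zeros((S, S))

    loglik = float(np.log(c).sum() + bmax.sum())
    return gamma, xi_sum, loglik


def forward_backward(params: HMMParameters, obs: np.ndarray):
    """Smoothed posteriors p(state_t = s | all observations) and log-likelihood."""
    params.validate()
    logb = params.log_emission(obs)
    gamma, _, loglik = _forward_backward_scaled(
        logb, np.asarray(params.initial_probs, float), np.asarray(params.transition_matrix, float)
    )
    return gamma, loglik


def _initial_params(
    obs: np.ndarray,
    n_states: int,
    emission_kind: str,
    variables,
    rng: np.random.Generator | None,
    jitter: float,
) -> HMMParameters:
    """Quantile-band initialization: state s starts at the mean of the s-th
    per-variable quantile band, with optional seeded jitter across restarts."""
    T, K = obs.shape
    S = n_states
    means = np.empty((S, K))
    srt = np.sort(obs, axis=0)
    edges = np.linspace(0, T, S + 1).astype(int)
    for s in range(S):
        band = srt[edges[s]: max(edges[s + 1], edges[s] + 1)]
        means[s] = band.mean(axis=0)
    sd = obs.std(axis=0)
    sd = np.maximum(sd, 1e-3 * np.maximum(np.abs(obs).mean(axis=0), 1.0) + 1e-6)
    if rng is not None and jitter > 0:
        means = means + rng.normal(0.0, jitter, size=means.shape) * sd
    pi = np.full(S, 1.0 / S)
    A = np.full((S, S), 0.1 / max(S - 1, 1))
    np.fill_diagonal(A, 0.9 if S > 1 else 1.0)
    if emission_kind == "diagonal":
        return HMMParameters(pi, A, means, sds=np.tile(sd, (S, 1)), variables=variables)
    cov = np.tile(np.diag(sd**2), (S, 1, 1))
    return HMMParameters(pi, A, means, covariances=cov, variables=variables)


def fit_baum_welch(
    obs: np.ndarray,
    n_states: int = 2,
    emission_kind: str = "diagonal",
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 3,
    seed: int | None = None,
    variables: tuple[str, ...] | None = None,
) -> HMMFit:
    """Maximum-likelihood fit via EM; the best of ``n_restarts`` runs wins.

    The first restart uses the deterministic quantile-band initialization;
    later restarts jitter it with the seeded RNG. Convergence is declared when
    the relative log-likelihood improvement drops below ``tol``.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 1 and obs.shape[1] != 1 and variables is None:
        obs = obs.T  # single-variable series passed as a flat vector
    T, K = obs.shape
    if emission_kind not in ("diagonal", "full"):
        raise ValueError(f"unknown emission_kind: {emission_kind}")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if T < n_states + 1:
        raise ValueError(f"series too short: T={T} < n_states+1={n_states + 1}")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations contain non-finite values")

    sample_var = obs.var(axis=0)
    degenerate = bool(np.all(sample_var == 0))
    var_floor = VARIANCE_FLOOR_FRAC * (sample_var + 1e-12) + 1e-300
    sd_floor = np.sqrt(var_floor)

    rng = np.random.default_rng(seed)
    best: HMMFit | None = None
    for restart in range(max(n_restarts, 1)):
        jitter = 0.0 if restart == 0 else 0.25
        params = _initial_params(obs, n_states, emission_kind, variables, rng, jitter)
        fit = _run_em(obs, params, tol, max_iter, sd_floor)
        if best is None or fit.loglik > best.loglik:
            best = fit
    best.degenerate = degenerate
    if degenerate:
        logger.warning("all-constant series: degenerate fit with variance floor applied")
    return best


def _run_em(obs, params, tol, max_iter, sd_floor) -> HMMFit:
    T, K = obs.shape
    S = params.n_states
    trace: list[float] = []
    converged = False
    gamma = np.full((T, S), 1.0 / S)
    for it in range(max_iter):
        logb = params.log_emission(obs)
        gamma, xi_sum, loglik = _forward_backward_scaled(
            logb, params.initial_probs, params.transition_matrix
        )
        trace.append(loglik)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if rel < tol:
                converged = True
                break
        # M-step
        w = gamma.sum(axis=0)  # (S,)
        pi = gamma[0] / gamma[0].sum()
        if S > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(rows > 0, xi_sum / np.where(rows > 0, rows, 1.0),
                         1.0 / S)
        else:
            A = np.ones((1, 1))
        means = (gamma.T @ obs) / w[:, None]
        if params.sds is not None:
            var = np.empty((S, K))
            for s in range(S):
                diff = obs - means[s]
                var[s] = (gamma[:, s][:, None] * diff**2).sum(axis=0) / w[s]
            sds = np.sqrt(np.maximum(var, sd_floor**2))
            params = HMMParameters(pi, A, means, sds=sds, variables=params.variables)
        else:
            covs = np.empty((S, K, K))
            for s in range(S):
                diff = obs - means[s]
                covs[s] = (gamma[:, s][:, None] * diff).T @ diff / w[s]
                covs[s] += np.diag(sd_floor**2) + 1e-10 * np.eye(K)
            params = HMMParameters(pi, A, means, covariances=covs, variables=params.variables)
    else:
        # recompute posteriors/loglik for the final parameters
        logb = params.log_emission(obs)
        gamma, _, loglik = _forward_backward_scaled(
            logb, params.initial_probs, params.transition_matrix
        )
        trace.append(loglik)
    decoded = gamma.argmax(axis=1)  # ties break toward the lower state index
    return HMMFit(
        params=params,
        posteriors=gamma,
        decoded=decoded,
        loglik_trace=trace,
        converged=converged,
        n_iter=len(trace),
    )


def align_states(
    fit: HMMFit, reference_variable: str = "map", convention: str = "lower_mean_is_failure"
) -> HMMFit:
    """Permute states so state 0 (user-facing state 1) is failure-aligned.

    The failure-aligned state is the one with the lower fitted mean on the
    reference variable ("map" by default, falling back to the first variable
    when the fit has no variable names). For S > 2 states are sorted by
    ascending reference mean. Ties keep the original order (logged).
    """
    if convention != "lower_mean_is_failure":
        raise ValueError(f"unknown convention: {convention}")
    params = fit.params
    if params.variables is not None:
        if reference_variable in params.variables:
            ref = params.variables.index(reference_variable)
        elif reference_variable == "map":
            ref = 0  # documented fallback: first variable
        else:
            raise ValueError(f"unknown reference variable: {reference_variable!r}")
    else:
        ref = 0
    ref_means = params.means[:, ref]
    order = np.argsort(ref_means, kind="stable")
    if len(set(ref_means.tolist())) < len(ref_means):
        logger.info("align_states: tied reference means; original order kept for ties")
    if np.array_equal(order, np.arange(params.n_states)):
        return replace(fit, aligned=True, alignment_reference=reference_variable)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    new_params = HMMParameters(
        initial_probs=params.initial_probs[order],
        transition_matrix=params.transition_matrix[np.ix_(order, order)],
        means=params.means[order],
        sds=None if params.sds is None else params.sds[order],
        covariances=None if params.covariances is None else params.covariances[order],
        variables=params.variables,
    )
    return replace(
        fit,
        params=new_params,
        posteriors=fit.posteriors[:, order],
        decoded=inv[fit.decoded],
        aligned=True,
        alignment_reference=reference_variable,
    )


def extract_parameters(fit: HMMFit, patient_id) -> pd.DataFrame:
    """One (mu_hat, sigma_hat) record per variable x state, states 1-based.

    For full-covariance fits sigma_hat is the square root of the diagonal.
    """
    params = fit.params
    S, K = params.means.shape
    variables = params.variables or tuple(f"var{k + 1}" for k in range(K))
    if params.sds is not None:
        sds = params.sds
    else:
        sds = np.sqrt(np.stack([np.diag(params.covariances[s]) for s in range(S)]))
    rows = [
        {"patient_id": patient_id, "variable": variables[k], "state": s + 1,
         "mu_hat": float(params.means[s, k]), "sigma_hat": float(sds[s, k])}
        for k in range(K)
        for s in range(S)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "variable", "state", "mu_hat", "sigma_hat"])


def fit_cohort(
    cohort,
    n_states: int = 2,
    emission_kind: str = "diagonal",
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 3,
    seed: int | None = None,
    align_reference: str = "map",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fit every patient, align states, and assemble records/posterior tables.

    Returns ``(records, posteriors, fits)`` where records follow the
    ParameterRecord schema, posteriors carry ``p_state1..p_stateS`` plus the
    decoded (1-based) state, and fits maps patient_id -> aligned HMMFit.
    """
    variables = tuple(cohort.monitored_variables())
    rec_frames, post_frames, fits = [], [], {}
    ss = np.random.SeedSequence(seed)
    for idx, pid in enumerate(cohort.patient_ids):
        sub = cohort.patient_series(pid)
        obs = sub[list(variables)].to_numpy(dtype=float)
        child_seed = np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0] \
            if seed is not None else None
        fit = fit_baum_welch(
            obs, n_states=n_states, emission_kind=emission_kind, tol=tol,
            max_iter=max_iter, n_restarts=n_restarts, seed=child_seed,
            variables=variables,
        )
        fit = align_states(fit, reference_variable=align_reference)
        fits[pid] = fit
        rec_frames.append(extract_parameters(fit, pid))
        post = pd.DataFrame({"patient_id": pid, "time": sub["time"].to_numpy()})
        for s in range(n_states):
            post[f"p_state{s + 1}"] = fit.posteriors[:, s]
        post["decoded"] = fit.decoded + 1
        post_frames.append(post)
        logger.debug(
            "fit patient=%s n_iter=%d loglik=%.3f converged=%s",
            pid, fit.n_iter, fit.loglik, fit.converged,
        )
    del ss
    records = pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame(
        columns=["patient_id", "variable", "state", "mu_hat", "sigma_hat"]
    )
    posteriors = pd.concat(post_frames, ignore_index=True) if post_frames else pd.DataFrame(
        columns=["patient_id", "time", "decoded"]
    )
    logger.info("fitted %d patients (%d states, %s emissions)", len(fits), n_states, emission_kind)
    return records, posteriors, fits
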