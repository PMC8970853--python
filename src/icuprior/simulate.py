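"""Seeded synthetic ICU cohorts with known two-state structure.

The simulator emits cohorts with the statistical shape the pipeline assumes:
covariates drawn per patient, per-patient emission parameters built from a
linear model on those covariates, a persistent first-order Markov state path,
Gaussian observations conditioned on the state, and MAP/lactate/drug channels
tied to the state so the rule label tracks the hidden truth.

Every patient has their own deterministic random substream derived from the
cohort seed and the patient index, so patient ``i``'s data does not depend on
``n_patients``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, label_states
from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

COVARIATES = ["sex", "age", "weight", "height", "bmi"]


@dataclass
class TruncNormal:
    """Truncated normal on [low, high] with the given location/scale.

    Sampled by rejection (cheap: the default bounds keep the acceptance rate
    near 1); after 1000 rejections the draw is clipped to the bounds.
    """

    loc: float
    scale: float
    low: float
    high: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        for i in range(size):
            v = self.loc
            for _ in range(1000):
                v = rng.normal(self.loc, self.scale)
                if self.low <= v <= self.high:
                    break
            out[i] = min(max(v, self.low), self.high)
        return out


@dataclass
class CovariateDists:
    sex_p: float = 0.5
    age: TruncNormal = field(default_factory=lambda: TruncNormal(62.0, 15.0, 18.0, 95.0))
    weight: TruncNormal = field(default_factory=lambda: TruncNormal(78.0, 15.0, 40.0, 160.0))
    height: TruncNormal = field(default_factory=lambda: TruncNormal(1.70, 0.10, 1.45, 2.05))


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    States are labeled 1..n_states everywhere user-facing. ``state_means`` and
    ``state_sds`` map each monitored variable to one baseline value per state.
    ``covariate_effects`` maps ``(variable, state, parameter, covariate)`` to a
    linear effect size, where parameter is ``"mu"`` (additive on the mean) or
    ``"sigma"`` (additive on log sigma, hence multiplicative on sigma). BMI is
    never sampled: it is derived as weight / height**2.
    """

    n_patients: int = 100
    t_range: tuple[int, int] = (50, 150)
    n_states: int = 2
    monitored_vars: tuple[str, ...] = ("hr", "map")
    state_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"hr": (95.0, 87.0), "map": (85.0, 55.0)}
    )
    state_sds: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"hr": (10.0, 9.0), "map": (8.0, 5.0)}
    )
    covariate_effects: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    transition_stay_prob: tuple[float, ...] = (0.95, 0.95)
    initial_probs: tuple[float, ...] = (0.5, 0.5)
    labeling_channels: bool = True
    lactate_meanlog: tuple[float, ...] = (math.log(1.2), math.log(3.0))
    lactate_sdlog: float = 0.25
    drug_prob_by_state: tuple[float, ...] = (0.05, 0.7)
    mu_noise_sd: float = 0.0
    sigma_noise_sd: float = 0.0
    covariate_dists: CovariateDists = field(default_factory=CovariateDists)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        tmin, tmax = self.t_range
        if tmin < 2 or tmax < tmin:
            raise ConfigError("t_range must satisfy 2 <= min <= max")
        if self.n_states < 1:
            raise ConfigError("n_states must be >= 1")
        S = self.n_states
        if abs(sum(self.initial_probs) - 1.0) > 1e-12:
            raise ConfigError("initial_probs must sum to 1 within 1e-12")
        if len(self.initial_probs) != S or any(not 0 <= p <= 1 for p in self.initial_probs):
            raise ConfigError("initial_probs must be n_states probabilities in [0,1]")
        if len(self.transition_stay_prob) != S or any(
            not 0 < p < 1 for p in self.transition_stay_prob
        ):
            raise ConfigError("transition_stay_prob must be n_states values in (0,1)")
        for var in self.monitored_vars:
            if var not in self.state_means or len(self.state_means[var]) != S:
                raise ConfigError(f"state_means missing or wrong length for variable '{var}'")
            if var not in self.state_sds or len(self.state_sds[var]) != S:
                raise ConfigError(f"state_sds missing or wrong length for variable '{var}'")
            if any(sd <= 0 for sd in self.state_sds[var]):
                raise ConfigError(f"state_sds must be > 0 for variable '{var}'")
        for key in self.covariate_effects:
            var, state, param, cov = key
            if var not in self.monitored_vars:
                raise ConfigError(f"covariate_effects: unknown variable '{var}'")
            if not 1 <= state <= S:
                raise ConfigError(f"covariate_effects: state {state} out of range")
            if param not in ("mu", "sigma"):
                raise ConfigError(f"covariate_effects: parameter must be mu/sigma, got '{param}'")
            if cov not in COVARIATES:
                raise ConfigError(f"covariate_effects: unknown covariate '{cov}'")
        if self.labeling_channels:
            if "map" not in self.monitored_vars:
                raise ConfigError("monitored_vars must include 'map' when labeling_channels is on")
            if len(self.lactate_meanlog) != S or len(self.drug_prob_by_state) != S:
                raise ConfigError("lactate_meanlog and drug_prob_by_state must have n_states entries")
            if any(not 0 <= p <= 1 for p in self.drug_prob_by_state):
                raise ConfigError("drug_prob_by_state must be probabilities in [0,1]")
        if not 0 <= self.covariate_dists.sex_p <= 1:
            raise ConfigError("covariate_dists.sex_p must be in [0,1]")
        if self.mu_noise_sd < 0 or self.sigma_noise_sd < 0:
            raise ConfigError("mu_noise_sd and sigma_noise_sd must be >= 0")

    def transition_matrix(self) -> np.ndarray:
        S = self.n_states
        A = np.zeros((S, S))
        for s in range(S):
            A[s, :] = (1.0 - self.transition_stay_prob[s]) / max(S - 1, 1)
            A[s, s] = self.transition_stay_prob[s] if S > 1 else 1.0
        return A

    def failure_state(self) -> int:
        """1-based index of the state with the lowest configured MAP mean."""
        if "map" not in self.state_means:
            raise ConfigError("failure_state requires a 'map' variable")
        return int(np.argmin(self.state_means["map"])) + 1


@dataclass
class GroundTruth:
    """Simulator-side truth: state paths and per-patient emission parameters."""

    states: pd.DataFrame  # patient_id, time, state (1-based)
    params: pd.DataFrame  # patient_id, variable, state, mu_true, sigma_true
    failure_state: int | None = None


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # spawn_key makes patient streams independent of n_patients
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full cohort plus its ground truth. Deterministic given config."""
    config.validate()
    S = config.n_states
    K = len(config.monitored_vars)
    A = config.transition_matrix()
    pi = np.asarray(config.initial_probs)

    profile_rows, series_frames, state_frames, param_rows = [], [], [], []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = i + 1

        sex = float(rng.random() < config.covariate_dists.sex_p)
        age = float(config.covariate_dists.age.sample(rng, 1)[0])
        weight = float(config.covariate_dists.weight.sample(rng, 1)[0])
        height = float(config.covariate_dists.height.sample(rng, 1)[0])
        bmi = weight / height**2
        cov = {"sex": sex, "age": age, "weight": weight, "height": height, "bmi": bmi}
        profile_rows.append({"patient_id": pid, **cov})

        # per-patient emission parameters from the linear model
        mu = np.empty((K, S))
        sigma = np.empty((K, S))
        for k, var in enumerate(config.monitored_vars):
            for s in range(S):
                m = config.state_means[var][s]
                ls = math.log(config.state_sds[var][s])
                for c in COVARIATES:
                    m += config.covariate_effects.get((var, s + 1, "mu", c), 0.0) * cov[c]
                    ls += config.covariate_effects.get((var, s + 1, "sigma", c), 0.0) * cov[c]
                if config.mu_noise_sd > 0:
                    m += rng.normal(0.0, config.mu_noise_sd)
                if config.sigma_noise_sd > 0:
                    ls += rng.normal(0.0, config.sigma_noise_sd)
                mu[k, s] = m
                sigma[k, s] = math.exp(ls)
                param_rows.append(
                    {"patient_id": pid, "variable": var, "state": s + 1,
                     "mu_true": mu[k, s], "sigma_true": sigma[k, s]}
                )

        T = int(rng.integers(config.t_range[0], config.t_range[1] + 1))
        path = np.empty(T, dtype=int)
        path[0] = rng.choice(S, p=pi)
        for t in range(1, T):
            path[t] = rng.choice(S, p=A[path[t - 1]])

        obs = rng.normal(mu[:, path].T, sigma[:, path].T)  # (T, K)
        frame = {"patient_id": pid, "time": np.arange(1, T + 1)}
        for k, var in enumerate(config.monitored_vars):
            frame[var] = obs[:, k]
        if config.labeling_channels:
            meanlog = np.asarray(config.lactate_meanlog)[path]
            frame["lactate"] = rng.lognormal(meanlog, config.lactate_sdlog)
            frame["drug_present"] = (
                rng.random(T) < np.asarray(config.drug_prob_by_state)[path]
            ).astype(int)
        series_frames.append(pd.DataFrame(frame))
        state_frames.append(
            pd.DataFrame({"patient_id": pid, "time": np.arange(1, T + 1), "state": path + 1})
        )

    profiles = pd.DataFrame(profile_rows, columns=["patient_id"] + COVARIATES)
    series_cols = ["patient_id", "time", *config.monitored_vars]
    if config.labeling_channels:
        series_cols += ["lactate", "drug_present"]
    if series_frames:
        series = pd.concat(series_frames, ignore_index=True)[series_cols]
        states = pd.concat(state_frames, ignore_index=True)
    else:
        series = pd.DataFrame(columns=series_cols)
        states = pd.DataFrame(columns=["patient_id", "time", "state"])
    params = pd.DataFrame(
        param_rows, columns=["patient_id", "variable", "state", "mu_true", "sigma_true"]
    )
    failure = config.failure_state() if "map" in config.state_means and S > 1 else None
    truth = GroundTruth(states=states, params=params, failure_state=failure)
    logger.info("simulated cohort: %d patients, %d series rows", len(profiles), len(series))
    return Cohort(profiles=profiles, series=series), truth


def rule_state_agreement(cohort: Cohort, truth: GroundTruth) -> float:
    """Fraction of time points where the rule label matches the true state.

    The truth state compared against ``failure`` is the state with the lowest
    true MAP mean (averaged across patients) unless the truth already records
    a failure state.
    """
    if not cohort.has_labeling_channels():
        raise SchemaError("cohort lacks labeling channels (map, lactate, drug_present)")
    failure = truth.failure_state
    if failure is None:
        p = truth.params
        if "map" not in set(p["variable"]):
            raise SchemaError("ground truth has no 'map' parameters to identify the failure state")
        by_state = p[p["variable"] == "map"].groupby("state")["mu_true"].mean()
        failure = int(by_state.idxmin())
    labels = label_states(cohort.series)
    merged = labels.merge(truth.states, on=["patient_id", "time"], validate="one_to_one")
    rule_failure = merged["label"].to_numpy() == "failure"
    true_failure = merged["state"].to_numpy() == failure
    return float(np.mean(rule_failure == true_failure))
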