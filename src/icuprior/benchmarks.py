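"""Definitional anchors and simulation analogs used for validation reporting.

Each function recomputes one headline quantity from scratch by running the
package's own machinery on seeded synthetic inputs: AUC anchors for the
ranking statistic, the nominal-to-quantile mapping, and held-out coverage /
relative-width analogs on cohorts with Gaussian within-leaf parameter
responses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import auc
from .forecast import evaluate_response, nominal_to_quantiles
from .simulate import CohortConfig, generate_cohort


def auc_perfect_ranking() -> tuple[float, int]:
    """AUC of a score vector ranking every positive above every negative."""
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [0, 0, 1, 1]
    return auc(scores, labels), len(scores)


def auc_random_scores(seed: int, n: int = 10_000) -> tuple[float, int]:
    """AUC of uniform random scores against independent Bernoulli(0.5) labels."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, 1.0, n)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():  # astronomically unlikely at n=10000
        labels[0] = not labels[0]
    return auc(scores, labels.astype(int)), n


def upper_quantile_level(level: float = 0.8) -> tuple[float, int]:
    """Quantile level of the interval's upper endpoint at the nominal level."""
    return nominal_to_quantiles(level)[1], 1


def _parameter_response_cohort(
    seed: int,
    n_patients: int,
    sex_effect: float,
    age_effect: float = 0.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cohort whose state-1 mean parameter is Gaussian (SD 1) around a linear
    covariate model; returns (per-patient response, profiles)."""
    config = CohortConfig(
        n_patients=n_patients,
        t_range=(2, 2),
        monitored_vars=("hr",),
        state_means={"hr": (0.0, 0.0)},
        state_sds={"hr": (1.0, 1.0)},
        labeling_channels=False,
        mu_noise_sd=1.0,
        covariate_effects={
            ("hr", 1, "mu", "sex"): sex_effect,
            ("hr", 1, "mu", "age"): age_effect,
        },
        seed=seed,
    )
    cohort, truth = generate_cohort(config)
    sub = truth.params[(truth.params["variable"] == "hr") & (truth.params["state"] == 1)]
    responses = sub.set_index("patient_id")["mu_true"]
    return responses, cohort.profiles


def heldout_coverage(seed: int, n_patients: int = 2000, level: float = 0.84
                     ) -> tuple[float, int]:
    """Held-out coverage of terminal-node quantile intervals at one level.

    Binary (sex) plus continuous (age) covariate effects drive the tree;
    within-node responses are Gaussian with SD ~1. 70/30 patient split.
    """
    responses, profiles = _parameter_response_cohort(
        seed, n_patients, sex_effect=0.6, age_effect=0.02
    )
    metrics = evaluate_response(responses, profiles, [level], split_seed=seed)[0]
    return metrics.coverage, metrics.n_evaluated


def average_relative_width(seed: int, n_patients: int = 6000, level: float = 0.8
                           ) -> tuple[float, int]:
    """Average relative width of nominal-80% leaf intervals on unit-variance
    Gaussian within-node responses with between-node shifts <= 0.25 SD."""
    responses, profiles = _parameter_response_cohort(seed, n_patients, sex_effect=0.25)
    metrics = evaluate_response(responses, profiles, [level], split_seed=seed)[0]
    return metrics.relative_width, metrics.n_evaluated
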