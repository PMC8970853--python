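"""ROC/AUC validation of decoded hidden states against the rule labels."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FAILURE
from .errors import StateError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AUCResult:
    patient_id: object
    auc: float
    n_pos: int
    n_neg: int


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney pair statistic.

    Equals (#concordant positive-negative pairs + 0.5 * #tied pairs) divided
    by n_pos * n_neg. Ties in the scores are credited one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present; pre-filter single-class patients")
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_cohort_auc(fits: dict, labels: pd.DataFrame, failure_state: int = 1
                        ) -> list[AUCResult]:
    """Per-patient AUC of the failure-aligned posterior against the rule label.

    Only patients whose labels contain both classes yield a result; the score
    is the smoothed posterior probability of the failure-aligned state (state
    ``failure_state``, 1-based). All fits must already be aligned.
    """
    for pid, fit in fits.items():
        if not fit.aligned:
            raise StateError(f"fit for patient {pid} is not aligned; call align_states first")
    results = []
    for pid, fit in fits.items():
        lab = labels[labels["patient_id"] == pid].sort_values("time")
        y = (lab["label"].to_numpy() == FAILURE).astype(int)
        if len(y) != fit.posteriors.shape[0]:
            raise ValueError(f"labels for patient {pid} do not cover the fitted time points")
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        if n_pos == 0 or n_neg == 0:
            continue
        score = fit.posteriors[:, failure_state - 1]
        results.append(AUCResult(pid, auc(score, y), n_pos, n_neg))
    logger.info("AUC computed for %d of %d patients", len(results), len(fits))
    return results


def auc_table_from_posteriors(posteriors: pd.DataFrame, labels: pd.DataFrame,
                              failure_state: int = 1) -> pd.DataFrame:
    """CSV-level variant of :func:`evaluate_cohort_auc` for the CLI."""
    col = f"p_state{failure_state}"
    if col not in posteriors.columns:
        raise ValueError(f"posteriors table has no column '{col}'")
    merged = posteriors.merge(labels, on=["patient_id", "time"], validate="one_to_one")
    rows = []
    for pid, grp in merged.groupby("patient_id", sort=True):
        y = (grp["label"].to_numpy() == FAILURE).astype(int)
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        if n_pos == 0 or n_neg == 0:
            continue
        rows.append({"patient_id": pid, "auc": auc(grp[col].to_numpy(), y),
                     "n_pos": n_pos, "n_neg": n_neg})
    return pd.DataFrame(rows, columns=["patient_id", "auc", "n_pos", "n_neg"])


def summarize_auc(results, n_bins: int = 20) -> tuple[dict, pd.DataFrame]:
    """Mean/median plus histogram bins on [0, 1] for reporting."""
    values = np.asarray([r.auc for r in results] if results and isinstance(
        results[0], AUCResult) else results, dtype=float)
    if values.size == 0:
        return {"n": 0, "mean": float("nan"), "median": float("nan")}, pd.DataFrame(
            columns=["bin_left", "bin_right", "count"])
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    summary = {"n": int(values.size), "mean": float(values.mean()),
               "median": float(np.median(values))}
    return summary, hist
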