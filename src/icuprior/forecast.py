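"""Terminal-node quantile interval forecasts and their quality metrics.

A nominal level c maps symmetrically to quantile levels ((1-c)/2, 1-(1-c)/2),
so an 80% interval runs from the 0.1 to the 0.9 empirical quantile of the leaf
responses (linear interpolation between order statistics). Interval widths are
made unit-free by dividing by the 0.95-0.05 quantile span of the full training
response column; coverage is the exact fraction of held-out responses falling
inside their leaf's interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import TreeNode, grow_tree, leaf_map, route

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForecastInterval:
    node_id: int
    level: float          # nominal probability content c
    lower: float
    upper: float
    q_lower: float        # quantile level of the lower endpoint
    q_upper: float


@dataclass(frozen=True)
class IntervalMetrics:
    level: float
    coverage: float
    relative_width: float
    n_evaluated: int


def nominal_to_quantiles(level: float) -> tuple[float, float]:
    """Symmetric mapping c -> (0.5 - c/2, 0.5 + c/2); 0.8 -> (0.1, 0.9)."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"nominal level must be in (0, 1], got {level}")
    # rounding cancels binary-representation residue so 0.8 -> exactly (0.1, 0.9)
    return round(0.5 - level / 2.0, 12), round(0.5 + level / 2.0, 12)


def leaf_interval(responses, level: float, node_id: int = -1) -> ForecastInterval:
    """Empirical quantile interval of a leaf's member responses."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        raise ValueError("empty leaf: no responses to form an interval")
    ql, qu = nominal_to_quantiles(level)
    lower, upper = np.quantile(responses, [ql, qu], method="linear")
    return ForecastInterval(node_id=node_id, level=level, lower=float(lower),
                            upper=float(upper), q_lower=ql, q_upper=qu)


def relative_width(interval: ForecastInterval, reference) -> float:
    """Interval width over the reference's 0.95-0.05 quantile span.

    Returns NaN (logged) when the reference spread is zero; callers exclude
    NaN widths from averages.
    """
    reference = np.asarray(reference, dtype=float)
    q05, q95 = np.quantile(reference, [0.05, 0.95], method="linear")
    span = q95 - q05
    if span == 0:
        logger.warning("relative width undefined: zero reference quantile span")
        return float("nan")
    return (interval.upper - interval.lower) / span


def make_leaf_intervals(tree: TreeNode, level: float) -> dict[int, ForecastInterval]:
    return {
        node_id: leaf_interval(leaf.responses, level, node_id=node_id)
        for node_id, leaf in leaf_map(tree).items()
    }


def coverage(
    intervals: dict[int, ForecastInterval],
    tree: TreeNode,
    eval_profiles: pd.DataFrame,
    eval_responses,
    reference,
    level: float,
) -> IntervalMetrics:
    """Route each held-out observation to its leaf and score the intervals.

    Coverage is exact counting (inside iff lower <= y <= upper). The reported
    relative width averages per-leaf widths weighted by evaluation counts;
    leaves with undefined width are excluded from that average.
    """
    eval_responses = np.asarray(eval_responses, dtype=float)
    if len(eval_profiles) != eval_responses.size:
        raise ValueError("evaluation profiles and responses must align")
    inside = 0
    leaf_counts: dict[int, int] = {}
    for (_, profile), y in zip(eval_profiles.iterrows(), eval_responses):
        node_id = route(tree, profile)
        iv = intervals[node_id]
        leaf_counts[node_id] = leaf_counts.get(node_id, 0) + 1
        if iv.lower <= y <= iv.upper:
            inside += 1
    total = int(eval_responses.size)
    widths, weights = [], []
    for node_id, cnt in leaf_counts.items():
        rw = relative_width(intervals[node_id], reference)
        if np.isfinite(rw):
            widths.append(rw)
            weights.append(cnt)
    avg_width = float(np.average(widths, weights=weights)) if widths else float("nan")
    return IntervalMetrics(
        level=level,
        coverage=inside / total if total else float("nan"),
        relative_width=avg_width,
        n_evaluated=total,
    )


def split_patients(patient_ids, test_frac: float = 0.3, seed: int | None = None):
    """Seeded patient-level train/test split; returns (train_ids, test_ids)."""
    ids = np.asarray(patient_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(test_frac * len(ids)))
    test = set(ids[perm[:n_test]].tolist())
    train = [i for i in ids.tolist() if i not in test]
    test_ordered = [i for i in ids.tolist() if i in test]
    return train, test_ordered


def response_columns(records: pd.DataFrame) -> list[tuple[str, str, int]]:
    """All (monitored variable, parameter, state) response keys present."""
    keys = []
    for variable in sorted(records["variable"].unique()):
        for param in ("mu", "sigma"):
            for state in sorted(records["state"].unique()):
                keys.append((variable, param, int(state)))
    return keys


def extract_response(records: pd.DataFrame, variable: str, parameter: str, state: int
                     ) -> pd.Series:
    """Per-patient response values for one (variable, parameter, state)."""
    col = "mu_hat" if parameter == "mu" else "sigma_hat"
    sub = records[(records["variable"] == variable) & (records["state"] == state)]
    return sub.set_index("patient_id")[col]


def evaluate_response(
    responses: pd.Series,
    profiles: pd.DataFrame,
    levels,
    predictors=("sex", "age", "weight", "height", "bmi"),
    alpha: float = 0.1,
    max_depth: int = 5,
    min_leaf: int = 20,
    test_frac: float = 0.3,
    split_seed: int | None = None,
) -> list[IntervalMetrics]:
    """Held-out interval metrics for one response column at several levels.

    Grows one tree on a seeded 70/30 patient split, forms leaf intervals per
    nominal level, and scores coverage / relative width on the held-out side.
    The relative-width reference is the training response column.
    """
    prof = profiles.set_index("patient_id")
    ids = [pid for pid in responses.index if pid in prof.index]
    train_ids, test_ids = split_patients(ids, test_frac=test_frac, seed=split_seed)
    y_train = responses.loc[train_ids].to_numpy(dtype=float)
    y_test = responses.loc[test_ids].to_numpy(dtype=float)
    X_train = prof.loc[train_ids, list(predictors)].reset_index(drop=True)
    X_test = prof.loc[test_ids, list(predictors)].reset_index(drop=True)
    tree = grow_tree(y_train, X_train, alpha=alpha, max_depth=max_depth, min_leaf=min_leaf)
    metrics = []
    for level in levels:
        intervals = make_leaf_intervals(tree, level)
        metrics.append(coverage(intervals, tree, X_test, y_test, y_train, level))
    return metrics


def coverage_width_curve(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    levels,
    responses: list[tuple[str, str, int]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-response, per-level metrics table (long format).

    Each (monitored variable, parameter, state) column gets its own tree;
    rows carry response, level, coverage, relative_width, n_eval. Use
    :func:`average_curve` for the across-response averages.
    """
    if len(levels) < 2:
        raise ValueError("coverage_width_curve needs at least 2 levels")
    if responses is None:
        responses = response_columns(records)
    rows = []
    for variable, parameter, state in responses:
        series = extract_response(records, variable, parameter, state)
        for m in evaluate_response(series, profiles, levels, **kwargs):
            rows.append({
                "response": f"{variable}:{parameter}:{state}",
                "level": m.level, "coverage": m.coverage,
                "relative_width": m.relative_width, "n_eval": m.n_evaluated,
            })
    return pd.DataFrame(rows, columns=["response", "level", "coverage",
                                       "relative_width", "n_eval"])


def average_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Across-response averages of coverage and relative width per level."""
    return (curve.groupby("level", as_index=False)
            .agg(coverage=("coverage", "mean"),
                 relative_width=("relative_width", "mean"),
                 n_responses=("response", "nunique")))
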