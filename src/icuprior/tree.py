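"""Conditional inference tree: p-value-guided binary recursive partitioning.

At each node the predictor with the smallest association p-value (Welch t-test
for binary predictors, correlation test for continuous ones — shared with the
association module) is selected; the minimum p-value is Bonferroni-multiplied
by the number of predictors actually tested and capped at 1. Splitting stops
when the adjusted p-value exceeds ``alpha``, the depth cap is hit, or no
cutpoint leaves both children with at least ``min_leaf`` members.

Cutpoints are midpoints between sorted distinct predictor values; the split
statistic is the standardized absolute two-sample mean difference. Routing
sends ``value <= threshold`` to the left child (binary predictors split at the
midpoint of their two categories, so the lower category goes left).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import correlation_test, welch_t_test

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    kind: str = "leaf"                      # "internal" or "leaf"
    split_variable: str | None = None
    split_point: float | None = None
    split_kind: str | None = None           # "continuous" or "binary"
    p_value: float | None = None            # Bonferroni-adjusted selection p
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    responses: np.ndarray | None = None     # leaf members' response values
    stop_reason: str | None = None

    def leaves(self) -> list["TreeNode"]:
        if self.kind == "leaf":
            return [self]
        return self.left.leaves() + self.right.leaves()

    def max_depth(self) -> int:
        if self.kind == "leaf":
            return self.depth
        return max(self.left.max_depth(), self.right.max_depth())


def _is_binary(x: np.ndarray) -> bool:
    return len(np.unique(x)) <= 2


def _predictor_p_value(responses, x, binary, rng=None, n_perm=0):
    """Association p-value of one predictor, or None when untestable."""
    try:
        if binary:
            cats = np.unique(x)
            if len(cats) < 2:
                return None
            _, _, p = welch_t_test(responses[x == cats[0]], responses[x == cats[1]])
        else:
            _, _, p = correlation_test(x, responses)
    except ValueError:
        return None
    if n_perm > 0:  # optional seeded Monte-Carlo permutation p-value
        obs = _abs_stat(responses, x, binary)
        if obs is None:
            return None
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(responses)
            st = _abs_stat(perm, x, binary)
            if st is not None and st >= obs:
                hits += 1
        p = (1.0 + hits) / (n_perm + 1.0)
    return p


def _abs_stat(responses, x, binary):
    try:
        if binary:
            cats = np.unique(x)
            t, _, _ = welch_t_test(responses[x == cats[0]], responses[x == cats[1]])
            return abs(t)
        r, _, _ = correlation_test(x, responses)
        return abs(r)
    except ValueError:
        return None


def split_variable_selection(
    responses: np.ndarray,
    predictors: pd.DataFrame,
    alpha: float = 0.1,
    method: str = "asymptotic",
    n_perm: int = 9999,
    rng: np.random.Generator | None = None,
) -> tuple[str, float] | None:
    """Pick the predictor with the smallest p-value; None means stop.

    The winning p-value is Bonferroni-adjusted (times the number of tested
    predictors, capped at 1). Ties break to the first predictor in column
    order.
    """
    if np.ptp(responses) == 0:
        return None
    use_perm = method == "permutation"
    if use_perm and rng is None:
        rng = np.random.default_rng(0)
    pvals = []
    for col in predictors.columns:
        x = predictors[col].to_numpy(dtype=float)
        p = _predictor_p_value(responses, x, _is_binary(x),
                               rng=rng, n_perm=n_perm if use_perm else 0)
        if p is not None:
            pvals.append((col, p))
    if not pvals:
        return None
    n_tested = len(pvals)
    best_col, best_p = min(pvals, key=lambda cp: cp[1])  # stable: first wins ties
    adj = min(best_p * n_tested, 1.0)
    if adj > alpha:
        return None
    return best_col, adj


def split_point_search(responses: np.ndarray, x: np.ndarray, min_leaf: int = 20
                       ) -> float | None:
    """Threshold maximizing the standardized |mean difference|; None if none
    is admissible (both children must keep >= min_leaf members)."""
    x = np.asarray(x, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], responses[order]
    n = len(ys)
    # candidate cuts sit between consecutive distinct sorted values; prefix
    # sums give both children's means/variances in O(n)
    cut = np.flatnonzero(xs[:-1] != xs[1:])  # left child = ys[:i+1]
    n_left = cut + 1
    n_right = n - n_left
    ok = (n_left >= min_leaf) & (n_right >= min_leaf)
    if not ok.any():
        return None
    cut = cut[ok]
    n_left, n_right = n_left[ok].astype(float), n_right[ok].astype(float)
    cs, cs2 = np.cumsum(ys), np.cumsum(ys**2)
    sum_l = cs[cut]
    sum_r = cs[-1] - sum_l
    sq_l = cs2[cut]
    sq_r = cs2[-1] - sq_l
    mean_l, mean_r = sum_l / n_left, sum_r / n_right
    var_l = np.maximum(sq_l - n_left * mean_l**2, 0.0) / np.maximum(n_left - 1, 1)
    var_r = np.maximum(sq_r - n_right * mean_r**2, 0.0) / np.maximum(n_right - 1, 1)
    se2 = var_l / n_left + var_r / n_right
    diff = np.abs(mean_l - mean_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se2 > 0, diff / np.sqrt(se2),
                        np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(stat))  # ties break to the lowest threshold
    if stat[best] <= 0:
        return None
    return float(0.5 * (xs[cut[best]] + xs[cut[best] + 1]))


def grow_tree(
    responses,
    predictors: pd.DataFrame,
    alpha: float = 0.1,
    max_depth: int = 5,
    min_leaf: int = 20,
    selection_method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> TreeNode:
    """Recursive partitioning of the response on the predictor columns."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        raise ValueError("empty input: no responses to partition")
    if len(predictors) != responses.size:
        raise ValueError("responses and predictors must have equal length")
    predictors = predictors.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(node_id=counter[0], depth=depth, n=len(idx))
        counter[0] += 1
        y = responses[idx]
        stop = None
        if depth >= max_depth:
            stop = "max_depth"
        elif len(idx) < 2 * min_leaf:
            stop = "min_leaf"
        sel = None
        if stop is None:
            sel = split_variable_selection(
                y, predictors.iloc[idx], alpha=alpha,
                method=selection_method, n_perm=n_perm, rng=rng,
            )
            if sel is None:
                stop = "alpha"
        thr = None
        if sel is not None:
            var, p_adj = sel
            x = predictors[var].to_numpy(dtype=float)[idx]
            thr = split_point_search(y, x, min_leaf=min_leaf)
            if thr is None:
                stop = "no_admissible_cutpoint"
        if stop is not None:
            node.responses = y
            node.stop_reason = stop
            return node
        node.kind = "internal"
        node.split_variable = var
        node.split_point = thr
        node.split_kind = "binary" if _is_binary(x) else "continuous"
        node.p_value = p_adj
        mask = x <= thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(responses.size), 0)
    logger.info("tree grown: %d leaves, depth %d", len(root.leaves()), root.max_depth())
    return root


def route(tree: TreeNode, profile) -> int:
    """Leaf node_id a covariate profile lands in (<= threshold goes left)."""
    node = tree
    while node.kind == "internal":
        try:
            value = float(profile[node.split_variable])
        except (KeyError, IndexError) as exc:
            raise ValueError(f"profile is missing split variable '{node.split_variable}'") from exc
        node = node.left if value <= node.split_point else node.right
    return node.node_id


def leaf_map(tree: TreeNode) -> dict[int, TreeNode]:
    return {leaf.node_id: leaf for leaf in tree.leaves()}


def tree_to_dict(tree: TreeNode, response_name: str | None = None) -> dict:
    nodes = []

    def visit(node: TreeNode):
        entry = {
            "node_id": node.node_id, "depth": node.depth, "n": node.n,
            "kind": node.kind,
        }
        if node.kind == "internal":
            entry.update({
                "split_variable": node.split_variable,
                "split_point": node.split_point,
                "split_kind": node.split_kind,
                "p_value": node.p_value,
                "left": node.left.node_id,
                "right": node.right.node_id,
            })
            nodes.append(entry)
            visit(node.left)
            visit(node.right)
        else:
            y = node.responses
            entry.update({
                "stop_reason": node.stop_reason,
                "responses": [float(v) for v in y],
                "summary": {"mean": float(np.mean(y)), "sd": float(np.std(y, ddof=1))
                            if len(y) > 1 else 0.0},
            })
            nodes.append(entry)

    visit(tree)
    return {"response": response_name, "nodes": nodes}


def tree_from_dict(doc: dict) -> TreeNode:
    by_id = {}
    for entry in doc["nodes"]:
        node = TreeNode(node_id=entry["node_id"], depth=entry["depth"],
                        n=entry["n"], kind=entry["kind"])
        if entry["kind"] == "internal":
            node.split_variable = entry["split_variable"]
            node.split_point = entry["split_point"]
            node.split_kind = entry["split_kind"]
            node.p_value = entry["p_value"]
            node._child_ids = (entry["left"], entry["right"])
        else:
            node.responses = np.asarray(entry["responses"], dtype=float)
            node.stop_reason = entry.get("stop_reason")
        by_id[node.node_id] = node
    for node in by_id.values():
        if node.kind == "internal":
            left_id, right_id = node._child_ids
            node.left, node.right = by_id[left_id], by_id[right_id]
            del node._child_ids
    return by_id[doc["nodes"][0]["node_id"]]


def save_tree(tree: TreeNode, path, response_name: str | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree, response_name), fh, indent=1)


def load_tree(path) -> tuple[TreeNode, str | None]:
    with open(path) as fh:
        doc = json.load(fh)
    return tree_from_dict(doc), doc.get("response")
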