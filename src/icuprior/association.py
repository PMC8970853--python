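"""Significance tests linking fitted emission parameters to basic covariates.

Binary covariates (sex) are tested with Welch's unequal-variance t-test;
continuous covariates (age, weight, height, BMI) with a Pearson correlation
test (Spearman available behind a flag). p-values are reported raw; the
significance threshold is a reporting convention, not an adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BINARY_COVARIATES = ("sex",)
CONTINUOUS_COVARIATES = ("age", "weight", "height", "bmi")


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.size} and {b.size})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa2, sb2 = va / a.size, vb / b.size
    se2 = sa2 + sb2
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero pooled spread with unequal means: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def correlation_test(x, y, method: str = "pearson", name: str = "x"
                     ) -> tuple[float, float, float]:
    """Correlation r, its t statistic t = r*sqrt((n-2)/(1-r^2)), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation test needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError(f"variable '{name}' is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; correlation undefined")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method}")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, float("inf"), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(t), float(p)


def build_association_table(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    alpha: float = 0.01,
    method: str = "pearson",
    binary_covariates=BINARY_COVARIATES,
    continuous_covariates=CONTINUOUS_COVARIATES,
) -> pd.DataFrame:
    """One test per (basic variable, monitored variable, parameter, state).

    Degenerate cells (constant parameter or covariate across patients, or a
    group too small to test) are kept in the table flagged ``untestable``
    rather than dropped. Deterministic given its inputs.
    """
    wide = records.pivot_table(
        index="patient_id", columns=["variable", "state"],
        values=["mu_hat", "sigma_hat"], sort=True,
    )
    prof = profiles.set_index("patient_id").loc[wide.index]
    rows = []
    for param, variable, state in wide.columns:
        resp = wide[(param, variable, state)].to_numpy(dtype=float)
        pname = "mu" if param == "mu_hat" else "sigma"
        for basic in list(binary_covariates) + list(continuous_covariates):
            if basic not in prof.columns:
                continue
            x = prof[basic].to_numpy(dtype=float)
            kind = "t_test" if basic in binary_covariates else f"correlation_{method}"
            stat = p = np.nan
            untestable = False
            try:
                if basic in binary_covariates:
                    cats = np.unique(x)
                    if len(cats) != 2:
                        raise ValueError("binary covariate not two-valued")
                    stat, _, p = welch_t_test(resp[x == cats[0]], resp[x == cats[1]])
                else:
                    stat, _, p = correlation_test(x, resp, method=method, name=basic)
            except ValueError as exc:
                untestable = True
                logger.info("untestable cell (%s, %s, %s, state %s): %s",
                            basic, variable, pname, state, exc)
            rows.append({
                "basic_var": basic, "monitored_var": variable, "parameter": pname,
                "state": state, "statistic": stat, "p_value": p, "test_kind": kind,
                "significant": bool(p < alpha) if not untestable else False,
                "untestable": untestable,
            })
    table = pd.DataFrame(rows, columns=["basic_var", "monitored_var", "parameter",
                                        "state", "statistic", "p_value", "test_kind",
                                        "significant", "untestable"])
    return table.sort_values(
        ["monitored_var", "parameter", "state", "basic_var"], kind="stable"
    ).reset_index(drop=True)


def association_table_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to the reporting layout: basic variables as rows, monitored
    variable x parameter x state as columns of p-values."""
    return table.pivot_table(
        index="basic_var", columns=["monitored_var", "parameter", "state"],
        values="p_value", sort=True,
    )
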