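"""Marginal (one-nutrient-at-a-time) association scan.

For each nutrient X and outcome Y the model is

    Y_z ~ 1 + age + sex + site + income + X_z

with the outcome and the nutrient z-scored and the four confounders on
their raw scale.  The nutrient's OLS coefficient is the reported
standardized coefficient; its confidence interval and two-sided p-value
come from the t distribution on the residual degrees of freedom
(n - 6 with four confounders).  Raw p-values are adjusted with the
Benjamini-Hochberg step-up procedure within a configurable family
(default: all nutrient x outcome pairs of one instrument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import AnalysisFrame

__all__ = [
    "MarginalResult",
    "fit_adjusted_model",
    "ci_from_coef_p",
    "bh_adjust",
    "marginal_scan",
    "scan_pivot",
]


@dataclass
class MarginalResult:
    """One nutrient-outcome standardized coefficient with inference."""

    nutrient: str
    outcome: str
    std_coef: float
    ci_low: float
    ci_high: float
    p_raw: float
    n: int
    df_resid: int
    p_adj: float | None = None


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (v - v.mean()) / sd


def fit_adjusted_model(
    y, x, confounders: pd.DataFrame | None, nutrient: str = "", outcome: str = ""
) -> MarginalResult:
    """OLS fit of one standardized nutrient against one standardized outcome,
    adjusting for the (raw-scale) confounders."""
    y = _z(np.asarray(y, dtype=float))
    x = _z(np.asarray(x, dtype=float))
    n = len(y)
    if confounders is not None and len(confounders.columns):
        C = confounders.to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), C, x])
    else:
        X = np.column_stack([np.ones(n), x])
    if n <= X.shape[1]:
        raise ValueError(f"n={n} too small for {X.shape[1]} regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(y, X).fit()
    coef = fit.params[-1]
    ci = fit.conf_int(alpha=0.05)[-1]
    return MarginalResult(
        nutrient=nutrient,
        outcome=outcome,
        std_coef=float(coef),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_raw=float(fit.pvalues[-1]),
        n=n,
        df_resid=int(fit.df_resid),
    )


def ci_from_coef_p(coef: float, p_raw: float, df_resid: int, level: float = 0.95):
    """Reconstruct a coefficient's confidence interval from its value, its
    two-sided p-value and the residual degrees of freedom.

    The implied standard error is |coef| / t_obs with
    t_obs = t.isf(p/2, df); the interval is coef +/- t_crit * se.
    """
    if not 0 < p_raw <= 1:
        raise ValueError("p_raw must lie in (0, 1]")
    t_obs = stats.t.isf(p_raw / 2.0, df_resid)
    se = abs(coef) / t_obs
    t_crit = stats.t.ppf(0.5 + level / 2.0, df_resid)
    return coef - t_crit * se, coef + t_crit * se


def bh_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` (>= len(p_values)) overrides the number of tests m in
    the family, for families only partially represented in the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    m = family_size if family_size is not None else k
    if m < k:
        raise ValueError("family_size must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def marginal_scan(
    frame: AnalysisFrame,
    nutrients: list[str] | None = None,
    outcomes: list[str] | None = None,
    family: str = "per_instrument",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Run the marginal model over every nutrient x outcome pair.

    ``family`` controls FDR grouping: "per_instrument" (default) adjusts
    across all pairs in one go; "per_outcome" adjusts within each outcome's
    14 tests.  ``family_size`` optionally overrides m.
    """
    nutrients = nutrients if nutrients is not None else frame.nutrient_cols
    outcomes = outcomes if outcomes is not None else frame.outcome_cols
    if not outcomes:
        raise ValueError("no outcomes to scan")
    conf = frame.df[frame.confounder_cols]
    rows = []
    for out in outcomes:
        for nut in nutrients:
            res = fit_adjusted_model(frame.df[out], frame.df[nut], conf, nut, out)
            rows.append(res)
    table = pd.DataFrame([vars(r) for r in rows])
    if family == "per_instrument":
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy(), family_size)
    elif family == "per_outcome":
        for out in outcomes:
            mask = table["outcome"] == out
            table.loc[mask, "p_adj"] = bh_adjust(
                table.loc[mask, "p_raw"].to_numpy(), family_size
            )
    else:
        raise ValueError(f"unknown FDR family policy {family!r}")
    return table


def scan_pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Wide rendering (nutrients x outcomes) of a scan: "coef (p)" strings,
    matching the published table layout."""
    def cell(row):
        return f"{row.std_coef:.2f} ({row.p_raw:.3g})"

    wide = table.assign(cell=table.apply(cell, axis=1)).pivot(
        index="nutrient", columns="outcome", values="cell"
    )
    order = table["nutrient"].drop_duplicates().tolist()
    return wide.loc[order, table["outcome"].drop_duplicates().tolist()]
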