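"""Cluster-constrained best-subset regression.

The joint model regresses a (z-scored) outcome on the four confounders plus
a subset of standardized nutrients containing at most one member of each
correlation cluster.  Every admissible subset (including the empty one) is
fit by OLS and the subset maximizing the adjusted R-squared is selected;
adjusted R-squared counts the selected nutrients plus the confounders as
regressors.  Overall model significance is the nested ANOVA F-test of the
selected model against the confounder-only baseline, with BH adjustment
across the instrument's outcomes.

The F-test p-value is computed on the same data used for selection and is
therefore anti-conservative post-selection; outputs carry that label.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clustering import ClusterSolution
from .marginal import bh_adjust
from .preprocess import AnalysisFrame

logger = logging.getLogger("milkcog")

__all__ = [
    "CandidateModel",
    "FitResult",
    "enumerate_candidates",
    "adjusted_r2",
    "best_subset_fit",
    "nested_anova_f",
    "select_models",
    "selection_table",
]

POST_SELECTION_NOTE = (
    "p-value computed on the data used for selection; anti-conservative"
)


@dataclass(frozen=True)
class CandidateModel:
    """A nutrient subset with at most one member per cluster."""

    selected: tuple[str, ...]
    cluster_ids: tuple[int, ...]

    @property
    def q(self) -> int:
        return len(self.selected)

    def __post_init__(self) -> None:
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise ValueError("two selected nutrients share a cluster")


@dataclass
class FitResult:
    """Fitted joint model for one outcome."""

    outcome: str
    candidate: CandidateModel
    r2: float
    adj_r2: float
    aic: float
    coefficients: pd.Series
    coef_pvalues: pd.Series
    f_stat: float | None
    p_raw: float | None
    n: int
    p_adj: float | None = None
    note: str = POST_SELECTION_NOTE
    n_candidates: int = 0


def enumerate_candidates(solution: ClusterSolution) -> list[CandidateModel]:
    """All subsets with at most one nutrient per cluster, including the
    empty set; their count is the product over clusters of (size + 1)."""
    members = solution.members()
    cluster_ids = sorted(members)
    choices = [[None] + sorted(members[c]) for c in cluster_ids]
    out = []
    for combo in itertools.product(*choices):
        sel = tuple(x for x in combo if x is not None)
        cids = tuple(c for c, x in zip(cluster_ids, combo) if x is not None)
        out.append(CandidateModel(selected=sel, cluster_ids=cids))
    return out


def adjusted_r2(r2: float, n: int, n_regressors: int) -> float:
    """1 - (1 - r2) (n - 1) / (n - n_regressors - 1)."""
    if n <= n_regressors + 1:
        raise ValueError("degenerate degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_regressors - 1)


def _design(frame: AnalysisFrame, selected: tuple[str, ...]) -> np.ndarray:
    df = frame.df
    cols = [np.ones(frame.n)]
    cols += [df[c].to_numpy(dtype=float) for c in frame.confounder_cols]
    cols += [df[c].to_numpy(dtype=float) for c in selected]
    return np.column_stack(cols)


def best_subset_fit(
    frame: AnalysisFrame,
    outcome: str,
    solution: ClusterSolution | None = None,
    candidates: list[CandidateModel] | None = None,
) -> FitResult:
    """Exhaustive adjusted-R-squared search over the admissible subsets.

    Confounders are always included and never count toward the cluster
    constraint.  Ties in adjusted R-squared break toward fewer nutrients,
    then lexicographic nutrient order.  Rank-deficient candidates are
    skipped with a log message.
    """
    if candidates is None:
        if solution is None:
            raise ValueError("provide a cluster solution or explicit candidates")
        candidates = enumerate_candidates(solution)
    y = frame.df[outcome].to_numpy(dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError(f"constant outcome {outcome!r}")
    yz = (y - y.mean()) / sd
    n = frame.n
    n_conf = len(frame.confounder_cols)
    tss = float(((yz - yz.mean()) ** 2).sum())
    best: tuple | None = None
    for cand in candidates:
        X = _design(frame, cand.selected)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("skipping rank-deficient candidate %s", cand.selected)
            continue
        coef, _, _, _ = np.linalg.lstsq(X, yz, rcond=None)
        rss = float(((yz - X @ coef) ** 2).sum())
        r2 = 1.0 - rss / tss
        a = adjusted_r2(r2, n, cand.q + n_conf)
        key = (-a, cand.q, cand.selected)
        if best is None or key < best[0]:
            best = (key, cand)
    if best is None:
        raise ValueError("every candidate design was rank-deficient")
    cand = best[1]
    # final inference fit via statsmodels
    X = _design(frame, cand.selected)
    names = ["intercept"] + list(frame.confounder_cols) + list(cand.selected)
    fit = sm.OLS(yz, X).fit()
    r2 = float(fit.rsquared)
    a = adjusted_r2(r2, n, cand.q + n_conf)
    X0 = _design(frame, ())
    fit0 = sm.OLS(yz, X0).fit()
    if cand.q > 0:
        f_stat, p_raw = nested_anova_f(fit, fit0)
    else:
        f_stat, p_raw = None, None
    return FitResult(
        outcome=outcome,
        candidate=cand,
        r2=r2,
        adj_r2=a,
        aic=float(fit.aic),
        coefficients=pd.Series(fit.params, index=names),
        coef_pvalues=pd.Series(fit.pvalues, index=names),
        f_stat=f_stat,
        p_raw=p_raw,
        n=n,
        n_candidates=len(candidates),
    )


def nested_anova_f(fit_full, fit_reduced) -> tuple[float, float]:
    """ANOVA F-test of a full OLS fit against a nested reduced fit.

    F = [(RSS_red - RSS_full) / q] / [RSS_full / df_resid_full].  Equal
    regressor sets (q = 0) are an error; a saturated full model (zero RSS)
    returns p = 0.
    """
    q = int(fit_reduced.df_resid - fit_full.df_resid)
    if q <= 0:
        raise ValueError("full model adds no regressors over the reduced model")
    rss_full = float(fit_full.ssr)
    rss_red = float(fit_reduced.ssr)
    df_full = float(fit_full.df_resid)
    if df_full <= 0 or rss_full <= 1e-12 * max(rss_red, 1.0):
        return np.inf, 0.0  # saturated (or numerically perfect) full fit
    f = max((rss_red - rss_full) / q, 0.0) / (rss_full / df_full)
    p = float(stats.f.sf(f, q, df_full))
    return float(f), p


def select_models(
    frame: AnalysisFrame,
    solution: ClusterSolution,
    outcomes: list[str] | None = None,
) -> list[FitResult]:
    """Run the constrained best-subset selection for each outcome of one
    instrument and BH-adjust the nested-F p-values across those outcomes."""
    outcomes = outcomes if outcomes is not None else frame.outcome_cols
    candidates = enumerate_candidates(solution)
    fits = [best_subset_fit(frame, out, candidates=candidates) for out in outcomes]
    tested = [f for f in fits if f.p_raw is not None]
    if tested:
        adj = bh_adjust([f.p_raw for f in tested])
        for f, a in zip(tested, adj):
            f.p_adj = float(a)
    return fits


def selection_table(fits: list[FitResult], nutrients: list[str]) -> pd.DataFrame:
    """Published-style summary: one column per outcome; rows are R-squared,
    adjusted R-squared, raw/adjusted model p, per-nutrient coefficients with
    p-values ("-" when unselected), then the confounder rows."""
    conf_names = None
    data = {}
    for f in fits:
        col = {
            "R-squared": f"{f.r2:.2f}",
            "Adjusted R-squared": f"{f.adj_r2:.2f}",
            "Raw p-value": "-" if f.p_raw is None else f"{f.p_raw:.3g}",
            "Adjusted p-value": "-" if f.p_adj is None else f"{f.p_adj:.3g}",
        }
        for nut in nutrients:
            if nut in f.candidate.selected:
                col[nut] = f"{f.coefficients[nut]:.2f} ({f.coef_pvalues[nut]:.2g})"
            else:
                col[nut] = "-"
        sel_set = set(nutrients) | {"intercept"}
        confs = [c for c in f.coefficients.index if c not in sel_set]
        conf_names = confs
        for c in confs:
            col[c] = f"{f.coefficients[c]:.2f} ({f.coef_pvalues[c]:.2g})"
        data[f.outcome] = col
    index = (
        ["R-squared", "Adjusted R-squared", "Raw p-value", "Adjusted p-value"]
        + nutrients
        + (conf_names or [])
    )
    return pd.DataFrame(data).reindex(index)
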