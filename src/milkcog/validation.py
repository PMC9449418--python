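"""Model validation: repeated k-fold cross-validation and follow-up
age-bin prediction.

The selected nutrient set is held fixed (selection is not re-run inside
folds, matching how the models were evaluated; the resulting optimism is
labelled in the output).  Each repetition randomly partitions the subjects
into k folds, refits the coefficients on each training 4/5, predicts the
held-out fold, pools all out-of-fold predictions, and records one Pearson
correlation and mean squared error.  Significance of a correlation r at
sample size n uses the t statistic r sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom.

Follow-up prediction freezes the fitted coefficients and applies them to
each follow-up subject's baseline standardized nutrients and baseline
confounders, comparing against the scores observed in each follow-up age
bin (lo, hi].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AnalysisFrame
from .selection import FitResult, POST_SELECTION_NOTE

__all__ = [
    "CVResult",
    "FollowupPrediction",
    "repeated_cv",
    "correlation_t_test",
    "significance_threshold_r",
    "followup_predict",
]

DEFAULT_BINS = ((6.0, 9.0), (9.0, 12.0), (12.0, 18.0))


@dataclass
class CVResult:
    """Per-repetition pooled out-of-fold prediction quality."""

    outcome: str
    correlations: np.ndarray  # one per repetition
    mse: np.ndarray
    train_mse: np.ndarray
    r_star: float  # two-sided significance threshold at alpha for pooled n
    fraction_significant: float
    mean_correlation: float
    interval: tuple[float, float]  # central 95% percentile interval
    n: int
    folds: int
    note: str = POST_SELECTION_NOTE


@dataclass
class FollowupPrediction:
    """Predicted-vs-observed agreement within one follow-up age bin."""

    outcome: str
    age_bin: tuple[float, float]
    subject_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray
    pearson_r: float
    p_value: float
    n: int


def correlation_t_test(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t distribution
    with n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        warnings.warn("|r| = 1: p-value is the limiting value 0")
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def significance_threshold_r(n: int, alpha: float = 0.05) -> float:
    """The |r| above which a correlation is significant at two-sided alpha:
    the solution of the t-quantile equation at n - 2 df."""
    tc = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tc / np.sqrt(n - 2 + tc**2))


def repeated_cv(
    frame: AnalysisFrame,
    outcome: str,
    selected: tuple[str, ...],
    folds: int = 5,
    reps: int = 100,
    seed=None,
    alpha: float = 0.05,
) -> CVResult:
    """Repeated k-fold CV of the fixed selected model, refitting the
    coefficients per training fold and pooling out-of-fold predictions."""
    n = frame.n
    if n < folds:
        raise ValueError("fewer subjects than folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = frame.df[outcome].to_numpy(dtype=float)
    yz = (y - y.mean()) / y.std(ddof=1)
    cols = [np.ones(n)]
    cols += [frame.df[c].to_numpy(dtype=float) for c in frame.confounder_cols]
    cols += [frame.df[c].to_numpy(dtype=float) for c in selected]
    X = np.column_stack(cols)
    corrs = np.empty(reps)
    mses = np.empty(reps)
    train_mses = np.empty(reps)
    for rep in range(reps):
        perm = rng.permutation(n)
        pred = np.empty(n)
        tr_sse = 0.0
        tr_n = 0
        for fold in np.array_split(perm, folds):
            if len(fold) == 0:
                raise ValueError("fold with zero test rows")
            train = np.setdiff1d(perm, fold, assume_unique=True)
            coef, _, _, _ = np.linalg.lstsq(X[train], yz[train], rcond=None)
            pred[fold] = X[fold] @ coef
            resid = yz[train] - X[train] @ coef
            tr_sse += float((resid**2).sum())
            tr_n += len(train)
        corrs[rep] = np.corrcoef(pred, yz)[0, 1]
        mses[rep] = float(((pred - yz) ** 2).mean())
        train_mses[rep] = tr_sse / tr_n
    r_star = significance_threshold_r(n, alpha)
    # a repetition counts as significant when its pooled prediction
    # correlation exceeds the positive threshold: out-of-fold predictions
    # under a null model are negatively biased, so a two-sided count would
    # flag anti-predictive noise fits as successes
    frac = float((corrs > r_star).mean())
    lo, hi = np.percentile(corrs, [2.5, 97.5])
    return CVResult(
        outcome=outcome,
        correlations=corrs,
        mse=mses,
        train_mse=train_mses,
        r_star=r_star,
        fraction_significant=frac,
        mean_correlation=float(corrs.mean()),
        interval=(float(lo), float(hi)),
        n=n,
        folds=folds,
    )


def _predict(fit: FitResult, frame: AnalysisFrame, rows: pd.DataFrame,
             age_col: str = "visit_age_months") -> np.ndarray:
    names = list(fit.coefficients.index)
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(len(rows)))
        elif name == "visit_age_months":
            cols.append(rows[age_col].to_numpy(dtype=float))
        else:
            cols.append(rows[name].to_numpy(dtype=float))
    return np.column_stack(cols) @ fit.coefficients.to_numpy()


def followup_predict(
    fit: FitResult,
    frame: AnalysisFrame,
    followup: pd.DataFrame,
    outcome: str | None = None,
    bins=DEFAULT_BINS,
    use_followup_age: bool = False,
    min_bin_n: int = 3,
) -> list[FollowupPrediction]:
    """Frozen-coefficient prediction of follow-up scores per age bin.

    Baseline standardized nutrients and baseline confounders feed the
    prediction; ``use_followup_age`` swaps the age covariate for the
    follow-up visit age.  Each bin must hold each subject at most once and
    at least ``min_bin_n`` subjects.
    """
    outcome = outcome if outcome is not None else fit.outcome
    if outcome not in followup.columns:
        raise ValueError(f"follow-up table lacks outcome column {outcome!r}")
    base = frame.df.set_index("subject_id")
    results = []
    for lo, hi in bins:
        mask = (followup["visit_age_months"] > lo) & (followup["visit_age_months"] <= hi)
        sub = followup.loc[mask & followup[outcome].notna()]
        if sub.empty:
            continue
        if sub["subject_id"].duplicated().any():
            raise ValueError(f"duplicate subject in bin ({lo}, {hi}]")
        known = sub["subject_id"].isin(base.index)
        sub = sub.loc[known]
        if len(sub) < min_bin_n:
            raise ValueError(f"bin ({lo}, {hi}] has fewer than {min_bin_n} subjects")
        rows = base.loc[sub["subject_id"]].reset_index()
        if use_followup_age:
            rows = rows.assign(
                visit_age_months=sub["visit_age_months"].to_numpy()
            )
        pred = _predict(fit, frame, rows)
        obs = sub[outcome].to_numpy(dtype=float)
        r = float(np.corrcoef(pred, obs)[0, 1])
        results.append(
            FollowupPrediction(
                outcome=outcome,
                age_bin=(lo, hi),
                subject_ids=sub["subject_id"].tolist(),
                predicted=pred,
                observed=obs,
                pearson_r=r,
                p_value=correlation_t_test(r, len(sub)),
                n=len(sub),
            )
        )
    return results
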