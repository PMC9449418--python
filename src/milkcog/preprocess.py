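"""Standardization, imputation and cohort-description statistics.

Nutrient concentrations are z-scored to zero mean and unit variance within
each analysis subset (subjects assessed with a given instrument), since
each instrument's models are fit on a different subject set.  Confounders
are left on their raw scale.  Missing household-income indicators are
replaced by the mean of the observed values (single mean imputation;
fractional values are permitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONFOUNDERS, NUTRIENTS
from .scoring import FactorLoadings, attach_scores

__all__ = [
    "AnalysisFrame",
    "standardize_columns",
    "impute_income",
    "nutrient_age_trends",
    "compare_cohort_subsets",
    "build_analysis_frame",
    "cohort_characteristics",
]

MSEL_OUTCOMES = ["msel_elc", "msel_gm", "msel_vr", "msel_fm", "msel_rl", "msel_el"]
IBQ_OUTCOMES = ["ibq_sur", "ibq_neg", "ibq_reg"]


def standardize_columns(
    df: pd.DataFrame, columns: list[str], raw_prefix: str = "raw_"
) -> pd.DataFrame:
    """Z-score the named columns (sample SD, ddof=1), keeping the originals
    under a ``raw_`` prefix.  A constant column is an error."""
    out = df.copy()
    for col in columns:
        v = out[col].astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant column {col!r}")
        raw_name = raw_prefix + col
        if raw_name not in out.columns:
            out[raw_name] = v
        out[col] = (v - v.mean()) / sd
    return out


def impute_income(col: pd.Series) -> pd.Series:
    """Replace missing income indicators with the mean of the observed ones."""
    observed = col.dropna()
    if observed.empty:
        raise ValueError("income column has no observed values to impute from")
    return col.fillna(observed.mean())


def nutrient_age_trends(
    df: pd.DataFrame, nutrients: list[str] | None = None, age_col: str = "visit_age_months"
) -> pd.DataFrame:
    """Per-nutrient slope and two-sided p-value from simple linear regression
    of concentration on postpartum age."""
    nutrients = nutrients if nutrients is not None else [c for c in NUTRIENTS if c in df]
    if len(df) < 3:
        raise ValueError("need at least 3 rows for an age trend")
    age = df[age_col].astype(float)
    if age.std(ddof=1) == 0:
        raise ValueError("degenerate age column")
    rows = []
    for nut in nutrients:
        res = stats.linregress(age, df[nut].astype(float))
        rows.append({"nutrient": nut, "slope": res.slope, "p_value": res.pvalue})
    return pd.DataFrame(rows).set_index("nutrient")


def compare_cohort_subsets(
    df: pd.DataFrame,
    ids_a,
    ids_b,
    nutrients: list[str] | None = None,
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Welch two-sided two-sample t-test per nutrient between two (possibly
    overlapping) subject subsets."""
    nutrients = nutrients if nutrients is not None else [c for c in NUTRIENTS if c in df]
    a = df[df[id_col].isin(set(ids_a))]
    b = df[df[id_col].isin(set(ids_b))]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each subset needs at least 2 rows")
    rows = []
    for nut in nutrients:
        t, p = stats.ttest_ind(a[nut], b[nut], equal_var=False)
        rows.append({"nutrient": nut, "t_stat": t, "p_value": p,
                     "mean_a": a[nut].mean(), "mean_b": b[nut].mean()})
    return pd.DataFrame(rows).set_index("nutrient")


@dataclass
class AnalysisFrame:
    """Model-ready table for one instrument: standardized nutrients, raw
    confounders (income imputed), outcome columns."""

    df: pd.DataFrame
    nutrient_cols: list[str]
    confounder_cols: list[str] = field(default_factory=lambda: list(CONFOUNDERS))
    outcome_cols: list[str] = field(default_factory=list)
    instrument: str = ""

    @property
    def n(self) -> int:
        return len(self.df)


def build_analysis_frame(
    baseline: pd.DataFrame,
    instrument: str,
    loadings: FactorLoadings | None = None,
) -> AnalysisFrame:
    """Subset the cohort to subjects with the instrument's scores, attach
    composites, impute income, and standardize the nutrient columns."""
    if instrument not in ("msel", "ibq"):
        raise ValueError("instrument must be 'msel' or 'ibq'")
    scored = attach_scores(baseline, loadings)
    outcomes = MSEL_OUTCOMES if instrument == "msel" else IBQ_OUTCOMES
    outcomes = [c for c in outcomes if c in scored.columns]
    if not outcomes:
        raise ValueError(f"no {instrument} outcome columns present")
    mask = scored[outcomes].notna().all(axis=1)
    sub = scored.loc[mask].reset_index(drop=True).copy()
    sub["income_lt75k"] = impute_income(sub["income_lt75k"])
    nutrient_cols = [c for c in NUTRIENTS if c in sub.columns]
    sub = standardize_columns(sub, nutrient_cols)
    return AnalysisFrame(
        df=sub,
        nutrient_cols=nutrient_cols,
        confounder_cols=list(CONFOUNDERS),
        outcome_cols=outcomes,
        instrument=instrument,
    )


def cohort_characteristics(baseline: pd.DataFrame, followup: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort-description table: subject counts, sex, age and income mix for
    the full cohort and each instrument subset (and follow-up bins if given)."""
    def describe(df: pd.DataFrame, label: str) -> dict:
        return {
            "subset": label,
            "n": len(df),
            "n_male": int(df["sex"].sum()) if "sex" in df else np.nan,
            "age_mean": df["visit_age_months"].mean(),
            "age_sd": df["visit_age_months"].std(ddof=1),
            "n_income_lt75k": int((df["income_lt75k"] == 1).sum()) if "income_lt75k" in df else np.nan,
            "n_income_missing": int(df["income_lt75k"].isna().sum()) if "income_lt75k" in df else np.nan,
        }

    msel_mask = baseline[[c for c in baseline if c.startswith("msel_")]].notna().all(axis=1)
    ibq_mask = baseline[[c for c in baseline if c.startswith("ibq_")]].notna().all(axis=1)
    rows = [
        describe(baseline, "all"),
        describe(baseline[msel_mask], "msel_baseline"),
        describe(baseline[ibq_mask], "ibq_baseline"),
        describe(baseline[msel_mask & ibq_mask], "both"),
    ]
    if followup is not None and len(followup):
        for (instr, label), grp in followup.groupby(["instrument", "age_bin"], sort=False):
            d = describe(grp.merge(baseline[["subject_id", "sex", "income_lt75k"]],
                                   on="subject_id", suffixes=("_f", "")), f"{instr}_{label}")
            rows.append(d)
    return pd.DataFrame(rows).set_index("subset")
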