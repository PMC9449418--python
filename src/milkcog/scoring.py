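"""Composite outcome scores.

The MSEL early learning composite (ELC) is the sum of the four
non-gross-motor subscale T-scores (visual reception, fine motor, receptive
language, expressive language).  The three IBQ-R temperament factors —
surgency/extraversion (SUR), negative affectivity (NEG) and
orienting/regulation (REG) — are linear weighted averages of the 14 IBQ-R
subscale means under a user-supplied loading matrix.

The loading matrix shipped with the package
(``data/ibq_loadings_placeholder.csv``) is a synthetic placeholder that
assigns each subscale to a single factor with unit weight; it exists so the
pipeline is runnable end-to-end.  Analyses of real data should load the
published exploratory-factor-analysis weights instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["FactorLoadings", "compute_elc", "compute_ibq_factors", "attach_scores"]

FACTORS = ["sur", "neg", "reg"]


def compute_elc(vr, fm, rl, el, gm=None):
    """Early learning composite: vr + fm + rl + el.

    The gross-motor T-score is accepted for interface symmetry but never
    enters the composite.  Missing subscales propagate to a missing
    composite.  Works elementwise on scalars, arrays and Series.
    """
    return vr + fm + rl + el


@dataclass
class FactorLoadings:
    """14-subscale x 3-factor weight matrix for the IBQ-R."""

    matrix: pd.DataFrame  # index: subscale names, columns: sur/neg/reg

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[1] != 3:
            raise ValueError("loadings must have exactly 3 factor columns")
        if m.shape[0] != 14:
            raise ValueError("loadings must have exactly 14 subscale rows")
        if (m != 0).sum(axis=0).min() == 0:
            raise ValueError("every factor needs at least one nonzero weight")

    @property
    def subscale_names(self) -> list[str]:
        return list(self.matrix.index)

    @classmethod
    def from_csv(cls, path) -> "FactorLoadings":
        df = pd.read_csv(path, index_col=0)
        df.columns = [c.lower() for c in df.columns]
        return cls(df[FACTORS])

    @classmethod
    def placeholder(cls) -> "FactorLoadings":
        """The synthetic placeholder loadings shipped with the package."""
        ref = resources.files("milkcog").joinpath("data/ibq_loadings_placeholder.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def compute_ibq_factors(
    subscales, loadings: FactorLoadings, normalize: bool = True
):
    """Factor scores as weighted averages of the 14 subscale means.

    Each factor is ``sum_i w_i s_i / sum_i w_i`` over the subscales with
    nonzero weight for that factor; ``normalize=False`` returns the raw
    weighted sum instead.  ``subscales`` may be a length-14 sequence/Series
    (returns a Series) or a DataFrame with the loading matrix's subscale
    columns (returns a DataFrame with one row per input row).
    """
    names = loadings.subscale_names
    if isinstance(subscales, pd.DataFrame):
        missing = [c for c in names if c not in subscales.columns]
        if missing:
            raise ValueError(f"subscale columns missing: {missing}")
        values = subscales[names].to_numpy(dtype=float)
    else:
        arr = np.asarray(subscales, dtype=float)
        if arr.ndim != 1 or arr.shape[0] != 14:
            raise ValueError("expected 14 subscale values")
        values = arr[None, :]
    w = loadings.matrix.to_numpy(dtype=float)
    sums = values @ w
    if normalize:
        denom = w.sum(axis=0)
        if np.any(denom == 0):
            raise ValueError("factor weight column sums to zero; cannot normalize")
        sums = sums / denom
    if isinstance(subscales, pd.DataFrame):
        return pd.DataFrame(sums, columns=FACTORS, index=subscales.index)
    return pd.Series(sums[0], index=FACTORS)


def attach_scores(
    df: pd.DataFrame, loadings: FactorLoadings | None = None, normalize: bool = True
) -> pd.DataFrame:
    """Add composite columns (msel_elc, ibq_sur/neg/reg) to a cohort table."""
    loadings = loadings if loadings is not None else FactorLoadings.placeholder()
    out = df.copy()
    if {"msel_vr", "msel_fm", "msel_rl", "msel_el"} <= set(df.columns):
        out["msel_elc"] = compute_elc(
            df["msel_vr"], df["msel_fm"], df["msel_rl"], df["msel_el"],
            gm=df.get("msel_gm"),
        )
    if set(loadings.subscale_names) <= set(df.columns):
        factors = compute_ibq_factors(df, loadings, normalize=normalize)
        for f in FACTORS:
            out[f"ibq_{f}"] = factors[f]
    return out
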