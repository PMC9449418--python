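"""Synthetic cohort generator.

Emulates the data structure of a breastfed-infant cohort in which 14
human-milk nutrient concentrations (fatty acids, phospholipids, choline
metabolites) are measured once per mother and infant cognition (MSEL
subscale T-scores) and temperament (IBQ-R subscale means) are assessed at a
baseline visit before 6 months, with follow-up assessments binned at 6-9,
9-12 and 12-18 months.

Nutrients are drawn multivariate-normal on the standardized scale with a
block correlation target, affinely mapped to the published means and SDs,
and truncated at zero (concentrations are nonnegative).  Outcomes are
linear in the standardized predictors plus Gaussian noise; the residual
scale can be set directly or derived from a target population R-squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("milkcog")

__all__ = [
    "NutrientSpec",
    "CorrelationTarget",
    "OutcomeModelSpec",
    "CohortConfig",
    "FollowupBin",
    "Cohort",
    "NUTRIENTS",
    "DEFAULT_PANEL",
    "REFERENCE_CLUSTERS",
    "DEFAULT_OUTCOME_MODELS",
    "default_panel",
    "default_correlation_target",
    "nearest_psd",
    "sample_nutrient_matrix",
    "sample_outcomes",
    "simulate_cohort",
    "write_cohort",
]

# ---------------------------------------------------------------------------
# Nutrient panel
# ---------------------------------------------------------------------------

#: Canonical column order of the 14-nutrient panel.
NUTRIENTS = [
    "TSFA", "TMUFA", "TPUFA", "n-6/n-3", "ARA", "DHA", "ARA/DHA",
    "PC", "PE", "PI", "SPH", "Choline", "PCho", "GPC",
]

#: Reference grouping of the panel into 7 correlation clusters:
#: bulk fatty acids + ARA, the n-6/n-3 ratio, DHA with the ARA/DHA ratio,
#: the four phospholipids, and the three choline metabolites apart.
REFERENCE_CLUSTERS = {
    "TSFA": 1, "TMUFA": 1, "TPUFA": 1, "ARA": 1,
    "n-6/n-3": 2,
    "DHA": 3, "ARA/DHA": 3,
    "PC": 4, "PE": 4, "PI": 4, "SPH": 4,
    "GPC": 5,
    "PCho": 6,
    "Choline": 7,
}

MSEL_SUBSCALES = ["gm", "vr", "fm", "rl", "el"]
MSEL_COLUMNS = [f"msel_{s}" for s in MSEL_SUBSCALES]
IBQ_COLUMNS = [f"ibq_{i:02d}" for i in range(1, 15)]

CONFOUNDERS = ["visit_age_months", "sex", "site", "income_lt75k"]


@dataclass(frozen=True)
class NutrientSpec:
    """Marginal distribution of one nutrient concentration.

    ``mean``/``sd`` are on the measurement scale (g/100ml, mg/100ml,
    mcmol/l, or dimensionless for the two ratios).
    """

    name: str
    mean: float
    sd: float
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0 for nutrient {self.name!r}")


# Published summary concentrations (mean, SD) for the default panel.
_PANEL_MOMENTS = {
    "TSFA": (1.54, 0.59),
    "TMUFA": (1.32, 0.53),
    "TPUFA": (0.64, 0.26),
    "n-6/n-3": (10.57, 2.27),
    "ARA": (20.07, 6.32),
    "DHA": (8.35, 5.14),
    "ARA/DHA": (3.24, 1.73),
    "PC": (4.99, 2.58),
    "PE": (7.53, 3.98),
    "PI": (3.06, 1.19),
    "SPH": (7.7, 3.61),
    "Choline": (216.49, 140.47),
    "PCho": (448.85, 235.64),
    "GPC": (568.53, 192.07),
}


def default_panel() -> list[NutrientSpec]:
    """The 14-nutrient default panel with published means/SDs."""
    return [
        NutrientSpec(name, *_PANEL_MOMENTS[name], cluster_id=REFERENCE_CLUSTERS[name])
        for name in NUTRIENTS
    ]


DEFAULT_PANEL = default_panel()


# ---------------------------------------------------------------------------
# Correlation target
# ---------------------------------------------------------------------------

class PSDRepairError(ValueError):
    """Raised when a correlation matrix is too far from positive semi-definite."""


def nearest_psd(matrix: np.ndarray, max_frobenius: float = 0.05) -> np.ndarray:
    """Repair a symmetric matrix to the nearest PSD matrix by eigenvalue clipping.

    Raises :class:`PSDRepairError` if the Frobenius distance of the repair
    exceeds ``max_frobenius``.
    """
    m = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    if vals.min() >= -1e-12:
        return m
    repaired = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    # restore unit diagonal after clipping
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    dist = float(np.linalg.norm(repaired - m, "fro"))
    if dist > max_frobenius:
        raise PSDRepairError(
            f"matrix is not PSD and nearest repair is {dist:.4f} Frobenius away "
            f"(limit {max_frobenius})"
        )
    logger.info("correlation target repaired to PSD (Frobenius distance %.2e)", dist)
    return repaired


@dataclass
class CorrelationTarget:
    """A labelled pairwise Pearson-correlation matrix."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        p = len(self.labels)
        if m.shape != (p, p):
            raise ValueError(f"matrix shape {m.shape} does not match {p} labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = nearest_psd(m)

    def submatrix(self, labels: list[str]) -> np.ndarray:
        idx = [self.labels.index(l) for l in labels]
        return self.matrix[np.ix_(idx, idx)]


def block_correlation_target(
    labels: list[str],
    clusters: dict[str, int],
    within: float = 0.8,
    between: float = 0.1,
    extra: dict[tuple[str, str], float] | None = None,
) -> CorrelationTarget:
    """Block correlation matrix: ``within`` inside a cluster, ``between`` across,
    with optional named pair overrides."""
    p = len(labels)
    m = np.full((p, p), between)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if clusters.get(a) == clusters.get(b):
                m[i, j] = within
    for (a, b), r in (extra or {}).items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = r
    np.fill_diagonal(m, 1.0)
    return CorrelationTarget(labels=list(labels), matrix=m)


def default_correlation_target() -> CorrelationTarget:
    """Default block target for the 14-nutrient panel.

    Within-cluster correlation 0.8, between-cluster 0.1, plus the two
    documented cross-cluster links: phosphocholine with free choline (0.50)
    and TSFA with PC (0.28), the strongest bridges between the choline and
    fatty-acid/phospholipid blocks respectively.
    """
    return block_correlation_target(
        NUTRIENTS,
        REFERENCE_CLUSTERS,
        within=0.8,
        between=0.1,
        extra={("PCho", "Choline"): 0.50, ("TSFA", "PC"): 0.28},
    )


# ---------------------------------------------------------------------------
# Nutrient sampling
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_nutrient_matrix(
    n: int,
    specs: list[NutrientSpec] | None = None,
    target: CorrelationTarget | None = None,
    seed=None,
    clip_at_zero: bool = True,
    max_truncation: float = 0.10,
) -> pd.DataFrame:
    """Draw ``n`` nutrient vectors matching the marginal specs and correlation target.

    Sampling is multivariate normal on the standardized scale, affinely
    mapped to each spec's (mean, sd), then truncated at zero because
    concentrations are nonnegative.  The per-nutrient fraction of truncated
    values is logged and stored in ``result.attrs["truncation_fraction"]``;
    fractions above ``max_truncation`` raise.  Nutrients whose mean is less
    than about two SDs above zero (DHA, free choline) clip a few percent of
    draws, which slightly raises their realized means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = list(specs) if specs is not None else default_panel()
    target = target if target is not None else default_correlation_target()
    names = [s.name for s in specs]
    if set(names) != set(target.labels) or len(names) != len(target.labels):
        raise ValueError("correlation target labels do not match nutrient specs")
    rng = _as_rng(seed)
    corr = target.submatrix(names)
    vals, vecs = np.linalg.eigh(corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, len(names))) @ factor.T
    means = np.array([s.mean for s in specs])
    sds = np.array([s.sd for s in specs])
    x = means + sds * z
    trunc = {}
    if clip_at_zero:
        # guard on the analytic clip probability so small samples cannot
        # trip it by chance; log the realized fractions
        from scipy.stats import norm

        for s in specs:
            expected = float(norm.cdf(-s.mean / s.sd))
            if expected > max_truncation:
                raise ValueError(
                    f"truncation fraction {expected:.3f} for {s.name!r} "
                    f"exceeds {max_truncation}"
                )
        frac = (x < 0).mean(axis=0)
        trunc = dict(zip(names, frac.tolist()))
        for name, f in trunc.items():
            if f > 0:
                logger.debug("truncated %.2f%% of %s draws at zero", 100 * f, name)
        x = np.clip(x, 0.0, None)
    df = pd.DataFrame(x, columns=names)
    df.attrs["truncation_fraction"] = trunc
    return df


# ---------------------------------------------------------------------------
# Outcome models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModelSpec:
    """Linear generating model for one outcome on the standardized scale.

    ``coefficients`` maps predictor column names (nutrients and/or
    confounders) to standardized effects.  If ``target_r2`` is given the
    residual SD is derived so that the population R-squared of the
    generating model (all coefficient terms jointly) equals it; otherwise
    ``noise_sd`` is used as given.
    """

    outcome_name: str
    coefficients: dict[str, float]
    noise_sd: float = 1.0
    target_r2: float | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_r2 is not None and not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0, 1)")


# Standardized generating coefficients for the five modelled outcomes
# (selected nutrients plus the four confounders), with the reported
# full-model R-squared used to set the residual scale.
DEFAULT_OUTCOME_MODELS: dict[str, OutcomeModelSpec] = {
    "msel_elc": OutcomeModelSpec(
        "msel_elc",
        {"TSFA": -0.42, "n-6/n-3": 0.26, "DHA": 0.55, "SPH": -0.22,
         "visit_age_months": -0.006, "sex": 0.03, "site": 0.20, "income_lt75k": -0.13},
        target_r2=0.31,
    ),
    "msel_gm": OutcomeModelSpec(
        "msel_gm",
        {"TMUFA": -0.51, "n-6/n-3": 0.19, "DHA": 0.30, "SPH": -0.24,
         "visit_age_months": 0.28, "sex": 0.08, "site": 0.44, "income_lt75k": 0.14},
        target_r2=0.42,
    ),
    "msel_rl": OutcomeModelSpec(
        "msel_rl",
        {"TSFA": -0.30, "n-6/n-3": 0.37, "DHA": 0.75, "PE": 0.30,
         "visit_age_months": 0.30, "sex": -0.01, "site": 0.10, "income_lt75k": -0.15},
        target_r2=0.36,
    ),
    "ibq_sur": OutcomeModelSpec(
        "ibq_sur",
        {"ARA": 0.42, "PI": 0.19, "PCho": 0.27,
         "visit_age_months": 0.18, "sex": -0.03, "site": -0.32, "income_lt75k": -0.15},
        target_r2=0.43,
    ),
    "ibq_reg": OutcomeModelSpec(
        "ibq_reg",
        {"ARA": 0.39,
         "visit_age_months": 0.18, "sex": -0.004, "site": 0.22, "income_lt75k": 0.06},
        target_r2=0.23,
    ),
}


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def sample_outcomes(
    nutrients: pd.DataFrame,
    confounders: pd.DataFrame | None,
    model: OutcomeModelSpec,
    seed=None,
) -> np.ndarray:
    """Generate one outcome column: intercept + sum of standardized-predictor
    effects + Gaussian noise.

    With ``target_r2`` set, the noise SD is scaled to the realized variance
    of the linear predictor so that the generating model's R-squared equals
    the target (exactly in population, conditional on the sampled design).
    """
    rng = _as_rng(seed)
    cols = {}
    for frame in (nutrients, confounders):
        if frame is not None:
            for c in frame.columns:
                cols[c] = np.asarray(frame[c], dtype=float)
    n = len(nutrients)
    eta = np.zeros(n)
    for key, beta in model.coefficients.items():
        if key not in cols:
            raise KeyError(f"unknown coefficient key {key!r}")
        if beta == 0.0:
            continue
        v = cols[key]
        if v.std(ddof=1) == 0:
            # a constant predictor (e.g. one-sex follow-up bin) carries no signal
            logger.debug("skipping constant predictor %r in %s", key, model.outcome_name)
            continue
        eta = eta + beta * _zscore(v)
    sig_var = float(eta.var())  # population convention: variance of the signal
    if model.target_r2 is not None and sig_var > 0:
        noise_sd = np.sqrt(sig_var * (1 - model.target_r2) / model.target_r2)
    else:
        noise_sd = model.noise_sd if sig_var > 0 or model.target_r2 is None else 0.0
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    return model.intercept + eta + noise


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollowupBin:
    """One follow-up age window (lo, hi] for one instrument."""

    instrument: str  # "msel" | "ibq"
    lo: float
    hi: float
    n: int
    age_mean: float
    age_sd: float

    @property
    def label(self) -> str:
        return f"{self.lo:g}-{self.hi:g}m"


@dataclass
class CohortConfig:
    """Study-condition defaults: 54 subjects, 38 with MSEL, 42 with IBQ-R
    (26 with both), two missing household incomes, baseline age 4.43 +/- 0.83
    months, and follow-up visits in the three age bins."""

    n_subjects: int = 54
    n_msel: int = 38
    n_ibq: int = 42
    n_both: int = 26
    n_male: int = 19
    n_missing_income: int = 2
    p_income_lt75k: float = 18 / 52
    p_site: float = 0.5
    age_mean: float = 4.43
    age_sd: float = 0.83
    age_range: tuple[float, float] = (1.0, 5.9)
    msel_loc: float = 50.0
    msel_scale: float = 10.0
    ibq_loc: float = 4.2
    ibq_scale: float = 0.8
    ibq_subscale_jitter: float = 0.2
    followup_bins: tuple[FollowupBin, ...] = (
        FollowupBin("msel", 6, 9, 27, 7.63, 0.87),
        FollowupBin("msel", 9, 12, 34, 10.5, 0.97),
        FollowupBin("msel", 12, 18, 25, 14.02, 1.08),
        FollowupBin("ibq", 6, 9, 7, 8.02, 0.40),
        FollowupBin("ibq", 9, 12, 7, 11.2, 0.62),
        FollowupBin("ibq", 12, 18, 27, 13.34, 0.79),
    )
    followup_signal_decay: float = 1.0
    panel: list[NutrientSpec] = field(default_factory=default_panel)
    correlation_target: CorrelationTarget = field(default_factory=default_correlation_target)
    outcome_models: dict[str, OutcomeModelSpec] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MODELS)
    )
    null_noise_sd: float = 1.0  # residual SD for outcomes with no generating model
    seed: int = 0

    def validate(self) -> None:
        if self.n_msel + self.n_ibq - self.n_both != self.n_subjects:
            raise ValueError(
                "instrument availability counts inconsistent: "
                f"{self.n_msel} + {self.n_ibq} - {self.n_both} != {self.n_subjects}"
            )
        if self.n_both > min(self.n_msel, self.n_ibq):
            raise ValueError("n_both exceeds an instrument count")
        if self.n_missing_income > self.n_subjects:
            raise ValueError("more missing incomes than subjects")
        if self.n_male > self.n_subjects:
            raise ValueError("more males than subjects")
        for b in self.followup_bins:
            cap = self.n_msel if b.instrument == "msel" else self.n_ibq
            if b.n > cap:
                raise ValueError(f"follow-up bin {b.label} larger than {b.instrument} cohort")


@dataclass
class Cohort:
    """A simulated cohort: one baseline row per subject plus follow-up rows."""

    baseline: pd.DataFrame
    followup: pd.DataFrame
    config: CohortConfig


# IBQ-R placeholder structure: subscales 1-6 load on surgency, 7-10 on
# negative affectivity, 11-14 on orienting/regulation (synthetic grouping;
# real factor loadings are supplied by the user at analysis time).
IBQ_FACTOR_GROUPS = {
    "sur": IBQ_COLUMNS[0:6],
    "neg": IBQ_COLUMNS[6:10],
    "reg": IBQ_COLUMNS[10:14],
}


def _decayed(y: np.ndarray, decay: float, rng: np.random.Generator) -> np.ndarray:
    """Attenuate the association between a score and its predictors while
    keeping the marginal variance: shrink toward noise with weight ``decay``."""
    if decay >= 1.0:
        return y
    sd = y.std()
    return decay * y + np.sqrt(max(1.0 - decay**2, 0.0)) * rng.normal(0.0, sd, len(y))


def _exact_binary(n: int, n_ones: int, rng: np.random.Generator) -> np.ndarray:
    v = np.zeros(n)
    v[rng.choice(n, size=n_ones, replace=False)] = 1.0
    return v


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Simulate a full cohort with baseline and follow-up visits.

    Availability patterns (MSEL-only / IBQ-only / both) and the male count
    are assigned by exact stratified draws matching the configured counts;
    missing incomes are injected completely at random.  Reproducible given
    the seed.
    """
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    subject_id = [f"S{i + 1:03d}" for i in range(n)]
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    )
    sex = _exact_binary(n, config.n_male, rng)
    site = (rng.random(n) < config.p_site).astype(float)
    income_true = (rng.random(n) < config.p_income_lt75k).astype(float)

    nutrients = sample_nutrient_matrix(
        n, config.panel, config.correlation_target, seed=rng
    )
    confounders = pd.DataFrame(
        {"visit_age_months": age, "sex": sex, "site": site, "income_lt75k": income_true}
    )

    # instrument availability: exact counts, stratified draw
    order = rng.permutation(n)
    both_idx = order[: config.n_both]
    msel_only = order[config.n_both : config.n_both + (config.n_msel - config.n_both)]
    ibq_only = order[config.n_both + (config.n_msel - config.n_both) :]
    has_msel = np.zeros(n, bool)
    has_msel[both_idx] = has_msel[msel_only] = True
    has_ibq = np.zeros(n, bool)
    has_ibq[both_idx] = has_ibq[ibq_only] = True

    models = config.outcome_models

    def _standard_outcome(key: str) -> np.ndarray:
        """Outcome on the standardized scale from its generating model,
        or confounder-free noise when no model is configured."""
        if key in models:
            return sample_outcomes(nutrients, confounders, models[key], seed=rng)
        return rng.normal(0.0, config.null_noise_sd, n)

    baseline = pd.DataFrame({"subject_id": subject_id})
    baseline["visit_age_months"] = age
    baseline["sex"] = sex
    baseline["site"] = site
    baseline["income_lt75k"] = income_true
    for c in nutrients.columns:
        baseline[c] = nutrients[c].to_numpy()

    msel_std = {s: _standard_outcome(f"msel_{s}") for s in MSEL_SUBSCALES}
    for s in MSEL_SUBSCALES:
        col = config.msel_loc + config.msel_scale * msel_std[s]
        baseline[f"msel_{s}"] = np.where(has_msel, col, np.nan)

    factor_std = {f: _standard_outcome(f"ibq_{f}") for f in IBQ_FACTOR_GROUPS}
    for fac, subs in IBQ_FACTOR_GROUPS.items():
        fval = config.ibq_loc + config.ibq_scale * factor_std[fac]
        for sc in subs:
            col = fval + rng.normal(0.0, config.ibq_subscale_jitter, n)
            baseline[sc] = np.where(has_ibq, col, np.nan)

    # missing income, completely at random
    if config.n_missing_income:
        miss = rng.choice(n, size=config.n_missing_income, replace=False)
        baseline.loc[miss, "income_lt75k"] = np.nan

    # follow-up visits: subjects drawn from the instrument's baseline set;
    # observed scores come from the same frozen generating model with fresh
    # noise, optionally attenuated by followup_signal_decay.
    rows = []
    for b in config.followup_bins:
        pool = np.flatnonzero(has_msel if b.instrument == "msel" else has_ibq)
        chosen = rng.choice(pool, size=b.n, replace=False)
        f_age = np.clip(rng.normal(b.age_mean, b.age_sd, b.n), b.lo + 1e-6, b.hi)
        sub_nut = nutrients.iloc[chosen].reset_index(drop=True)
        sub_conf = confounders.iloc[chosen].reset_index(drop=True)
        rec = pd.DataFrame(
            {
                "subject_id": [subject_id[i] for i in chosen],
                "visit_age_months": f_age,
                "instrument": b.instrument,
                "age_bin": b.label,
            }
        )
        if b.instrument == "msel":
            for s in MSEL_SUBSCALES:
                key = f"msel_{s}"
                if key in models:
                    y = _decayed(
                        sample_outcomes(sub_nut, sub_conf, models[key], seed=rng),
                        config.followup_signal_decay, rng,
                    )
                else:
                    y = rng.normal(0.0, config.null_noise_sd, b.n)
                rec[key] = config.msel_loc + config.msel_scale * y
        else:
            for fac, subs in IBQ_FACTOR_GROUPS.items():
                key = f"ibq_{fac}"
                if key in models:
                    y = _decayed(
                        sample_outcomes(sub_nut, sub_conf, models[key], seed=rng),
                        config.followup_signal_decay, rng,
                    )
                else:
                    y = rng.normal(0.0, config.null_noise_sd, b.n)
                fval = config.ibq_loc + config.ibq_scale * y
                for sc in subs:
                    rec[sc] = fval + rng.normal(0.0, config.ibq_subscale_jitter, b.n)
        rows.append(rec)
    followup = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    return Cohort(baseline=baseline, followup=followup, config=config)


def write_cohort(cohort: Cohort, baseline_path, followup_path=None, config_path=None) -> None:
    """Write the cohort CSVs plus a plain-text key-value sidecar recording
    the generation parameters and seed."""
    cohort.baseline.to_csv(baseline_path, index=False)
    if followup_path is not None:
        cohort.followup.to_csv(followup_path, index=False)
    if config_path is not None:
        cfg = cohort.config
        lines = [
            f"seed = {cfg.seed}",
            f"n_subjects = {cfg.n_subjects}",
            f"n_msel = {cfg.n_msel}",
            f"n_ibq = {cfg.n_ibq}",
            f"n_both = {cfg.n_both}",
            f"n_male = {cfg.n_male}",
            f"n_missing_income = {cfg.n_missing_income}",
            f"age_mean = {cfg.age_mean}",
            f"age_sd = {cfg.age_sd}",
            f"followup_signal_decay = {cfg.followup_signal_decay}",
        ]
        for b in cfg.followup_bins:
            lines.append(
                f"followup_bin = {b.instrument} ({b.lo},{b.hi}] n={b.n} "
                f"age={b.age_mean}({b.age_sd})"
            )
        for name, model in cfg.outcome_models.items():
            coefs = ", ".join(f"{k}={v}" for k, v in model.coefficients.items())
            r2 = f" target_r2={model.target_r2}" if model.target_r2 is not None else ""
            lines.append(f"outcome_model = {name}: {coefs}{r2}")
        with open(config_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
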