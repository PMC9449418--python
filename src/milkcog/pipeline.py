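"""End-to-end orchestration: simulate or ingest a cohort, score composites,
preprocess, run the marginal scan, cluster the nutrients, select joint
models, cross-validate them and evaluate follow-up prediction, writing
every stage table as CSV plus a run log.

Every numeric output is reproduced bit-identically under a fixed seed; the
seed is recorded in the run log and the simulation sidecar.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CONFOUNDERS,
    NUTRIENTS,
    Cohort,
    CohortConfig,
    simulate_cohort,
    write_cohort,
)
from .clustering import (
    minimum_spanning_tree,
    optimal_partition,
    pairwise_correlations,
    partition_table,
)
from .marginal import marginal_scan, scan_pivot
from .preprocess import (
    IBQ_OUTCOMES,
    MSEL_OUTCOMES,
    build_analysis_frame,
    cohort_characteristics,
    compare_cohort_subsets,
    nutrient_age_trends,
)
from .scoring import FactorLoadings, attach_scores
from .selection import select_models, selection_table
from .validation import DEFAULT_BINS, followup_predict, repeated_cv

logger = logging.getLogger("milkcog")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    With ``input_baseline`` unset, a synthetic cohort is simulated from
    ``cohort``; otherwise baseline (and optionally follow-up) CSVs are
    read.  Paper-ambiguous choices are explicit keys: the FDR family
    policy, the clustering distance variant, and which age covariate feeds
    follow-up prediction.
    """

    seed: int = 0
    output_dir: str = "milkcog_output"
    input_baseline: str | None = None
    input_followup: str | None = None
    loadings_csv: str | None = None
    instruments: tuple[str, ...] = ("msel", "ibq")
    msel_outcomes: tuple[str, ...] = tuple(MSEL_OUTCOMES)
    ibq_outcomes: tuple[str, ...] = tuple(IBQ_OUTCOMES)
    fdr_family: str = "per_instrument"
    fdr_family_size: int | None = None
    cluster_distance_absolute: bool = False
    cv_folds: int = 5
    cv_reps: int = 100
    followup_bins: tuple[tuple[float, float], ...] = DEFAULT_BINS
    followup_use_followup_age: bool = False
    cv_outcomes: tuple[str, ...] = ()  # empty: every outcome with q >= 1
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cohort_raw:
            ckn = {f.name for f in fields(CohortConfig)}
            bad = set(cohort_raw) - ckn
            if bad:
                raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
            cfg.cohort = replace(CohortConfig(), **cohort_raw)
        for tup in ("instruments", "msel_outcomes", "ibq_outcomes", "cv_outcomes"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        cfg.followup_bins = tuple(tuple(b) for b in cfg.followup_bins)
        return cfg


@dataclass
class PipelineResult:
    """Handles to every stage output of one run."""

    cohort: Cohort
    characteristics: pd.DataFrame
    age_trends: pd.DataFrame
    subset_comparison: pd.DataFrame
    scans: dict[str, pd.DataFrame]
    correlations: object
    partition_scan: object
    mst: object
    fits: dict[str, list]
    cv: dict[str, object]
    followup: dict[str, list]
    output_dir: Path


def _validate_cohort_columns(df: pd.DataFrame) -> None:
    required = ["subject_id"] + CONFOUNDERS + NUTRIENTS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order, writing stage CSVs to the output
    directory.  Any stage failure propagates with the stage name attached."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"milkcog {__version__}",
        f"python {sys.version.split()[0]}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed = {config.seed}",
    ]

    stage = "ingest"
    try:
        if config.input_baseline is None:
            stage = "simulate"
            cohort = simulate_cohort(config.cohort, seed=config.seed)
        else:
            baseline = pd.read_csv(config.input_baseline)
            follow = (
                pd.read_csv(config.input_followup)
                if config.input_followup
                else pd.DataFrame()
            )
            cohort = Cohort(baseline=baseline, followup=follow, config=config.cohort)
        _validate_cohort_columns(cohort.baseline)
        write_cohort(
            cohort,
            out / "cohort_baseline.csv",
            out / "cohort_followup.csv",
            out / "cohort_config.txt",
        )

        stage = "scoring"
        loadings = (
            FactorLoadings.from_csv(config.loadings_csv)
            if config.loadings_csv
            else FactorLoadings.placeholder()
        )
        followup_scored = (
            attach_scores(cohort.followup, loadings)
            if len(cohort.followup)
            else cohort.followup
        )

        stage = "preprocess"
        characteristics = cohort_characteristics(cohort.baseline, cohort.followup)
        characteristics.to_csv(out / "characteristics.csv")
        trends = nutrient_age_trends(cohort.baseline)
        trends.to_csv(out / "age_trends.csv")
        frames = {}
        for instrument in config.instruments:
            frames[instrument] = build_analysis_frame(
                cohort.baseline, instrument, loadings
            )
        if {"msel", "ibq"} <= set(frames):
            comparison = compare_cohort_subsets(
                cohort.baseline,
                frames["msel"].df["subject_id"],
                frames["ibq"].df["subject_id"],
            )
        else:
            comparison = pd.DataFrame()
        comparison.to_csv(out / "subset_comparison.csv")

        stage = "marginal"
        scans = {}
        for instrument, frame in frames.items():
            outcomes = (
                config.msel_outcomes if instrument == "msel" else config.ibq_outcomes
            )
            scan = marginal_scan(
                frame,
                outcomes=[o for o in outcomes if o in frame.df.columns],
                family=config.fdr_family,
                family_size=config.fdr_family_size,
            )
            scans[instrument] = scan
            scan.to_csv(out / f"marginal_{instrument}.csv", index=False)
            scan_pivot(scan).to_csv(out / f"marginal_{instrument}_wide.csv")

        stage = "clustering"
        # correlations on the pooled baseline concentrations (scale-invariant)
        corr = pairwise_correlations(cohort.baseline, NUTRIENTS)
        corr.frame().to_csv(out / "correlations.csv")
        scan_part = optimal_partition(corr, absolute=config.cluster_distance_absolute)
        partition_table(scan_part).to_csv(out / "partitions.csv")
        mst = minimum_spanning_tree(corr, absolute=config.cluster_distance_absolute)
        pd.DataFrame(mst.edges, columns=["source", "target", "r"]).to_csv(
            out / "mst_edges.csv", index=False
        )
        solution = scan_part.selected

        stage = "selection"
        fits = {}
        for instrument, frame in frames.items():
            outcomes = (
                config.msel_outcomes if instrument == "msel" else config.ibq_outcomes
            )
            instrument_fits = select_models(
                frame, solution, [o for o in outcomes if o in frame.df.columns]
            )
            fits[instrument] = instrument_fits
            selection_table(instrument_fits, frame.nutrient_cols).to_csv(
                out / f"selection_{instrument}.csv"
            )

        stage = "cross-validation"
        rng = np.random.default_rng(config.seed)
        cv = {}
        cv_rows = []
        rep_rows = []
        for instrument, instrument_fits in fits.items():
            frame = frames[instrument]
            for fit in instrument_fits:
                if config.cv_outcomes and fit.outcome not in config.cv_outcomes:
                    continue
                if fit.candidate.q == 0:
                    continue
                res = repeated_cv(
                    frame,
                    fit.outcome,
                    fit.candidate.selected,
                    folds=config.cv_folds,
                    reps=config.cv_reps,
                    seed=rng,
                )
                cv[fit.outcome] = res
                cv_rows.append(
                    {
                        "outcome": fit.outcome,
                        "mean_correlation": res.mean_correlation,
                        "ci_low": res.interval[0],
                        "ci_high": res.interval[1],
                        "fraction_significant": res.fraction_significant,
                        "r_star": res.r_star,
                        "mean_mse": float(res.mse.mean()),
                        "n": res.n,
                        "note": res.note,
                    }
                )
                for i, (r, m) in enumerate(zip(res.correlations, res.mse)):
                    rep_rows.append(
                        {"outcome": fit.outcome, "repetition": i, "correlation": r,
                         "cv_mse": m}
                    )
        pd.DataFrame(cv_rows).to_csv(out / "cv_summary.csv", index=False)
        pd.DataFrame(rep_rows).to_csv(out / "cv_repetitions.csv", index=False)

        stage = "follow-up"
        followup_results = {}
        fu_rows = []
        if len(followup_scored):
            for instrument, instrument_fits in fits.items():
                frame = frames[instrument]
                sub = followup_scored[followup_scored["instrument"] == instrument]
                if sub.empty:
                    continue
                for fit in instrument_fits:
                    if fit.candidate.q == 0 or fit.outcome not in sub.columns:
                        continue
                    preds = followup_predict(
                        fit,
                        frame,
                        sub,
                        bins=config.followup_bins,
                        use_followup_age=config.followup_use_followup_age,
                    )
                    followup_results[fit.outcome] = preds
                    for p in preds:
                        fu_rows.append(
                            {
                                "outcome": p.outcome,
                                "age_bin": f"({p.age_bin[0]:g}, {p.age_bin[1]:g}]",
                                "pearson_r": p.pearson_r,
                                "p_value": p.p_value,
                                "n": p.n,
                            }
                        )
        pd.DataFrame(fu_rows).to_csv(out / "followup_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_lines.append("stages completed: simulate/ingest, scoring, preprocess, "
                     "marginal, clustering, selection, cross-validation, follow-up")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        cohort=cohort,
        characteristics=characteristics,
        age_trends=trends,
        subset_comparison=comparison,
        scans=scans,
        correlations=corr,
        partition_scan=scan_part,
        mst=mst,
        fits=fits,
        cv=cv,
        followup=followup_results,
        output_dir=out,
    )
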