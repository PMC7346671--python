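"""End-to-end pipeline: simulate -> preprocess -> trajectories -> cluster ->
associate, with a single config, one root seed, and a structured run report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import (
    fit_pf_model,
    lrt_effect_modification,
    mvpa_split,
    stratified_estimates,
)
from .clustering import (
    concordance,
    hier_cluster,
    profiles_from_assignments,
    select_k_phase1,
)
from .containers import ClassifiedDay
from .preprocessing import (
    aggregate_minutes,
    choi_nonwear,
    classify_epochs,
    filter_cohort,
    resolve_bed_times,
)
from .synthetic import GeneratorConfig, default_config, generate_cohort
from .trajectories import (
    DayDropped,
    copy_mean_impute,
    extract_trajectory,
    extract_trajectory_clock,
    hourly_sb,
    trajectory_matrix,
)

logger = logging.getLogger("sbpatterns")

__all__ = ["PipelineConfig", "RunReport", "run", "preprocess_cohort", "cluster_variant"]


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=default_config)
    alignments: tuple[str, ...] = ("wake_aligned",)  # may add "clock_aligned"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    K_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    n_restarts: int = 5
    seed: int = 0
    adjust_sedentary: bool = True
    clock_start_hour: int = 8
    output_dir: str | None = None

    def validate(self) -> None:
        self.generator.seed = self.seed
        self.generator.validate()
        if not self.k_range or not self.K_range:
            raise ValueError("k_range and K_range must be non-empty")
        for a in self.alignments:
            if a not in ("wake_aligned", "clock_aligned"):
                raise ValueError(f"unknown alignment variant: {a}")
        if not self.alignments:
            raise ValueError("at least one alignment variant is required")


@dataclass
class RunReport:
    """Everything a run computed, in plain data structures."""

    attrition: dict
    chosen_k: int
    phase1_diagnostics: pd.DataFrame
    centroids: np.ndarray
    day_cluster_labels: dict[int, str]
    chosen_K: int
    silhouette_by_K: dict[int, float]
    proportion_summaries: pd.DataFrame  # per pattern x day-cluster quartiles
    pattern_sizes: dict[int, int]
    stratified: object  # StratifiedEstimates
    lrt: tuple[float, int, float]
    mvpa_split_value: float
    concordance_day_pct: float | None = None
    concordance_participant_pct: float | None = None

    def to_dict(self) -> dict:
        payload = {
            "attrition": self.attrition,
            "phase1": {
                "chosen_k": self.chosen_k,
                "diagnostics": self.phase1_diagnostics.to_dict(orient="records"),
                "centroids": self.centroids.tolist(),
                "labels": {str(k): v for k, v in self.day_cluster_labels.items()},
            },
            "phase2": {
                "chosen_K": self.chosen_K,
                "silhouette_by_K": {str(k): v for k, v in self.silhouette_by_K.items()},
                "pattern_sizes": {str(k): v for k, v in self.pattern_sizes.items()},
                "proportion_summaries": self.proportion_summaries.to_dict(orient="records"),
            },
            "association": {
                "mvpa_split_value": self.mvpa_split_value,
                "lrt": {"statistic": self.lrt[0], "df": self.lrt[1], "p": self.lrt[2]},
                "cells": self.stratified.cells.to_dict(orient="records"),
                "pattern_contrasts": self.stratified.pattern_contrasts.to_dict(
                    orient="records"
                ),
                "mvpa_contrasts": self.stratified.mvpa_contrasts.to_dict(orient="records"),
            },
        }
        if self.concordance_day_pct is not None:
            payload["concordance"] = {
                "day_pct": self.concordance_day_pct,
                "participant_pct": self.concordance_participant_pct,
            }
        return payload


def preprocess_cohort(series, sleep_logs):
    """Classify every participant-day: wear detection, bed times, cutpoints."""
    bed_times = resolve_bed_times(sleep_logs)
    days: list[ClassifiedDay] = []
    for s in series:
        minutes = aggregate_minutes(s)
        wear = ~choi_nonwear(minutes)
        days.extend(classify_epochs(s, wear, bed_times))
    return days


def _extract_days(days, alignment: str, clock_start_hour: int):
    trajectories = []
    dropped = 0
    for day in days:
        sb, cov = hourly_sb(day)
        try:
            if alignment == "wake_aligned":
                trajectories.append(extract_trajectory(day, sb, cov))
            else:
                trajectories.append(
                    extract_trajectory_clock(day, sb, cov, fixed_start_hour=clock_start_hour)
                )
        except DayDropped as exc:
            logger.info("dropped day: %s", exc)
            dropped += 1
    return trajectories, dropped


def cluster_variant(days, alignment, config: PipelineConfig):
    """Trajectories -> imputation -> Phase I -> profiles -> Phase II for one variant."""
    raw, dropped = _extract_days(days, alignment, config.clock_start_hour)
    completed, _mean_curve = copy_mean_impute(raw, seed=config.seed)
    X, index = trajectory_matrix(completed)
    chosen_k, diag, models = select_k_phase1(
        X, k_range=config.k_range, n_restarts=config.n_restarts, seed=config.seed
    )
    model = models[chosen_k]
    # Drop participants who fell below 4 trajectory days (extraction drops).
    counts = index.groupby("participant_id").size()
    keep = counts[counts >= 4].index
    keep_mask = index["participant_id"].isin(keep).to_numpy()
    pruned = dataclasses.replace(
        model, assignments=model.assignments[keep_mask], sse=model.sse
    )
    profiles = profiles_from_assignments(pruned, index.loc[keep_mask, "participant_id"].to_numpy())
    assignment = hier_cluster(profiles, K_range=config.K_range)
    return model, index, assignment, profiles, diag, dropped


def _proportion_summaries(profiles: pd.DataFrame, patterns: pd.Series) -> pd.DataFrame:
    prop_cols = [c for c in profiles.columns if c.startswith("prop_")]
    merged = profiles.copy()
    merged["pattern"] = merged["participant_id"].map(patterns)
    rows = []
    for pat, grp in merged.groupby("pattern"):
        for c in prop_cols:
            q25, q50, q75 = np.percentile(grp[c], [25, 50, 75])
            rows.append(
                {
                    "pattern": int(pat),
                    "day_cluster": c.removeprefix("prop_"),
                    "median": q50,
                    "q25": q25,
                    "q75": q75,
                }
            )
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> RunReport:
    """Execute all stages; identical config + seed gives identical reports."""
    config.validate()
    series, sleep_logs, covariates, pf_panel, truth = generate_cohort(config.generator)
    days = preprocess_cohort(series, sleep_logs)
    summary = filter_cohort(days)
    attrition = {
        "days_recorded": summary.n_days_input,
        "participants_recorded": summary.n_participants_input,
        "adherent_days": len(summary.days),
        "participants_retained": len(summary.participants),
    }

    primary = config.alignments[0]
    model, index, assignment, profiles, diag, dropped = cluster_variant(
        summary.days, primary, config
    )
    attrition["trajectory_days"] = int(index.shape[0])
    attrition["days_dropped_no_start_hour"] = dropped

    # Association stage on measured covariates.
    measured = covariates.drop(columns=["total_sedentary_min", "mvpa_min"], errors="ignore")
    measured = measured.merge(
        summary.participant_means[["participant_id", "total_sedentary_min", "mvpa_min"]],
        on="participant_id",
        how="inner",
    )
    patterns = assignment.patterns
    mvpa_high, split_value = mvpa_split(measured[measured["participant_id"].isin(patterns.index)])
    full_ml = fit_pf_model(
        pf_panel, patterns, measured,
        include_sedentary=config.adjust_sedentary,
        include_mvpa_interaction=True, mvpa_high=mvpa_high, reml=False,
    )
    reduced_ml = fit_pf_model(
        pf_panel, patterns, measured,
        include_sedentary=config.adjust_sedentary,
        include_mvpa_interaction=False, reml=False,
    )
    # The reduced ML fit drops rows only by covariate completeness, as does
    # the full fit plus the MVPA column (always complete here).
    lrt = lrt_effect_modification(full_ml, reduced_ml)
    full_reml = fit_pf_model(
        pf_panel, patterns, measured,
        include_sedentary=config.adjust_sedentary,
        include_mvpa_interaction=True, mvpa_high=mvpa_high, reml=True,
    )
    strat = stratified_estimates(full_reml, mvpa_split_value=split_value)

    report = RunReport(
        attrition=attrition,
        chosen_k=model.k,
        phase1_diagnostics=diag,
        centroids=model.centroids,
        day_cluster_labels=model.labels,
        chosen_K=assignment.K,
        silhouette_by_K=assignment.silhouette_by_K,
        proportion_summaries=_proportion_summaries(profiles, patterns),
        pattern_sizes={int(k): int(v) for k, v in patterns.value_counts().sort_index().items()},
        stratified=strat,
        lrt=lrt,
        mvpa_split_value=split_value,
    )

    if len(config.alignments) > 1:
        secondary = [a for a in config.alignments if a != primary][0]
        model_b, index_b, assignment_b, *_ = cluster_variant(summary.days, secondary, config)
        key_a = pd.MultiIndex.from_frame(index[["participant_id", "date"]])
        key_b = pd.MultiIndex.from_frame(index_b[["participant_id", "date"]])
        assign_a = pd.Series(model.assignments, index=key_a)
        assign_b = pd.Series(model_b.assignments, index=key_b)
        common = key_a.intersection(key_b)
        if len(common) == 0:
            raise ValueError("alignment variants share no days")
        common_pids = assignment.patterns.index.intersection(assignment_b.patterns.index)
        day_pct, part_pct = concordance(
            assign_a.loc[common],
            assign_b.loc[common],
            assignment.patterns.loc[common_pids],
            assignment_b.patterns.loc[common_pids],
        )
        report.concordance_day_pct = day_pct
        report.concordance_participant_pct = part_pct

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_json(report.to_dict(), out / "report.json")
        strat.cells.to_csv(out / "stratified_estimates.csv", index=False)
        profiles.to_csv(out / "participant_profiles.csv", index=False)
    return report
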