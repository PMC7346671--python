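"""Synthetic cohort generator with known ground truth.

Emulates a hip-worn accelerometer study of older women: ~7 calendar days of
15-s vector-magnitude counts per participant, daily sleep logs (with
missingness), a baseline covariate table, and an annual physical-functioning
(PF, 0-100) panel. Days are drawn from four latent diurnal sedentary-behavior
archetypes; participants mix archetypes according to a latent pattern; PF
trajectories follow a random-intercept linear model whose baseline and slope
differ by pattern x MVPA stratum. The returned :class:`SyntheticTruth` carries
every latent label so recovery of the structure can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_MINUTE,
    MINUTES_PER_DAY,
    ClassCode,
    EpochSeries,
    format_clock,
)

__all__ = [
    "PFModelTruth",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_config",
    "generate_cohort",
    "generate_covariates",
    "generate_pf_panel",
    "pf_linear_predictor",
]

# Count bands (vector-magnitude counts per 15-s epoch).
SEDENTARY_MAX_COUNT = 18
MVPA_MIN_COUNT = 520
COUNT_CEILING = 5000

ARCHETYPE_LABELS = ("A", "B", "C", "D")

# Hourly sedentary minutes over the 14 waking hours, hour 0 = first full
# clock hour after waking. Qualitative shapes: A high and gently rising,
# B low start rising steeply, C high start with a ~6-h decline then rising,
# D low and flat. Integer-valued so the zero-noise limit is exact.
# Daily totals are ordered A > B > C > D so that the letters assigned by the
# day-cluster model (descending centroid volume) coincide with these names.
_DEFAULT_ARCHETYPES = {
    "A": [46, 47, 47, 48, 49, 49, 50, 51, 51, 52, 53, 53, 54, 54],
    "B": [22, 25, 29, 33, 37, 41, 44, 46, 48, 50, 52, 53, 54, 55],
    "C": [46, 43, 40, 37, 35, 33, 32, 34, 36, 39, 41, 43, 45, 46],
    "D": [22, 23, 23, 24, 25, 25, 26, 26, 27, 28, 28, 29, 30, 30],
}

# Pattern k is dominated by archetype k; the high- and low-SB patterns carry
# little of the opposite extreme. Dominance is set at 0.85 so that latent
# patterns remain identifiable from the at-most-7 observed days per
# participant (real cohorts mix day types more evenly; see docs/methods.md).
_DEFAULT_MIXTURES = [
    [0.8500, 0.0600, 0.0600, 0.0300],
    [0.0495, 0.8500, 0.0630, 0.0375],
    [0.0495, 0.0630, 0.8500, 0.0375],
    [0.0300, 0.0600, 0.0600, 0.8500],
]

# Cohort shares of the four patterns (high-SB pattern most common).
_DEFAULT_PATTERN_WEIGHTS = [0.361, 0.248, 0.183, 0.208]

# Daily MVPA minutes by pattern: high-SB participants move least.
_DEFAULT_MVPA_MEANS = [28.6, 54.2, 50.7, 82.1]
_DEFAULT_MVPA_SDS = [19.2, 28.8, 28.0, 38.9]

# Daily sedentary minutes by pattern, used only when covariates are drawn
# without an accompanying accelerometer stream.
_DEFAULT_SEDENTARY_MEANS = [668.8, 577.5, 592.7, 501.2]
_DEFAULT_SEDENTARY_SD = 85.0

POPULATION_IN_BED = "22:45"
POPULATION_OUT_OF_BED = "07:22"


@dataclass
class PFModelTruth:
    """Generative truth for the physical-functioning panel.

    ``baseline_by_stratum`` / ``slope_by_stratum`` are 2 x K arrays indexed
    [mvpa stratum (0 = low, 1 = high), pattern - 1]; units are PF points and
    PF points/year. Covariate effects are expressed relative to reference
    levels (categorical) or a centering constant (continuous), so each
    stratum baseline is the adjusted mean of its cell.
    """

    baseline_by_stratum: np.ndarray = field(
        default_factory=lambda: np.array(
            [[70.6, 75.1, 74.4, 73.5], [78.9, 81.5, 78.6, 80.5]]
        )
    )
    slope_by_stratum: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-2.4, -3.0, -2.5, -2.0], [-2.1, -1.9, -1.6, -1.7]]
        )
    )
    continuous_effects: dict = field(
        default_factory=lambda: {
            "age": (-0.5, 79.0),
            "bmi": (-0.5, 28.1),
            "total_sedentary_min": (-0.01, 597.0),
        }
    )
    categorical_effects: dict = field(
        default_factory=lambda: {
            "race_ethnicity": {"White": 0.0, "Black": -1.0, "Hispanic": -0.5},
            "education": {"hs_or_less": 0.0, "some_college": 1.0, "college_plus": 2.0},
            "smoker": {False: 0.0, True: -3.0},
            "alcohol": {"none": 0.0, "lt1_per_week": 0.5, "ge1_per_week": 1.0, "unknown": 0.0},
            "morbidity_count": {"0": 0.0, "1": -2.0, "2": -4.0, "3+": -7.0},
            "self_rated_health": {"excellent_vg": 0.0, "good": -4.0, "fair_poor": -10.0},
        }
    )
    random_intercept_sd: float = 12.0
    residual_sd: float = 7.0
    n_years: int = 7  # assessments at t = 0..6
    visit_missing_rate: float = 0.25  # post-baseline visits missed at random

    def validate(self) -> None:
        b = np.asarray(self.baseline_by_stratum, float)
        s = np.asarray(self.slope_by_stratum, float)
        if b.shape != s.shape or b.ndim != 2 or b.shape[0] != 2:
            raise ValueError("baseline/slope arrays must both be 2 x K")
        if np.any((b < 0) | (b > 100)):
            raise ValueError("stratum baselines must lie in [0, 100]")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_years < 2:
            raise ValueError("need at least two assessment years")

    @property
    def n_patterns(self) -> int:
        return np.asarray(self.baseline_by_stratum).shape[1]


class ConfigurationError(ValueError):
    """Raised for non-stochastic inconsistencies in a GeneratorConfig."""


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort draw."""

    n_participants: int = 500
    n_days: int = 7
    epoch_seconds: int = 15
    day_archetypes: dict = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_ARCHETYPES.items()}
    )
    archetype_noise_sd: float = 5.0
    pattern_mixtures: list = field(default_factory=lambda: [list(m) for m in _DEFAULT_MIXTURES])
    pattern_weights: list = field(default_factory=lambda: list(_DEFAULT_PATTERN_WEIGHTS))
    # Clock-time distributions, minutes since midnight.
    wake_time_mean: str = "07:20"
    wake_time_sd_min: float = 40.0
    sleep_time_mean: str = "22:30"
    sleep_time_sd_min: float = 45.0
    sleeplog_missing_rate: float = 0.08  # per day-field
    full_sleeplog_missing_rate: float = 0.07  # per participant
    nonwear_bout_rate: float = 0.10  # expected short bouts per day
    nonwear_bout_min_minutes: float = 90.0
    nonwear_bout_mean_extra: float = 20.0
    nonwear_bout_max_minutes: float = 150.0
    # A small share of participants wear the device erratically; their days
    # are frequently non-adherent, exercising the >= 4 adherent-day filter.
    low_adherence_participant_rate: float = 0.05
    low_adherence_day_drop: float = 0.60
    nonadherent_day_rate: float = 0.03
    mvpa_means_by_pattern: list = field(default_factory=lambda: list(_DEFAULT_MVPA_MEANS))
    mvpa_sds_by_pattern: list = field(default_factory=lambda: list(_DEFAULT_MVPA_SDS))
    mvpa_day_sd: float = 8.0
    # Latent stratum threshold: the population median of the MVPA mixture,
    # so the sample median split estimates the same cut the truth uses.
    mvpa_split_truth: float = 45.4
    mvpa_early_decay_hours: float = 4.0  # MVPA concentrates in early waking hours
    inbed_nonzero_rate: float = 0.02  # sparse low counts while in bed
    target_daily_sedentary_min: float = 597.0
    covariate_missing_rate: float = 0.02
    pf_model: PFModelTruth = field(default_factory=PFModelTruth)
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def archetype_labels(self) -> list[str]:
        return list(self.day_archetypes.keys())

    @property
    def n_archetypes(self) -> int:
        return len(self.day_archetypes)

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_mixtures)

    @property
    def wake_mean_min(self) -> float:
        from .containers import parse_clock

        return parse_clock(self.wake_time_mean)

    @property
    def sleep_mean_min(self) -> float:
        from .containers import parse_clock

        return parse_clock(self.sleep_time_mean)

    def archetype_matrix(self) -> np.ndarray:
        return np.array([self.day_archetypes[k] for k in self.archetype_labels], float)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if self.epoch_seconds != 15:
            raise ConfigurationError("only 15-s epochs are supported")
        curves = self.archetype_matrix()
        if curves.shape[1] != 14:
            raise ConfigurationError("archetype curves must have 14 hourly values")
        if np.any((curves < 0) | (curves > 60)):
            raise ConfigurationError("archetype values must lie in [0, 60] minutes/hour")
        if len(self.pattern_weights) != self.n_patterns:
            raise ConfigurationError("pattern_weights length must match pattern_mixtures")
        if abs(sum(self.pattern_weights) - 1.0) > 1e-9:
            raise ConfigurationError("pattern_weights must sum to 1")
        for m in self.pattern_mixtures:
            if len(m) != self.n_archetypes:
                raise ConfigurationError(
                    "mixture length must equal the number of archetypes"
                )
            if abs(sum(m) - 1.0) > 1e-9:
                raise ConfigurationError("each pattern mixture must sum to 1")
            if any(p < 0 for p in m):
                raise ConfigurationError("mixture probabilities must be non-negative")
        if not (
            len(self.mvpa_means_by_pattern)
            == len(self.mvpa_sds_by_pattern)
            == self.n_patterns
        ):
            raise ConfigurationError("MVPA mean/SD lists must match the pattern count")
        if self.archetype_noise_sd < 0:
            raise ConfigurationError("archetype_noise_sd must be non-negative")
        for rate in (
            self.sleeplog_missing_rate,
            self.full_sleeplog_missing_rate,
            self.covariate_missing_rate,
            self.low_adherence_participant_rate,
            self.nonadherent_day_rate,
        ):
            if not 0 <= rate <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.nonwear_bout_min_minutes < 90:
            raise ConfigurationError("non-wear bouts must last at least 90 minutes")
        self.pf_model.validate()
        if self.pf_model.n_patterns != self.n_patterns:
            raise ConfigurationError("PF truth pattern count must match pattern_mixtures")


@dataclass
class SyntheticTruth:
    """Latent labels behind one generated cohort."""

    pattern_by_participant: pd.Series  # pid -> pattern index (1-based)
    day_archetype: pd.DataFrame  # participant_id, date, archetype label
    mvpa_by_participant: pd.Series  # pid -> latent mean daily MVPA minutes
    mvpa_stratum: pd.Series  # pid -> 0 (low) / 1 (high)
    nonwear_bouts: pd.DataFrame  # participant_id, date, start_min, end_min
    pf_params: PFModelTruth

    def to_json(self, path) -> None:
        payload = {
            "pattern_by_participant": self.pattern_by_participant.to_dict(),
            "day_archetype": self.day_archetype.assign(
                date=self.day_archetype["date"].astype(str)
            ).to_dict(orient="list"),
            "mvpa_by_participant": self.mvpa_by_participant.to_dict(),
            "mvpa_stratum": {k: int(v) for k, v in self.mvpa_stratum.items()},
            "nonwear_bouts": self.nonwear_bouts.assign(
                date=self.nonwear_bouts["date"].astype(str)
            ).to_dict(orient="list"),
            "pf_params": {
                "baseline_by_stratum": np.asarray(self.pf_params.baseline_by_stratum).tolist(),
                "slope_by_stratum": np.asarray(self.pf_params.slope_by_stratum).tolist(),
                "random_intercept_sd": self.pf_params.random_intercept_sd,
                "residual_sd": self.pf_params.residual_sd,
                "n_years": self.pf_params.n_years,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_config(**overrides) -> GeneratorConfig:
    """The shipped default cohort configuration.

    Four day archetypes and four participant patterns, calibrated so the
    cohort means land near a typical older-women hip-accelerometer study:
    ~597 sedentary minutes/day, ~50 MVPA minutes/day, ~95% of participants
    retained by the adherence filter.
    """
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

_COVARIATE_LEVELS = {
    "race_ethnicity": (["White", "Black", "Hispanic"], [0.496, 0.336, 0.168]),
    "education": (["hs_or_less", "some_college", "college_plus"], [0.203, 0.381, 0.416]),
    "alcohol": (
        ["none", "lt1_per_week", "ge1_per_week", "unknown"],
        [0.337, 0.309, 0.269, 0.085],
    ),
    "morbidity_count": (["0", "1", "2", "3+"], [0.175, 0.340, 0.268, 0.217]),
    "self_rated_health": (["excellent_vg", "good", "fair_poor"], [0.520, 0.373, 0.107]),
}


def generate_covariates(
    participant_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the baseline covariate table (independent of pattern)."""
    n = len(participant_ids)
    table = pd.DataFrame({"participant_id": participant_ids})
    table["age"] = np.clip(rng.normal(79.0, 7.0, n), 63, 99).round(1)
    table["bmi"] = np.clip(rng.normal(28.1, 5.7, n), 15, 55).round(1)
    table["smoker"] = rng.random(n) < 0.026
    for col, (levels, probs) in _COVARIATE_LEVELS.items():
        table[col] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    return table


def pf_linear_predictor(
    pfm: PFModelTruth,
    pattern: np.ndarray,
    stratum: np.ndarray,
    covariates: pd.DataFrame,
    t: np.ndarray,
) -> np.ndarray:
    """Deterministic part of the PF model for participant rows at times t."""
    base = np.asarray(pfm.baseline_by_stratum, float)[stratum, pattern - 1]
    slope = np.asarray(pfm.slope_by_stratum, float)[stratum, pattern - 1]
    lp = base + slope * t
    for col, (effect, center) in pfm.continuous_effects.items():
        if col in covariates:
            lp = lp + effect * (covariates[col].to_numpy(float) - center)
    for col, mapping in pfm.categorical_effects.items():
        if col in covariates:
            lp = lp + covariates[col].map(mapping).to_numpy(float)
    return lp


def _draw_pattern_mvpa(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pattern = rng.choice(config.n_patterns, size=n, p=np.asarray(config.pattern_weights)) + 1
    means = np.asarray(config.mvpa_means_by_pattern)[pattern - 1]
    sds = np.asarray(config.mvpa_sds_by_pattern)[pattern - 1]
    mvpa = np.clip(rng.normal(means, sds), 0.0, None)
    stratum = (mvpa > config.mvpa_split_truth).astype(int)
    return pattern, mvpa, stratum


def _pf_panel(
    config: GeneratorConfig,
    participant_ids: list[str],
    pattern: np.ndarray,
    stratum: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    pfm = config.pf_model
    n = len(participant_ids)
    intercepts = rng.normal(0.0, pfm.random_intercept_sd, n)
    records = []
    for t in range(pfm.n_years):
        lp = pf_linear_predictor(pfm, pattern, stratum, covariates, np.full(n, float(t)))
        pf = lp + intercepts + rng.normal(0.0, pfm.residual_sd, n)
        pf = np.clip(pf, 0.0, 100.0)
        seen = np.ones(n, bool)
        if t > 0 and pfm.visit_missing_rate > 0:
            seen = rng.random(n) >= pfm.visit_missing_rate
        for i in np.nonzero(seen)[0]:
            records.append((participant_ids[i], t, pf[i]))
    return pd.DataFrame(records, columns=["participant_id", "year", "pf"])


def _blank_covariates(
    covariates: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Inject sporadic missingness into bmi / self-rated health."""
    out = covariates.copy()
    if rate > 0:
        for col in ("bmi", "self_rated_health"):
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = np.nan
    return out


def generate_pf_panel(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw pattern labels, covariates and a PF panel without accelerometry.

    A lightweight entry point for association-stage studies (parameter
    recovery, likelihood-ratio power) where the accelerometer stream is not
    needed. Returns ``(panel, covariates, truth_frame)`` where the covariate
    table includes the latent ``pattern``/``mvpa`` columns in ``truth_frame``.
    """
    config = config or default_config()
    config.validate()
    root = config.seed if seed is None else seed
    rng = substream(root, "pf-panel")
    ids = [f"P{i:04d}" for i in range(config.n_participants)]
    pattern, mvpa, stratum = _draw_pattern_mvpa(config, len(ids), rng)
    covariates = generate_covariates(ids, rng)
    sed_means = np.asarray(_DEFAULT_SEDENTARY_MEANS)[pattern - 1]
    covariates["total_sedentary_min"] = np.clip(
        rng.normal(sed_means, _DEFAULT_SEDENTARY_SD), 120, 1200
    ).round(1)
    covariates["mvpa_min"] = np.round(mvpa, 2)
    panel = _pf_panel(config, ids, pattern, stratum, covariates, rng)
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "pattern": pattern,
            "mvpa_stratum": stratum,
            "mvpa": mvpa,
        }
    )
    emitted = _blank_covariates(covariates, config.covariate_missing_rate, rng)
    return panel, emitted, truth


# ---------------------------------------------------------------------------
# Accelerometer stream generation
# ---------------------------------------------------------------------------


def _simulate_day_minutes(
    config: GeneratorConfig,
    curve: np.ndarray,
    wake_m: int,
    bed_m: int,
    mvpa_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minute-level behaviour classes for one calendar day."""
    classes = np.full(MINUTES_PER_DAY, int(ClassCode.INBED), dtype=np.int8)
    if bed_m <= wake_m:
        return classes
    first_full_hour = -(-wake_m // 60)  # ceil
    noise = config.archetype_noise_sd
    for h in range(wake_m // 60, (bed_m - 1) // 60 + 1):
        lo = max(h * 60, wake_m)
        hi = min(h * 60 + 60, bed_m)
        avail = hi - lo
        if avail <= 0:
            continue
        idx = min(max(h - first_full_hour, 0), 13)
        target = curve[idx] * avail / 60.0
        sd = noise * avail / 60.0
        sb = int(round(np.clip(rng.normal(target, sd) if sd > 0 else target, 0, avail)))
        minutes = np.arange(lo, hi)
        sed = rng.choice(minutes, size=sb, replace=False)
        classes[minutes] = int(ClassCode.LIGHT)
        classes[sed] = int(ClassCode.SEDENTARY)
    # MVPA placed among non-sedentary awake minutes, weighted toward the
    # early waking hours.
    if mvpa_target > 0:
        cand = np.nonzero(classes == int(ClassCode.LIGHT))[0]
        if cand.size:
            hours_from_wake = (cand - wake_m) / 60.0
            w = np.exp(-np.maximum(hours_from_wake, 0.0) / config.mvpa_early_decay_hours)
            w = w / w.sum()
            take = min(mvpa_target, cand.size)
            chosen = rng.choice(cand, size=take, replace=False, p=w)
            classes[chosen] = int(ClassCode.MVPA)
    return classes


def _counts_from_minutes(
    config: GeneratorConfig, classes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """15-s epoch counts realising the minute classes via the count bands."""
    counts = np.zeros(MINUTES_PER_DAY * EPOCHS_PER_MINUTE, dtype=np.int32)
    per_epoch = np.repeat(classes, EPOCHS_PER_MINUTE)
    sed = per_epoch == int(ClassCode.SEDENTARY)
    light = per_epoch == int(ClassCode.LIGHT)
    mvpa = per_epoch == int(ClassCode.MVPA)
    counts[sed] = rng.integers(0, SEDENTARY_MAX_COUNT + 1, sed.sum())
    counts[light] = rng.integers(SEDENTARY_MAX_COUNT + 1, MVPA_MIN_COUNT, light.sum())
    counts[mvpa] = rng.integers(MVPA_MIN_COUNT, COUNT_CEILING + 1, mvpa.sum())
    # Sparse low counts during in-bed minutes (turning over in bed).
    inbed_minutes = np.nonzero(classes == int(ClassCode.INBED))[0]
    if config.inbed_nonzero_rate > 0 and inbed_minutes.size:
        stir = inbed_minutes[rng.random(inbed_minutes.size) < config.inbed_nonzero_rate]
        for m in stir:
            counts[m * EPOCHS_PER_MINUTE : (m + 1) * EPOCHS_PER_MINUTE] = rng.integers(
                1, SEDENTARY_MAX_COUNT + 1, EPOCHS_PER_MINUTE
            )
    return counts


def _inject_nonwear(
    config: GeneratorConfig,
    counts_day: np.ndarray,
    wake_m: int,
    bed_m: int,
    low_adherence: bool,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Zero out non-wear bouts within the waking window; return bout spans."""
    span = bed_m - wake_m
    bouts: list[tuple[int, int]] = []
    if span < 120:
        return bouts
    drop_p = config.low_adherence_day_drop if low_adherence else config.nonadherent_day_rate
    if rng.random() < drop_p:
        # One long bout that pushes awake wear below the 600-min adherence bar.
        need = max(int(span - 599), 90)
        dur = int(rng.uniform(min(need + 30, span - 60), max(need + 30, span - 60) + 1))
        dur = min(max(dur, need), span - 30)
        start = wake_m + int(rng.uniform(0, span - dur))
        bouts.append((start, start + dur))
    else:
        n_bouts = rng.poisson(config.nonwear_bout_rate)
        budget = span - 630  # keep the day adherent
        for _ in range(n_bouts):
            dur = int(
                min(
                    config.nonwear_bout_min_minutes
                    + rng.exponential(config.nonwear_bout_mean_extra),
                    config.nonwear_bout_max_minutes,
                )
            )
            if dur > budget:
                continue
            for _attempt in range(5):
                start = wake_m + int(rng.uniform(0, span - dur))
                if all(start + dur <= b0 or start >= b1 for b0, b1 in bouts):
                    bouts.append((start, start + dur))
                    budget -= dur
                    break
    for b0, b1 in bouts:
        counts_day[b0 * EPOCHS_PER_MINUTE : b1 * EPOCHS_PER_MINUTE] = 0
    return bouts


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[list[EpochSeries], pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a full synthetic cohort.

    Returns ``(epoch_series, sleep_logs, covariates, pf_panel, truth)``.
    Sleep-log times are ``"HH:MM"`` strings with blanks for missing entries;
    the covariate table carries accelerometer-derived mean daily sedentary
    and MVPA minutes alongside the questionnaire covariates.
    """
    config = config or default_config()
    config.validate()
    rng = substream(config.seed, "cohort")
    pf_rng = substream(config.seed, "pf-panel")
    n = config.n_participants
    ids = [f"P{i:04d}" for i in range(n)]
    pattern, mvpa, stratum = _draw_pattern_mvpa(config, n, rng)
    covariates = generate_covariates(ids, pf_rng)
    curves = config.archetype_matrix()
    labels = config.archetype_labels
    start0 = pd.Timestamp("2024-01-01")

    series: list[EpochSeries] = []
    sleep_rows = []
    truth_days = []
    truth_bouts = []
    measured_sed = np.zeros(n)
    measured_mvpa = np.zeros(n)
    low_adh = rng.random(n) < config.low_adherence_participant_rate
    full_log_missing = rng.random(n) < config.full_sleeplog_missing_rate

    for i, pid in enumerate(ids):
        mix = np.asarray(config.pattern_mixtures[pattern[i] - 1], float)
        counts = np.zeros(config.n_days * EPOCHS_PER_DAY, dtype=np.int32)
        sed_days = []
        mvpa_days = []
        for d in range(config.n_days):
            date = start0 + pd.Timedelta(days=d)
            arch = int(rng.choice(config.n_archetypes, p=mix))
            wake_m = int(round(np.clip(rng.normal(config.wake_mean_min, config.wake_time_sd_min), 240, 720)))
            bed_m = int(round(np.clip(rng.normal(config.sleep_mean_min, config.sleep_time_sd_min), 1140, 1439)))
            mvpa_today = int(round(max(rng.normal(mvpa[i], config.mvpa_day_sd), 0.0)))
            classes = _simulate_day_minutes(
                config, curves[arch], wake_m, bed_m, mvpa_today, rng
            )
            day_counts = _counts_from_minutes(config, classes, rng)
            bouts = _inject_nonwear(config, day_counts, wake_m, bed_m, bool(low_adh[i]), rng)
            counts[d * EPOCHS_PER_DAY : (d + 1) * EPOCHS_PER_DAY] = day_counts
            sed_days.append((classes == int(ClassCode.SEDENTARY)).sum())
            mvpa_days.append((classes == int(ClassCode.MVPA)).sum())
            truth_days.append((pid, date, labels[arch]))
            for b0, b1 in bouts:
                truth_bouts.append((pid, date, b0, b1))
            in_bed = format_clock(bed_m)
            out_bed = format_clock(wake_m)
            if full_log_missing[i]:
                in_bed = out_bed = ""
            else:
                if rng.random() < config.sleeplog_missing_rate:
                    in_bed = ""
                if rng.random() < config.sleeplog_missing_rate:
                    out_bed = ""
            sleep_rows.append((pid, date, in_bed, out_bed))
        series.append(EpochSeries(pid, start0, counts))
        measured_sed[i] = float(np.mean(sed_days))
        measured_mvpa[i] = float(np.mean(mvpa_days))

    covariates["total_sedentary_min"] = np.round(measured_sed, 2)
    covariates["mvpa_min"] = np.round(measured_mvpa, 2)
    pf_panel = _pf_panel(config, ids, pattern, stratum, covariates, pf_rng)
    covariates_out = _blank_covariates(covariates, config.covariate_missing_rate, pf_rng)

    sleep_logs = pd.DataFrame(
        sleep_rows, columns=["participant_id", "date", "in_bed", "out_of_bed"]
    )
    truth = SyntheticTruth(
        pattern_by_participant=pd.Series(pattern, index=ids, name="pattern"),
        day_archetype=pd.DataFrame(
            truth_days, columns=["participant_id", "date", "archetype"]
        ),
        mvpa_by_participant=pd.Series(mvpa, index=ids, name="mvpa"),
        mvpa_stratum=pd.Series(stratum, index=ids, name="mvpa_stratum"),
        nonwear_bouts=pd.DataFrame(
            truth_bouts, columns=["participant_id", "date", "start_min", "end_min"]
        ),
        pf_params=dataclasses.replace(config.pf_model),
    )
    return series, sleep_logs, covariates_out, pf_panel, truth
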