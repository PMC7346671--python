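"""Wake-aligned 14-hour daily sedentary trajectories with Copy-Mean imputation.

Each adherent day is reduced to 14 consecutive hourly sedentary-minute
values, starting at the first full clock hour the participant was awake and
wearing the device. Hours without complete awake wear are treated as missing
and imputed by Copy Mean: linear interpolation between observed values,
corrected by the local shape of the population mean curve (with an optional
seeded Gaussian jitter, off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import ClassCode, ClassifiedDay, EPOCHS_PER_MINUTE

__all__ = [
    "DayTrajectory",
    "DayDropped",
    "hourly_sb",
    "extract_trajectory",
    "extract_trajectory_clock",
    "copy_mean_impute",
    "trajectory_matrix",
]

TRAJECTORY_HOURS = 14
DEFAULT_CLOCK_START_HOUR = 8
MAX_MISSING_FRACTION = 0.5


class DayDropped(ValueError):
    """A day could not yield a trajectory (e.g. no fully worn awake hour)."""


@dataclass
class DayTrajectory:
    """One day's 14-element hourly sedentary-minute vector.

    ``values`` holds NaN at masked (unobserved) positions before imputation;
    after imputation every entry lies in [0, 60].
    """

    participant_id: str
    date: pd.Timestamp
    values: np.ndarray  # length 14, minutes/hour
    observed_mask: np.ndarray  # length 14, True = observed
    alignment: str  # "wake_aligned" | "clock_aligned"
    start_hour: int  # clock hour of element 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != (TRAJECTORY_HOURS,) or self.observed_mask.shape != (
            TRAJECTORY_HOURS,
        ):
            raise ValueError("a day trajectory has exactly 14 hourly elements")

    @property
    def n_missing(self) -> int:
        return int((~self.observed_mask).sum())


def hourly_sb(day: ClassifiedDay) -> tuple[np.ndarray, np.ndarray]:
    """Per clock-hour sedentary minutes and awake-wear coverage for one day.

    Returns ``(sb, coverage)``, both length-24 arrays in minutes: ``sb[h]``
    is sedentary time with timestamps in [h:00, h:59], ``coverage[h]`` the
    awake-wear minutes in the same window.
    """
    cls = day.epoch_classes.reshape(24, 60 * EPOCHS_PER_MINUTE)
    sb = (cls == int(ClassCode.SEDENTARY)).sum(axis=1) / EPOCHS_PER_MINUTE
    awake = np.isin(cls, (int(ClassCode.SEDENTARY), int(ClassCode.LIGHT), int(ClassCode.MVPA)))
    coverage = awake.sum(axis=1) / EPOCHS_PER_MINUTE
    return sb.astype(float), coverage.astype(float)


def _build(day, sb, coverage, start_hour, alignment) -> DayTrajectory:
    values = np.full(TRAJECTORY_HOURS, np.nan)
    mask = np.zeros(TRAJECTORY_HOURS, dtype=bool)
    for j in range(TRAJECTORY_HOURS):
        h = start_hour + j
        if h > 23:
            break  # trailing elements beyond the day remain missing
        if coverage[h] == 60.0:
            values[j] = sb[h]
            mask[j] = True
    return DayTrajectory(
        participant_id=day.participant_id,
        date=day.date,
        values=values,
        observed_mask=mask,
        alignment=alignment,
        start_hour=start_hour,
    )


def extract_trajectory(
    day: ClassifiedDay,
    sb: np.ndarray | None = None,
    coverage: np.ndarray | None = None,
    *,
    require_awake: bool = True,
) -> DayTrajectory:
    """Wake-aligned trajectory: element 0 is the first clock-hour bin at or
    after the resolved wake time with 60 min of coverage.

    With ``require_awake`` (default) coverage means awake wear, i.e. the
    starting hour must be fully awake *and* worn; with ``require_awake=False``
    only full wear is required (in-bed minutes do not disqualify the hour,
    though such hours still count as missing in the body of the trajectory).
    """
    if sb is None or coverage is None:
        sb, coverage = hourly_sb(day)
    if not require_awake:
        nonwear = (day.epoch_classes.reshape(24, 240) == int(ClassCode.NONWEAR)).sum(axis=1)
        start_cov = 60.0 - nonwear / EPOCHS_PER_MINUTE
    else:
        start_cov = coverage
    wake = day.wake_minutes
    start_hour = None
    for h in range(24):
        if h * 60 >= wake and start_cov[h] == 60.0:
            start_hour = h
            break
    if start_hour is None:
        raise DayDropped(
            f"{day.participant_id} {day.date.date()}: no fully worn awake hour"
        )
    return _build(day, sb, coverage, start_hour, "wake_aligned")


def extract_trajectory_clock(
    day: ClassifiedDay,
    sb: np.ndarray | None = None,
    coverage: np.ndarray | None = None,
    *,
    fixed_start_hour: int = DEFAULT_CLOCK_START_HOUR,
) -> DayTrajectory:
    """Clock-aligned variant: 14 bins from a fixed clock hour (default 08:00,
    covering 8 am to 10 pm), with the same full-coverage missingness rule."""
    if sb is None or coverage is None:
        sb, coverage = hourly_sb(day)
    return _build(day, sb, coverage, fixed_start_hour, "clock_aligned")


def population_mean_curve(trajectories: list[DayTrajectory]) -> np.ndarray:
    """Hour-wise mean of observed values across all day trajectories."""
    stack = np.array([t.values for t in trajectories])
    mask = np.array([t.observed_mask for t in trajectories])
    with np.errstate(invalid="ignore"):
        sums = np.where(mask, stack, 0.0).sum(axis=0)
        counts = mask.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("population mean curve undefined: some hour never observed")
    return sums / counts


def _impute_one(values: np.ndarray, mask: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Copy-Mean completion of one trajectory against mean curve M."""
    out = values.copy()
    obs = np.flatnonzero(mask)
    first, last = obs[0], obs[-1]
    for t in np.flatnonzero(~mask):
        if t < first:  # leading gap: carry nearest observed value, mean-shifted
            out[t] = values[first] + (M[t] - M[first])
        elif t > last:
            out[t] = values[last] + (M[t] - M[last])
        else:
            a = obs[obs < t][-1]
            b = obs[obs > t][0]
            w = (t - a) / (b - a)
            interp_obs = values[a] + w * (values[b] - values[a])
            interp_m = M[a] + w * (M[b] - M[a])
            out[t] = interp_obs + (M[t] - interp_m)
    return np.clip(out, 0.0, 60.0)


def copy_mean_impute(
    trajectories: list[DayTrajectory],
    *,
    jitter_sd: float = 0.0,
    seed: int = 0,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> tuple[list[DayTrajectory], np.ndarray]:
    """Complete missing hours by Copy Mean.

    Days with more than ``max_missing_fraction`` of hours missing are dropped
    before the population mean curve is computed. Observed entries are never
    modified. Returns ``(completed trajectories, population mean curve)``.
    """
    kept = [t for t in trajectories if t.n_missing / TRAJECTORY_HOURS <= max_missing_fraction]
    if not kept:
        raise ValueError("no trajectories survive the missingness guard")
    for t in kept:
        if t.observed_mask.sum() == 0:
            raise ValueError("all-missing trajectory should have been dropped upstream")
    M = population_mean_curve(kept)
    rng = substream(seed, "copy-mean-jitter")
    completed = []
    for t in kept:
        if t.n_missing == 0:
            completed.append(t)
            continue
        values = _impute_one(t.values, t.observed_mask, M)
        if jitter_sd > 0:
            missing = ~t.observed_mask
            values[missing] = np.clip(
                values[missing] + rng.normal(0.0, jitter_sd, missing.sum()), 0.0, 60.0
            )
        completed.append(
            DayTrajectory(
                participant_id=t.participant_id,
                date=t.date,
                values=values,
                observed_mask=t.observed_mask,
                alignment=t.alignment,
                start_hour=t.start_hour,
            )
        )
    return completed, M


def trajectory_matrix(trajectories: list[DayTrajectory]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack completed trajectories into an (n_days x 14) matrix plus an index."""
    X = np.array([t.values for t in trajectories], dtype=float)
    index = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trajectories],
            "date": [t.date for t in trajectories],
            "alignment": [t.alignment for t in trajectories],
            "start_hour": [t.start_hour for t in trajectories],
        }
    )
    return X, index
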