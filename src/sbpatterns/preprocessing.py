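"""Raw epoch streams -> classified, wear-masked, adherence-filtered days.

The processing chain mirrors standard hip-accelerometer practice for older
cohorts: sum 15-s vector-magnitude counts to the minute, detect non-wear on
the minute series with the Choi algorithm (90-min window, 30-min stream
frame, 2-min tolerance), remove in-bed time using sleep logs (imputing
missing bed times), classify remaining epochs with the calibrated cutpoints
(sedentary <= 18 counts/15 s, MVPA > 519), and keep calendar days with at
least 10 h of awake wear for participants contributing at least 4 such days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_MINUTE,
    MINUTES_PER_DAY,
    ClassCode,
    ClassifiedDay,
    EpochSeries,
    circular_mean_clock,
    parse_clock,
)
from .synthetic import (
    MVPA_MIN_COUNT,
    POPULATION_IN_BED,
    POPULATION_OUT_OF_BED,
    SEDENTARY_MAX_COUNT,
)

__all__ = [
    "aggregate_minutes",
    "choi_nonwear",
    "resolve_bed_times",
    "classify_epochs",
    "filter_cohort",
    "CohortSummary",
]

CHOI_WINDOW_MIN = 90
CHOI_STREAM_FRAME_MIN = 30
CHOI_TOLERANCE_MIN = 2

ADHERENT_WEAR_MINUTES = 600.0
MIN_ADHERENT_DAYS = 4


def aggregate_minutes(epochs: EpochSeries) -> np.ndarray:
    """Minute-level counts: the sum of each minute's four 15-s epochs.

    A partial trailing minute (fewer than 4 epochs) is dropped.
    """
    counts = np.asarray(epochs.counts)
    n_minutes = counts.shape[0] // EPOCHS_PER_MINUTE
    if n_minutes == 0:
        raise ValueError("epoch stream shorter than one minute")
    return counts[: n_minutes * EPOCHS_PER_MINUTE].reshape(n_minutes, EPOCHS_PER_MINUTE).sum(axis=1)


def _zero_runs(zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open intervals."""
    padded = np.concatenate([[False], zero, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def choi_nonwear(minute_counts: np.ndarray) -> np.ndarray:
    """Per-minute non-wear mask (True = non-wear) by the Choi rule.

    A non-wear interval is a run of zero-count minutes at least 90 min long,
    in which an interruption of up to 2 consecutive non-zero minutes is
    tolerated provided the zero runs immediately flanking it are each at
    least 30 min long (the stream frame). Tolerated interruption minutes are
    themselves marked non-wear. Interruptions at the boundary of a run are
    not tolerated.
    """
    minute_counts = np.asarray(minute_counts)
    if minute_counts.size == 0:
        raise ValueError("empty minute series")
    zero = minute_counts == 0
    runs = _zero_runs(zero)
    nonwear = np.zeros(minute_counts.size, dtype=bool)
    if not runs:
        return nonwear
    # Chain zero runs across tolerated interruptions; flank lengths are the
    # original zero-run lengths adjacent to each interruption.
    i = 0
    while i < len(runs):
        j = i
        while j + 1 < len(runs):
            gap = runs[j + 1][0] - runs[j][1]
            left_len = runs[j][1] - runs[j][0]
            right_len = runs[j + 1][1] - runs[j + 1][0]
            if (
                gap <= CHOI_TOLERANCE_MIN
                and left_len >= CHOI_STREAM_FRAME_MIN
                and right_len >= CHOI_STREAM_FRAME_MIN
            ):
                j += 1
            else:
                break
        span_start, span_stop = runs[i][0], runs[j][1]
        if span_stop - span_start >= CHOI_WINDOW_MIN:
            nonwear[span_start:span_stop] = True
        i = j + 1
    return nonwear


def resolve_bed_times(sleep_logs: pd.DataFrame) -> pd.DataFrame:
    """Complete nightly in-bed / out-of-bed times.

    Missing fields are filled with that participant's circular mean of the
    available same-field clock times; participants missing a field on every
    night receive the population constants (in-bed 22:45, out-of-bed 07:22).

    Input columns: participant_id, date, in_bed, out_of_bed, where times are
    ``"HH:MM"`` strings (or already-numeric minutes) with blanks/NaN for
    missing. Output replaces the time columns with float minutes since
    midnight and adds ``in_bed_imputed`` / ``out_of_bed_imputed`` flags.
    """

    def to_minutes(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        if isinstance(v, str):
            return parse_clock(v) if v.strip() else np.nan
        return float(v)

    out = sleep_logs.copy()
    for col in ("in_bed", "out_of_bed"):
        out[col] = out[col].map(to_minutes)
        out[f"{col}_imputed"] = out[col].isna()
    pop = {"in_bed": parse_clock(POPULATION_IN_BED), "out_of_bed": parse_clock(POPULATION_OUT_OF_BED)}
    for col in ("in_bed", "out_of_bed"):
        for _, idx in out.groupby("participant_id").groups.items():
            vals = out.loc[idx, col]
            if vals.isna().all():
                out.loc[idx, col] = pop[col]
            elif vals.isna().any():
                fill = circular_mean_clock(vals.dropna().to_numpy())
                out.loc[idx, col] = vals.fillna(fill)
    return out


def classify_epochs(
    epochs: EpochSeries,
    wear_minutes: np.ndarray,
    bed_times: pd.DataFrame,
) -> list[ClassifiedDay]:
    """Label every epoch and split the stream into classified calendar days.

    Per-epoch priority: in-bed > non-wear > intensity class. In-bed time for
    calendar day d is [midnight, out_of_bed_d) plus [in_bed_d, midnight);
    an in-bed clock time before noon is interpreted as after midnight and is
    covered by the next morning's window. ``wear_minutes`` is the per-minute
    wear mask (True = worn) from :func:`choi_nonwear`, inverted.
    """
    counts = np.asarray(epochs.counts)
    n_days = counts.shape[0] // EPOCHS_PER_DAY
    if n_days * EPOCHS_PER_DAY != counts.shape[0]:
        raise ValueError("epoch stream must cover whole calendar days")
    if wear_minutes.shape[0] < n_days * MINUTES_PER_DAY:
        raise ValueError("wear mask does not cover the epoch span")

    classes = np.where(
        counts <= SEDENTARY_MAX_COUNT,
        int(ClassCode.SEDENTARY),
        np.where(counts >= MVPA_MIN_COUNT, int(ClassCode.MVPA), int(ClassCode.LIGHT)),
    ).astype(np.int8)
    nonwear_epochs = np.repeat(~wear_minutes[: n_days * MINUTES_PER_DAY], EPOCHS_PER_MINUTE)
    classes[nonwear_epochs] = int(ClassCode.NONWEAR)

    logs = bed_times[bed_times["participant_id"] == epochs.participant_id]
    by_date = {pd.Timestamp(d).normalize(): (ib, ob) for d, ib, ob in
               zip(logs["date"], logs["in_bed"], logs["out_of_bed"])}

    days: list[ClassifiedDay] = []
    for d in range(n_days):
        date = (epochs.start + pd.Timedelta(days=d)).normalize()
        if date not in by_date:
            raise ValueError(f"no resolved bed times for {epochs.participant_id} on {date.date()}")
        in_bed, out_bed = by_date[date]
        day_cls = classes[d * EPOCHS_PER_DAY : (d + 1) * EPOCHS_PER_DAY].copy()
        morning_end = int(round(out_bed)) * EPOCHS_PER_MINUTE
        day_cls[: min(morning_end, EPOCHS_PER_DAY)] = int(ClassCode.INBED)
        if in_bed >= 720:  # evening bedtime on this date
            evening_start = int(round(in_bed)) * EPOCHS_PER_MINUTE
            day_cls[min(evening_start, EPOCHS_PER_DAY):] = int(ClassCode.INBED)
        days.append(
            ClassifiedDay(
                participant_id=epochs.participant_id,
                date=date,
                epoch_classes=day_cls,
                wake_minutes=float(out_bed),
                bed_minutes=float(in_bed),
            )
        )
    return days


@dataclass
class CohortSummary:
    """Analytic day and participant sets after the adherence filter."""

    days: list[ClassifiedDay]  # adherent days of retained participants
    participants: list[str]
    participant_means: pd.DataFrame  # mean daily sedentary / MVPA over retained days
    n_days_input: int
    n_participants_input: int


def filter_cohort(days: list[ClassifiedDay]) -> CohortSummary:
    """Keep adherent days, then participants with >= 4 adherent days."""
    n_days_input = len(days)
    pids_input = {d.participant_id for d in days}
    adherent = [d for d in days if d.adherent]
    per_pid: dict[str, list[ClassifiedDay]] = {}
    for d in adherent:
        per_pid.setdefault(d.participant_id, []).append(d)
    kept = {pid: ds for pid, ds in per_pid.items() if len(ds) >= MIN_ADHERENT_DAYS}
    retained_days = [d for ds in kept.values() for d in ds]
    means = pd.DataFrame(
        {
            "participant_id": list(kept),
            "n_adherent_days": [len(ds) for ds in kept.values()],
            "total_sedentary_min": [
                float(np.mean([d.sedentary_minutes_total for d in ds])) for ds in kept.values()
            ],
            "mvpa_min": [
                float(np.mean([d.mvpa_minutes_total for d in ds])) for ds in kept.values()
            ],
        }
    )
    return CohortSummary(
        days=retained_days,
        participants=sorted(kept),
        participant_means=means,
        n_days_input=n_days_input,
        n_participants_input=len(pids_input),
    )
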