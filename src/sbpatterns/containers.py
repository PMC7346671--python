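"""Core in-memory containers shared across the pipeline.

Conventions used throughout:

* Epochs are 15-second windows; a minute is exactly 4 epochs; a calendar day
  is 5760 epochs (1440 minutes), midnight to midnight local time.
* Clock times are minutes since local midnight (float in [0, 1440)).
* Per-epoch behaviour classes are small integer codes (`ClassCode`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

EPOCH_SECONDS = 15
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS
MINUTES_PER_DAY = 1440
EPOCHS_PER_DAY = MINUTES_PER_DAY * EPOCHS_PER_MINUTE

__all__ = [
    "EPOCH_SECONDS",
    "EPOCHS_PER_MINUTE",
    "MINUTES_PER_DAY",
    "EPOCHS_PER_DAY",
    "ClassCode",
    "EpochSeries",
    "ClassifiedDay",
    "parse_clock",
    "format_clock",
    "circular_mean_clock",
]


class ClassCode(IntEnum):
    """Per-epoch behaviour class.

    Priority when labelling is in-bed > non-wear > intensity class; the
    intensity cutpoints operate on vector-magnitude counts per 15-s epoch
    (sedentary <= 18 counts, MVPA > 519 counts, light in between).
    """

    SEDENTARY = 0
    LIGHT = 1
    MVPA = 2
    NONWEAR = 3
    INBED = 4


def parse_clock(text: str) -> float:
    """Parse ``"HH:MM"`` into minutes since midnight."""
    hh, mm = text.strip().split(":")
    value = int(hh) * 60 + int(mm)
    if not 0 <= value < MINUTES_PER_DAY:
        raise ValueError(f"clock time out of range: {text!r}")
    return float(value)


def format_clock(minutes: float) -> str:
    """Render minutes-since-midnight as ``"HH:MM"`` (rounded to the minute)."""
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def circular_mean_clock(values: np.ndarray | list[float]) -> float:
    """Mean of clock times on the 24-h circle, in minutes since midnight.

    A naive arithmetic mean of 23:30 and 00:30 gives midday; the circular
    mean correctly gives midnight.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("circular mean of empty set")
    theta = v * (2 * np.pi / MINUTES_PER_DAY)
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float((mean_angle * MINUTES_PER_DAY / (2 * np.pi)) % MINUTES_PER_DAY)


@dataclass
class EpochSeries:
    """Contiguous 15-s vector-magnitude count stream for one participant.

    ``start`` is midnight of the first recorded calendar day; ``counts`` runs
    on an uninterrupted 15-s grid from there (``n_days * 5760`` entries for a
    whole-day recording).
    """

    participant_id: str
    start: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("vector-magnitude counts must be non-negative")
        self.start = pd.Timestamp(self.start)

    @property
    def n_epochs(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_days(self) -> int:
        return self.n_epochs // EPOCHS_PER_DAY

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * EPOCH_SECONDS, unit="s"
        )

    def dates(self) -> list[pd.Timestamp]:
        """Midnights of the calendar days covered by the stream."""
        return [self.start + pd.Timedelta(days=d) for d in range(self.n_days)]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EpochSeries":
        """Build from a long-format frame (participant_id, timestamp, vm_counts).

        The timestamps must form a strictly increasing, gap-free 15-s grid.
        """
        pids = frame["participant_id"].unique()
        if len(pids) != 1:
            raise ValueError("from_frame expects a single participant")
        ts = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
        if ts.has_duplicates:
            raise ValueError("duplicate timestamps in epoch stream")
        deltas = np.diff(ts.asi8)
        if len(deltas) and not np.all(deltas == EPOCH_SECONDS * 1_000_000_000):
            raise ValueError("timestamps must be a contiguous 15-s grid")
        start = ts[0].normalize()
        offset = int((ts[0] - start).total_seconds()) // EPOCH_SECONDS
        if offset != 0:
            # Pad the head of the day with zero counts so the stream is
            # midnight-aligned; padded epochs fall in the in-bed window for
            # any plausible wake time.
            counts = np.concatenate(
                [np.zeros(offset, dtype=np.int32), frame["vm_counts"].to_numpy(np.int32)]
            )
        else:
            counts = frame["vm_counts"].to_numpy(np.int32)
        return cls(str(pids[0]), start, counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.timestamps(),
                "vm_counts": self.counts,
            }
        )


@dataclass
class ClassifiedDay:
    """One calendar day of per-epoch behaviour classes with daily totals."""

    participant_id: str
    date: pd.Timestamp
    epoch_classes: np.ndarray  # int8 codes, length 5760
    wake_minutes: float  # resolved out-of-bed clock time for this day
    bed_minutes: float  # resolved in-bed clock time for this day
    awake_wear_minutes: float = field(init=False)
    sedentary_minutes_total: float = field(init=False)
    mvpa_minutes_total: float = field(init=False)
    adherent: bool = field(init=False)

    ADHERENT_WEAR_MINUTES = 600.0  # "10 h or more of awake wear"

    def __post_init__(self) -> None:
        c = np.asarray(self.epoch_classes, dtype=np.int8)
        if c.shape != (EPOCHS_PER_DAY,):
            raise ValueError("a classified day must contain exactly 5760 epochs")
        self.epoch_classes = c
        awake = np.isin(c, (ClassCode.SEDENTARY, ClassCode.LIGHT, ClassCode.MVPA))
        self.awake_wear_minutes = float(awake.sum() / EPOCHS_PER_MINUTE)
        self.sedentary_minutes_total = float(
            (c == ClassCode.SEDENTARY).sum() / EPOCHS_PER_MINUTE
        )
        self.mvpa_minutes_total = float((c == ClassCode.MVPA).sum() / EPOCHS_PER_MINUTE)
        self.adherent = self.awake_wear_minutes >= self.ADHERENT_WEAR_MINUTES

    def class_counts(self) -> dict[str, int]:
        return {
            code.name.lower(): int((self.epoch_classes == code).sum())
            for code in ClassCode
        }
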