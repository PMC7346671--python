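"""Reading and writing pipeline artifacts as plain-text formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSeries
from .trajectories import DayTrajectory, TRAJECTORY_HOURS

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_sleep_logs",
    "read_sleep_logs",
    "write_trajectories",
    "read_trajectories",
    "write_wear_mask_rle",
    "write_json",
]


def write_epochs(series: list[EpochSeries], path: str | Path, fmt: str = "csv") -> None:
    """Long-format epoch table (participant_id, timestamp, vm_counts)."""
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    path = Path(path)
    if fmt == "parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_epochs(path: str | Path) -> list[EpochSeries]:
    path = Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        EpochSeries.from_frame(g.sort_values("timestamp"))
        for _, g in frame.groupby("participant_id", sort=True)
    ]


def write_sleep_logs(logs: pd.DataFrame, path: str | Path) -> None:
    out = logs.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_sleep_logs(path: str | Path) -> pd.DataFrame:
    logs = pd.read_csv(path, dtype={"in_bed": str, "out_of_bed": str})
    logs["date"] = pd.to_datetime(logs["date"])
    for col in ("in_bed", "out_of_bed"):
        logs[col] = logs[col].fillna("")
    return logs


def write_trajectories(trajectories: list[DayTrajectory], path: str | Path) -> None:
    """Wide CSV: h00..h13 values plus m00..m13 observation-mask columns."""
    rows = []
    for t in trajectories:
        row = {
            "participant_id": t.participant_id,
            "date": pd.Timestamp(t.date).date(),
            "alignment": t.alignment,
            "start_hour": t.start_hour,
        }
        for j in range(TRAJECTORY_HOURS):
            row[f"h{j:02d}"] = t.values[j]
            row[f"m{j:02d}"] = int(t.observed_mask[j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[DayTrajectory]:
    frame = pd.read_csv(path, parse_dates=["date"])
    out = []
    for _, row in frame.iterrows():
        out.append(
            DayTrajectory(
                participant_id=str(row["participant_id"]),
                date=row["date"],
                values=np.array([row[f"h{j:02d}"] for j in range(TRAJECTORY_HOURS)]),
                observed_mask=np.array(
                    [bool(row[f"m{j:02d}"]) for j in range(TRAJECTORY_HOURS)]
                ),
                alignment=str(row["alignment"]),
                start_hour=int(row["start_hour"]),
            )
        )
    return out


def write_wear_mask_rle(
    masks: dict[str, np.ndarray], start: pd.Timestamp, path: str | Path
) -> None:
    """Per-minute wear masks as run-length intervals (participant, start, end, state)."""
    rows = []
    for pid, wear in masks.items():
        w = np.asarray(wear, bool)
        boundaries = np.flatnonzero(np.diff(w.astype(int))) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [w.size]])
        for s, e in zip(starts, ends):
            rows.append(
                {
                    "participant_id": pid,
                    "start": start + pd.Timedelta(minutes=int(s)),
                    "end": start + pd.Timedelta(minutes=int(e)),
                    "state": "wear" if w[s] else "nonwear",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(payload: dict, path: str | Path) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (pd.Timestamp,)):
            return str(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)
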