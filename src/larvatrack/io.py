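"""Trajectory tables, robot event logs and provenance-stamped artifacts.

The trajectory table is the pipeline's central on-disk record: one CSV row
per (frame, animal), with posture and state columns appended as analysis
stages run.  Files carry ``# key=value`` provenance comment lines (config
hash, seed) ahead of the header.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RobotEvent

TRAJECTORY_COLUMNS = [
    "time_s",
    "frame",
    "animal_id",
    "x_mm",
    "y_mm",
    "head_x_mm",
    "head_y_mm",
    "tail_x_mm",
    "tail_y_mm",
    "bend_deg",
    "state",
    "interpolated",
    "contact",
    "event_id",
]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory table."""


def write_trajectory_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a trajectory table, prepending provenance comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_trajectory_table(path) -> pd.DataFrame:
    """Read and validate a trajectory table.

    Raises :class:`TrajectoryFormatError` naming the offending line for
    duplicated (frame, animal_id) keys; unknown columns raise a warning.
    Provenance comments are returned in ``df.attrs['meta']``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", dtype={"event_id": "string"})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    if unknown:
        warnings.warn(f"unknown trajectory columns ignored: {unknown}", stacklevel=2)
    if len(df):
        dup = df.duplicated(subset=["frame", "animal_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            line_no = row + n_comment + 2  # 1-based, after comments and header
            raise TrajectoryFormatError(
                f"duplicate (frame, animal_id) key at line {line_no}: "
                f"frame={df.iloc[row]['frame']}, animal_id={df.iloc[row]['animal_id']}"
            )
    df.attrs["meta"] = meta
    return df


def write_events_jsonl(events: list[RobotEvent], path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if meta:
            fh.write(json.dumps({"_meta": meta}) + "\n")
        for ev in events:
            fh.write(json.dumps(ev.to_json()) + "\n")


def read_events_jsonl(path) -> list[RobotEvent]:
    events: list[RobotEvent] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if "_meta" in d:
                continue
            events.append(
                RobotEvent(
                    time_s=d["time_s"],
                    frame=d["frame"],
                    animal_id=d["animal_id"],
                    type=d["type"],
                    from_xy_mm=tuple(d["from_xy_mm"]) if d["from_xy_mm"] else None,
                    to_xy_mm=tuple(d["to_xy_mm"]) if d["to_xy_mm"] else None,
                    attempts=d["attempts"],
                    success=d["success"],
                )
            )
    return events


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
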