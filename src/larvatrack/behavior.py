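"""Per-frame run/turn classification and conversion to labeled segments.

A frame is a turn candidate when the centrally smoothed heading rate or the
body bend exceeds an onset threshold; candidates are expanded in both
directions (hysteresis) while the signals stay above relaxed thresholds.
Labels are a pure, time-symmetric function of the windowed series: the cues
are path bends and head swings judged with context from frames both before
and after, so reversing the time axis of the input reverses the label
sequence exactly.  Thresholds are deliberate, config-exposed substitutes
for a learned state classifier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import boxcar, circmean_deg, wrap_deg

STATE_RUN = 0
STATE_TURN = 1


def heading_rate(heading_deg: np.ndarray, frame_rate_hz: float, smooth_window: int) -> np.ndarray:
    """Smoothed heading rate (deg/s) from an unwrapped, boxcar-filtered heading."""
    h = np.asarray(heading_deg, dtype=float)
    nan = np.isnan(h)
    if nan.any():
        # fill gaps by nearest valid sample so the unwrap stays sane
        idx = np.arange(len(h))
        if (~nan).sum() == 0:
            return np.full_like(h, np.nan)
        h = np.interp(idx, idx[~nan], h[~nan])
    unwrapped = np.degrees(np.unwrap(np.radians(h)))
    smoothed = boxcar(unwrapped, smooth_window)
    rate = np.gradient(smoothed) * frame_rate_hz
    if nan.any():
        rate[nan] = np.nan
    return rate


def classify_states(
    heading_deg: np.ndarray,
    frame_rate_hz: float,
    bend_deg: np.ndarray | None = None,
    bend_on_deg: float = 30.0,
    bend_off_deg: float = 15.0,
    heading_rate_on_deg_s: float = 20.0,
    smooth_window: int = 11,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame run/turn labels with bidirectional hysteresis.

    ``bend_deg`` is optional (heading-only mode).  Frames marked invalid
    (e.g. interpolated across a robot manipulation) are never candidates and
    default to run.  Raises on tracks shorter than ``smooth_window``.
    """
    h = np.asarray(heading_deg, dtype=float)
    T = len(h)
    if T < smooth_window:
        raise ValueError(f"track length {T} shorter than smooth_window {smooth_window}")
    rate = heading_rate(h, frame_rate_hz, smooth_window)
    with np.errstate(invalid="ignore"):
        cand = np.abs(rate) >= heading_rate_on_deg_s
        relax = np.abs(rate) >= heading_rate_on_deg_s / 2.0
    if bend_deg is not None:
        b = boxcar(np.nan_to_num(np.asarray(bend_deg, dtype=float)), smooth_window)
        cand |= b >= bend_on_deg
        relax |= b >= bend_off_deg
    if valid is not None:
        bad = ~np.asarray(valid, bool)
        cand &= ~bad
        relax &= ~bad
    # expand candidates bidirectionally through the relaxed mask
    lab, n = ndimage.label(relax | cand)
    keep = np.unique(lab[cand])
    keep = keep[keep > 0]
    turn = np.isin(lab, keep)
    return np.where(turn, STATE_TURN, STATE_RUN).astype(np.int8)


@dataclass
class BehaviorSegment:
    animal_id: int
    state: str  # run | turn
    start_frame: int
    end_frame: int  # inclusive
    direction: str | None = None  # left | right (turns only)
    turn_size_deg: float | None = None


def segment_behaviors(
    labels: np.ndarray,
    heading_deg: np.ndarray,
    frame_rate_hz: float,
    animal_id: int = 0,
    flank_s: float = 1.0,
) -> pd.DataFrame:
    """Maximal constant-state intervals with turn direction and size.

    Turn size is the absolute wrapped difference between the circular mean
    heading over the 1 s after the turn and the 1 s before it; the turn is
    ``left`` when that difference is counter-clockwise (positive in y-up
    coordinates), with the probability-zero 180 deg tie broken as left.
    Turns clipped by the track boundary keep their segment but have
    direction/size missing.
    """
    labels = np.asarray(labels)
    h = np.asarray(heading_deg, dtype=float)
    T = len(labels)
    if T == 0:
        return pd.DataFrame(
            columns=["animal_id", "state", "start_frame", "end_frame", "direction", "turn_size_deg"]
        )
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds - 1, [T - 1]])
    flank = max(1, int(round(flank_s * frame_rate_hz)))
    rows = []
    for s, e in zip(starts, ends):
        state = "turn" if labels[s] == STATE_TURN else "run"
        direction = None
        size = None
        if state == "turn":
            if s - flank >= 0 and e + flank < T:
                before = circmean_deg(h[s - flank : s])
                after = circmean_deg(h[e + 1 : e + 1 + flank])
                d = wrap_deg(after - before)
                if not np.isnan(d):
                    size = abs(float(d))
                    direction = "left" if d > 0 or d == 180.0 else "right"
        rows.append((animal_id, state, int(s), int(e), direction, size))
    df = pd.DataFrame(
        rows, columns=["animal_id", "state", "start_frame", "end_frame", "direction", "turn_size_deg"]
    )
    return df.astype({"turn_size_deg": float, "direction": "string"})
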