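"""Derived behavioral statistics: kinematics, turn statistics, navigation
index, peri-event transients, trajectory stitching, population summaries and
speed/turn-rate correlation.

The navigation index NI = <v_x>/<v> is the mean velocity component along
the (warm) gradient axis normalized by the mean speed: +1 for crawling
straight up the gradient, -1 straight down, 0 perpendicular.  It is the
ratio of means, not the mean of per-frame ratios, and frames slower than
``v_min`` are excluded from both means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import boxcar, wrap_deg


@dataclass
class FeatureSeries:
    """Per-frame kinematics of one animal."""

    frame_rate_hz: float
    speed_mm_s: np.ndarray
    heading_deg: np.ndarray
    curvature_per_mm: np.ndarray
    valid: np.ndarray  # frames usable for summary statistics


def kinematics(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    frame_rate_hz: float,
    smooth_window: int = 11,
    v_min: float = 0.05,
    exclude: np.ndarray | None = None,
) -> FeatureSeries:
    """Speed, heading and path curvature from a position series.

    Central-difference velocities are boxcar-smoothed.  Curvature is
    |d(heading)/ds| along the path and is missing where speed < ``v_min``.
    Frames in ``exclude`` (interpolated/contact) are invalidated together
    with a ``smooth_window`` margin around them, so manipulation jumps never
    leak into summaries.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    T = len(x)
    if T < smooth_window:
        raise ValueError(f"track length {T} shorter than smooth_window {smooth_window}")
    dt = 1.0 / frame_rate_hz
    # smooth the central-difference velocity (not the positions): identical in
    # the series interior, but unbiased at the track ends for uniform motion
    vx = boxcar(np.gradient(x) / dt, smooth_window)
    vy = boxcar(np.gradient(y) / dt, smooth_window)
    speed = np.hypot(vx, vy)
    heading = np.degrees(np.arctan2(vy, vx))

    dh = np.abs(wrap_deg(np.diff(heading, append=heading[-1:])))
    ds = speed * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.radians(dh) / ds
    curvature[speed < v_min] = np.nan

    valid = np.ones(T, dtype=bool)
    if exclude is not None:
        bad = ndimage.binary_dilation(np.asarray(exclude, bool), iterations=smooth_window)
        valid &= ~bad
        speed = speed.copy()
        heading = heading.copy()
        speed[bad] = np.nan
        heading[bad] = np.nan
        curvature[bad] = np.nan
    return FeatureSeries(frame_rate_hz, speed, heading, curvature, valid)


@dataclass
class TurnSummary:
    n_left: int
    n_right: int
    n_total: int
    handedness: float | None  # (N_left - N_right)/N_total; None when no turns
    rate_per_min: float  # turns initiated per minute of track time
    rate_per_run_min: float  # turns per minute of run time (Poisson-rate estimate)


def turn_statistics(
    segments: pd.DataFrame,
    n_frames: int,
    frame_rate_hz: float,
    window_min: float = 10.0,
) -> tuple[pd.DataFrame, TurnSummary]:
    """Sliding-window turn rate, turn-size series and handedness.

    Handedness (N_left - N_right)/N_total is undefined (None), not 0, when
    there are no directed turns.
    """
    turns = segments[segments["state"] == "turn"]
    n_total = len(turns)
    n_left = int((turns["direction"] == "left").sum())
    n_right = int((turns["direction"] == "right").sum())
    n_directed = n_left + n_right
    handedness = (n_left - n_right) / n_directed if n_directed > 0 else None

    duration_min = n_frames / frame_rate_hz / 60.0
    run_frames = (
        segments.loc[segments["state"] == "run", "end_frame"]
        - segments.loc[segments["state"] == "run", "start_frame"]
        + 1
    ).sum()
    run_min = run_frames / frame_rate_hz / 60.0
    summary = TurnSummary(
        n_left=n_left,
        n_right=n_right,
        n_total=n_total,
        handedness=handedness,
        rate_per_min=n_total / duration_min if duration_min > 0 else float("nan"),
        rate_per_run_min=n_total / run_min if run_min > 0 else float("nan"),
    )

    win_frames = max(1, int(round(window_min * 60.0 * frame_rate_hz)))
    starts = np.arange(0, n_frames, win_frames)
    onset = turns["start_frame"].to_numpy()
    sizes = turns["turn_size_deg"].to_numpy(dtype=float)
    rows = []
    for s in starts:
        e = min(s + win_frames, n_frames)
        in_win = (onset >= s) & (onset < e)
        mins = (e - s) / frame_rate_hz / 60.0
        win_sizes = sizes[in_win]
        win_sizes = win_sizes[np.isfinite(win_sizes)]
        rows.append(
            (
                (s + e) / 2.0 / frame_rate_hz,
                int(in_win.sum()),
                in_win.sum() / mins if mins > 0 else np.nan,
                float(win_sizes.mean()) if win_sizes.size else np.nan,
            )
        )
    series = pd.DataFrame(rows, columns=["time_s", "n_turns", "turn_rate_per_min", "mean_turn_size_deg"])
    return series, summary


@dataclass
class NavigationResult:
    ni: float  # overall <v_x>/<v>
    vx_mean_mm_s: float
    speed_mean_mm_s: float
    windows: pd.DataFrame  # time_s, ni per window


def navigation_index(
    speed_mm_s: np.ndarray,
    heading_deg: np.ndarray,
    frame_rate_hz: float,
    axis_deg: float = 0.0,
    window_min: float = 10.0,
    v_min: float = 0.05,
    run_mask: np.ndarray | None = None,
) -> NavigationResult:
    """Navigation index <v_x>/<v> along the gradient axis.

    ``run_mask`` optionally restricts the means to run frames.  NI is
    missing (NaN) when no frame clears ``v_min``.
    """
    speed = np.asarray(speed_mm_s, dtype=float)
    heading = np.asarray(heading_deg, dtype=float)
    with np.errstate(invalid="ignore"):
        ok = (speed >= v_min) & ~np.isnan(heading)
    if run_mask is not None:
        ok &= np.asarray(run_mask, bool)
    vx = speed * np.cos(np.radians(heading - axis_deg))

    def _ni(sel: np.ndarray) -> tuple[float, float, float]:
        if not sel.any():
            return float("nan"), float("nan"), float("nan")
        vbar = float(speed[sel].mean())
        vxbar = float(vx[sel].mean())
        return (vxbar / vbar if vbar > 0 else float("nan")), vxbar, vbar

    ni_all, vx_mean, v_mean = _ni(ok)
    win = max(1, int(round(window_min * 60.0 * frame_rate_hz)))
    rows = []
    for s in range(0, len(speed), win):
        e = min(s + win, len(speed))
        sel = np.zeros_like(ok)
        sel[s:e] = ok[s:e]
        ni_w, _, _ = _ni(sel)
        rows.append(((s + e) / 2.0 / frame_rate_hz, ni_w))
    return NavigationResult(
        ni=ni_all,
        vx_mean_mm_s=vx_mean,
        speed_mean_mm_s=v_mean,
        windows=pd.DataFrame(rows, columns=["time_s", "ni"]),
    )


@dataclass
class PeriEventResult:
    n_events: int
    n_skipped: int
    time_s: np.ndarray  # relative to event, [-window, +window)
    mean: np.ndarray
    sd: np.ndarray
    minute_p: np.ndarray  # one p-value per post-event minute
    returns_to_baseline: bool


def peri_event_average(
    speed_mm_s: np.ndarray,
    frame_rate_hz: float,
    event_frames,
    window_min: float = 5.0,
    valid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> PeriEventResult:
    """Event-aligned speed average with per-minute transient tests.

    Each post-event minute is compared (two-sample t-test on per-event
    minute means) against the pooled pre-event minutes.  Events without a
    full window on both sides are skipped and counted.
    """
    v = np.asarray(speed_mm_s, dtype=float)
    if valid is not None:
        v = np.where(np.asarray(valid, bool), v, np.nan)
    T = len(v)
    w = int(round(window_min * 60.0 * frame_rate_hz))
    per_min = int(round(60.0 * frame_rate_hz))
    n_min = int(window_min)
    aligned = []
    n_skipped = 0
    for f in np.atleast_1d(np.asarray(event_frames, dtype=int)):
        if f - w < 0 or f + w > T:
            n_skipped += 1
            continue
        aligned.append(v[f - w : f + w])
    if not aligned:
        return PeriEventResult(
            0, n_skipped, np.array([]), np.array([]), np.array([]), np.array([]), True
        )
    A = np.vstack(aligned)  # (events, 2w)
    mean = np.nanmean(A, axis=0)
    sd = np.nanstd(A, axis=0)
    time = (np.arange(2 * w) - w) / frame_rate_hz

    # per-event minute means vs the pooled pre-event minutes; with a single
    # event there is no across-event variance, so fall back to frame samples
    if len(A) >= 2:
        pre = np.nanmean(A[:, :w].reshape(len(A), n_min, per_min), axis=2).ravel()
        post = [np.nanmean(A[:, w:].reshape(len(A), n_min, per_min), axis=2)[:, m] for m in range(n_min)]
    else:
        pre = A[0, :w]
        post = [A[0, w + m * per_min : w + (m + 1) * per_min] for m in range(n_min)]
    pvals = np.empty(n_min)
    for m in range(n_min):
        res = stats.ttest_ind(post[m], pre, equal_var=False, nan_policy="omit")
        pvals[m] = res.pvalue
    returns = bool(pvals[-1] >= alpha)
    return PeriEventResult(len(A), n_skipped, time, mean, sd, pvals, returns)


def stitch_trajectory(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    jumps: list[tuple[int, tuple[float, float], tuple[float, float]]],
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list[int]]:
    """Stitch a trajectory across transport events into a continuous path.

    ``jumps`` are (frame, from_xy, to_xy) triples: from ``frame`` onward the
    path is rigidly translated so the post-drop-off sub-path starts at the
    pre-pick-up end point.  Returns (x, y, path_length_m, skipped_jump
    frames); path length sums displacements over non-excluded frames, so
    the manipulation displacement never contributes.
    """
    x = np.array(x_mm, dtype=float)
    y = np.array(y_mm, dtype=float)
    skipped: list[int] = []
    for frame, from_xy, to_xy in sorted(jumps, key=lambda j: j[0]):
        if from_xy is None or to_xy is None:
            skipped.append(int(frame))
            continue
        dx = from_xy[0] - to_xy[0]
        dy = from_xy[1] - to_xy[1]
        x[frame:] += dx
        y[frame:] += dy
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    if exclude is not None:
        bad = np.asarray(exclude, bool)
        step = step[~(bad[1:] | bad[:-1])]
    return x, y, float(np.nansum(step)) / 1000.0, skipped


def binned_population_summary(
    values_by_animal: dict[int, np.ndarray],
    frame_rate_hz: float,
    bin_min: float = 10.0,
) -> pd.DataFrame:
    """Time-binned across-animal mean and SD of within-animal bin means.

    The animal, not the frame, is the statistical unit.  Bins with fewer
    than 2 contributing animals get NaN SD; empty bins get NaN mean.
    """
    win = max(1, int(round(bin_min * 60.0 * frame_rate_hz)))
    T = max(len(v) for v in values_by_animal.values())
    starts = np.arange(0, T, win)
    rows = []
    for s in starts:
        e = min(s + win, T)
        per_animal = []
        for v in values_by_animal.values():
            seg = np.asarray(v[s:e], dtype=float)
            if seg.size and not np.all(np.isnan(seg)):
                per_animal.append(np.nanmean(seg))
        if per_animal:
            mean = float(np.mean(per_animal))
            sd = float(np.std(per_animal, ddof=1)) if len(per_animal) >= 2 else float("nan")
        else:
            mean, sd = float("nan"), float("nan")
        rows.append(((s + e) / 2.0 / frame_rate_hz, mean, sd, len(per_animal)))
    return pd.DataFrame(rows, columns=["time_s", "mean", "sd", "n_animals"])


def decline_slope(summary: pd.DataFrame, t_max_s: float = 3600.0) -> float:
    """Linear slope (units of value per second) of the binned mean over the
    first ``t_max_s`` of the experiment — the activity-decline estimate."""
    sel = summary[(summary["time_s"] <= t_max_s) & summary["mean"].notna()]
    if len(sel) < 2:
        return float("nan")
    res = stats.linregress(sel["time_s"], sel["mean"])
    return float(res.slope)


@dataclass
class CorrelationResult:
    r_population: float
    r_individual_mean: float
    r_individual_sd: float
    r_per_animal: dict[int, float] = field(default_factory=dict)


def speed_turnrate_correlation(
    speed_bins_by_animal: dict[int, np.ndarray],
    turnrate_bins_by_animal: dict[int, np.ndarray],
) -> CorrelationResult:
    """Pearson correlation between binned speed and turn rate.

    The population coefficient correlates the across-animal mean series; the
    individual coefficients correlate each animal's own series (reported as
    mean +/- SD).  Zero-variance series yield a missing coefficient.
    """
    animals = sorted(set(speed_bins_by_animal) & set(turnrate_bins_by_animal))
    if not animals:
        return CorrelationResult(float("nan"), float("nan"), float("nan"))
    n_bins = min(len(speed_bins_by_animal[a]) for a in animals)
    if n_bins < 10:
        raise ValueError(f"need >= 10 matched bins, got {n_bins}")
    S = np.vstack([np.asarray(speed_bins_by_animal[a][:n_bins], float) for a in animals])
    R = np.vstack([np.asarray(turnrate_bins_by_animal[a][:n_bins], float) for a in animals])

    def _corr(u: np.ndarray, w: np.ndarray) -> float:
        ok = ~(np.isnan(u) | np.isnan(w))
        if ok.sum() < 3 or np.std(u[ok]) == 0 or np.std(w[ok]) == 0:
            return float("nan")
        return float(stats.pearsonr(u[ok], w[ok]).statistic)

    r_pop = _corr(np.nanmean(S, axis=0), np.nanmean(R, axis=0))
    per = {a: _corr(S[i], R[i]) for i, a in enumerate(animals)}
    vals = np.array([r for r in per.values() if not np.isnan(r)])
    return CorrelationResult(
        r_population=r_pop,
        r_individual_mean=float(vals.mean()) if vals.size else float("nan"),
        r_individual_sd=float(vals.std(ddof=1)) if vals.size >= 2 else float("nan"),
        r_per_animal=per,
    )
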