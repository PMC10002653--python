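"""Agent-based simulator of larva crawling and the transport-robot controller.

Each larva performs a modified 2D random walk: forward runs at a slowly
declining speed with Gaussian heading diffusion, interrupted by Poisson
turn events that reorient the heading over a short turn bout with
near-zero translation.  Under a thermal gradient, the turn rate is
modulated by the heading relative to the warm axis (klinokinesis): turns
are initiated more often while crawling toward the cold side, which biases
net displacement toward warmth without any directional turn bias.

A stochastic controller emulates the closed-loop transport robot: when an
animal enters the arena's edge margin it is picked up (Bernoulli retries
with calibration perturbation after repeated failures) and dropped off at
the arena center; camera frames during the manipulation are dropped.

Every simulation returns full ground truth (positions, headings, body
endpoints, per-frame run/turn labels, turn events, robot events, dropped
frames) so each downstream analysis stage can be validated exactly.

Random streams: one seeded generator per animal plus one for the
controller and one for placement, so adding animals does not perturb
existing trajectories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArenaConfig, ControllerParams, SimParams, ThermalField

MODE_RUN, MODE_TURN, MODE_MANIP, MODE_FEED = 0, 1, 2, 3
MODE_NAMES = {MODE_RUN: "run", MODE_TURN: "turn", MODE_MANIP: "run", MODE_FEED: "run"}

_CTRL_STREAM = 999_983
_PLACE_STREAM = 500_009


@dataclass
class RobotEvent:
    """One robot interaction: pick-up, drop-off, feed or rinse."""

    time_s: float
    frame: int
    animal_id: int
    type: str  # pickup | dropoff | feed | rinse
    from_xy_mm: tuple[float, float] | None
    to_xy_mm: tuple[float, float] | None
    attempts: int
    success: bool

    def to_json(self) -> dict:
        return {
            "time_s": self.time_s,
            "frame": self.frame,
            "animal_id": self.animal_id,
            "type": self.type,
            "from_xy_mm": list(self.from_xy_mm) if self.from_xy_mm is not None else None,
            "to_xy_mm": list(self.to_xy_mm) if self.to_xy_mm is not None else None,
            "attempts": self.attempts,
            "success": self.success,
        }


@dataclass
class GroundTruth:
    """Per-frame, per-animal ground truth of a simulated experiment."""

    arena: ArenaConfig
    params: SimParams
    thermal: ThermalField | None
    n_frames: int
    n_animals: int
    positions: np.ndarray  # (T, A, 2) mm
    heading_deg: np.ndarray  # (T, A)
    mode: np.ndarray  # (T, A) int8, MODE_* codes
    bend_deg: np.ndarray  # (T, A)
    bend_dir: np.ndarray  # (T, A) int8, +1 = bend to the left of heading
    head_mm: np.ndarray  # (T, A, 2)
    tail_mm: np.ndarray  # (T, A, 2)
    turn_events: pd.DataFrame  # animal_id, start_frame, end_frame, direction, size_deg
    events: list[RobotEvent] = field(default_factory=list)
    dropped: np.ndarray = None  # (T,) bool

    @property
    def frame_rate_hz(self) -> float:
        return self.arena.frame_rate_hz

    def to_table(self) -> pd.DataFrame:
        """Trajectory table (cli_io format) on the ground-truth fast path.

        Frames during robot manipulation or global camera occlusion are
        flagged ``interpolated`` — they are exactly the frames the tracking
        stage would have to bridge.
        """
        from .io import TRAJECTORY_COLUMNS

        T, A = self.n_frames, self.n_animals
        rate = self.arena.frame_rate_hz
        frames = np.arange(T)
        rows = []
        manip_events = [
            (i, ev) for i, ev in enumerate(self.events) if ev.type in ("pickup", "dropoff")
        ]
        for a in range(A):
            interp = self.dropped | (self.mode[:, a] >= MODE_MANIP)
            df = pd.DataFrame(
                {
                    "time_s": frames / rate,
                    "frame": frames,
                    "animal_id": a,
                    "x_mm": self.positions[:, a, 0],
                    "y_mm": self.positions[:, a, 1],
                    "head_x_mm": self.head_mm[:, a, 0],
                    "head_y_mm": self.head_mm[:, a, 1],
                    "tail_x_mm": self.tail_mm[:, a, 0],
                    "tail_y_mm": self.tail_mm[:, a, 1],
                    "bend_deg": self.bend_deg[:, a],
                    "state": np.where(self.mode[:, a] == MODE_TURN, "turn", "run"),
                    "interpolated": interp,
                    "contact": False,
                    "event_id": "",
                }
            )
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        # reference robot events from the frames they occlude
        for i, ev in manip_events:
            sel = (out["animal_id"] == ev.animal_id) & (out["frame"] == ev.frame)
            out.loc[sel, "event_id"] = str(i)
        return out[TRAJECTORY_COLUMNS]


def body_endpoints(
    x: float, y: float, heading_deg: float, bend_deg: float, bend_dir: int, length_mm: float
) -> tuple[float, float, float, float]:
    """Head and tail of a body bent at the midpoint, centered on its centroid.

    The body is two chords of length L/2 meeting at a joint; the head chord
    points along ``heading + dir*bend/2`` and the tail chord along
    ``heading - dir*bend/2``.  The joint is placed so that the continuous
    centroid of the two chords coincides with (x, y).
    """
    hh = math.radians(heading_deg + bend_dir * bend_deg / 2.0)
    ht = math.radians(heading_deg - bend_dir * bend_deg / 2.0)
    uhx, uhy = math.cos(hh), math.sin(hh)
    utx, uty = math.cos(ht), math.sin(ht)
    L8 = length_mm / 8.0
    jx = x - L8 * (uhx - utx)
    jy = y - L8 * (uhy - uty)
    L2 = length_mm / 2.0
    return jx + L2 * uhx, jy + L2 * uhy, jx - L2 * utx, jy - L2 * uty


def body_midline(
    x: float,
    y: float,
    heading_deg: float,
    bend_deg: float,
    bend_dir: int,
    length_mm: float,
    n_points: int = 11,
) -> np.ndarray:
    """Midline polyline head->tail, (n_points, 2) mm, consistent with
    :func:`body_endpoints`."""
    hx, hy, tx, ty = body_endpoints(x, y, heading_deg, bend_deg, bend_dir, length_mm)
    hh = math.radians(heading_deg + bend_dir * bend_deg / 2.0)
    ht = math.radians(heading_deg - bend_dir * bend_deg / 2.0)
    L8 = length_mm / 8.0
    jx = x - L8 * (math.cos(hh) - math.cos(ht))
    jy = y - L8 * (math.sin(hh) - math.sin(ht))
    half = n_points // 2
    s_head = np.linspace(1.0, 0.0, half + 1)
    s_tail = np.linspace(0.0, 1.0, half + 1)[1:]
    pts_head = np.column_stack([jx + s_head * (hx - jx), jy + s_head * (hy - jy)])
    pts_tail = np.column_stack([jx + s_tail * (tx - jx), jy + s_tail * (ty - jy)])
    return np.vstack([pts_head, pts_tail])


def draw_turn_size(rng: np.random.Generator, params: SimParams) -> float:
    """Turn magnitude (deg) from a truncated Gaussian via rejection sampling."""
    lo, hi = params.turn_size_min_deg, params.turn_size_max_deg
    while True:
        s = rng.normal(params.turn_size_mean_deg, params.turn_size_sd_deg)
        if lo <= s <= hi:
            return float(s)


def attempt_sequence(
    rng: np.random.Generator,
    p_first: float,
    max_attempts: int,
    perturb_after: int,
    p_boost: float = 0.05,
) -> tuple[int, bool]:
    """Bernoulli retry sequence with calibration perturbation.

    Each attempt succeeds with probability ``p``; after ``perturb_after``
    failures the calibration is perturbed, nudging ``p`` upward by
    ``p_boost`` per subsequent failure.  Returns (attempts used, success).
    """
    p = p_first
    for k in range(1, max_attempts + 1):
        if rng.random() < p:
            return k, True
        if k >= perturb_after:
            p = min(0.99, p + p_boost)
    return max_attempts, False


def simulate_experiment(
    arena: ArenaConfig | None = None,
    thermal: ThermalField | None = None,
    params: SimParams | None = None,
    controller: ControllerParams | None = None,
    n_animals: int = 5,
    duration_s: float = 3600.0,
    seed: int = 0,
) -> GroundTruth:
    """Simulate ``n_animals`` larvae for ``duration_s`` seconds.

    ``controller=None`` disables the robot entirely (animals bounce off the
    walls instead of being transported); passing a :class:`ControllerParams`
    enables edge-triggered pick-up/drop-off and optional scheduled feeding.
    Thermotaxis requires both an enabled ``thermal`` field and
    ``params.thermotaxis_gain > 0``.
    """
    arena = arena or ArenaConfig()
    params = params or SimParams()
    fr = arena.frame_rate_hz
    dt = 1.0 / fr
    T = int(round(duration_s * fr))
    A = int(n_animals)
    side = arena.side_length_mm
    L = params.body_length_mm

    taxis = (
        thermal is not None and thermal.enabled and params.thermotaxis_gain > 0.0
    )
    axis_deg = thermal.axis_deg if thermal is not None else 0.0
    gain = params.thermotaxis_gain
    lam0_s = params.base_turn_rate_per_min / 60.0
    p_turn0 = -math.expm1(-lam0_s * dt)
    diff_step = params.heading_diffusion_deg_rt_s * math.sqrt(dt)
    turn_frames_total = max(1, int(round(params.turn_duration_s * fr)))
    trans_frac = params.turn_translation_frac

    # independent random streams
    animal_rngs = [np.random.default_rng([seed, a]) for a in range(A)]
    ctrl_rng = np.random.default_rng([seed, _CTRL_STREAM])
    place_rngs = [np.random.default_rng([seed, _PLACE_STREAM, a]) for a in range(A)]
    u_turn = [r.random(T) for r in animal_rngs]
    z_head = [r.standard_normal(T) for r in animal_rngs]
    z_bend = [r.standard_normal(T) for r in animal_rngs]

    # output arrays
    pos = np.empty((T, A, 2))
    heading = np.empty((T, A))
    mode_arr = np.zeros((T, A), dtype=np.int8)
    bend_arr = np.empty((T, A))
    bdir_arr = np.ones((T, A), dtype=np.int8)
    head_arr = np.empty((T, A, 2))
    tail_arr = np.empty((T, A, 2))
    dropped = np.zeros(T, dtype=bool)

    # animal state
    cx0, cy0 = arena.center_mm
    xs = [cx0 + r.uniform(-side / 6.0, side / 6.0) for r in place_rngs]
    ys = [cy0 + r.uniform(-side / 6.0, side / 6.0) for r in place_rngs]
    hs = [r.uniform(0.0, 360.0) for r in place_rngs]
    modes = [MODE_RUN] * A
    turn_remaining = [0] * A
    turn_rate = [0.0] * A
    turn_size = [0.0] * A
    turn_dir = [1] * A
    turn_start = [0] * A
    bend_peak = [0.0] * A
    cooldown = [0] * A  # earliest frame at which a failed pickup may retrigger
    feed_until = [-1.0] * A

    events: list[RobotEvent] = []
    turn_rows: list[tuple[int, int, int, str, float]] = []

    # robot state
    busy_until = -1
    carry = -1
    release_frame = -1
    drop_xy = (cx0, cy0)
    next_feed = (
        controller.feed_interval_s
        if controller is not None and controller.feed_interval_s
        else math.inf
    )

    margin = arena.edge_margin_mm
    cos_f, sin_f, rad = math.cos, math.sin, math.radians

    for t in range(T):
        ts = t * dt
        v_t = params.speed_at(ts)
        robot_busy = t < busy_until
        if robot_busy:
            dropped[t] = True

        # drop-off: carried animal reappears at the arena center
        just_released = -1
        if carry >= 0 and t == release_frame:
            a = carry
            xs[a], ys[a] = drop_xy
            hs[a] = float(ctrl_rng.uniform(0.0, 360.0))
            modes[a] = MODE_RUN
            just_released = a
            carry = -1

        for a in range(A):
            if a == just_released:
                # recorded exactly at the drop point; crawling resumes next frame
                mode_arr[t, a] = MODE_RUN
                bend = 0.0
                bd = 1
            elif a == carry:
                # on the nozzle: frozen at pick-up point, off the agar
                mode_arr[t, a] = MODE_MANIP
                bend = 0.0
                bd = 1
            elif ts < feed_until[a]:
                mode_arr[t, a] = MODE_FEED
                bend = abs(2.0 * z_bend[a][t])
                bd = 1 if z_bend[a][t] >= 0 else -1
            elif modes[a] == MODE_TURN:
                hs[a] += turn_rate[a] * dt
                x = xs[a] + trans_frac * v_t * dt * cos_f(rad(hs[a]))
                y = ys[a] + trans_frac * v_t * dt * sin_f(rad(hs[a]))
                xs[a], ys[a], hs[a] = _bounce(x, y, hs[a], side)
                k = turn_frames_total - turn_remaining[a] + 1
                bend = bend_peak[a] * math.sin(math.pi * k / (turn_frames_total + 1))
                bend += abs(2.0 * z_bend[a][t])
                bd = turn_dir[a]
                mode_arr[t, a] = MODE_TURN
                turn_remaining[a] -= 1
            else:  # run
                hs[a] += diff_step * z_head[a][t]
                x = xs[a] + v_t * dt * cos_f(rad(hs[a]))
                y = ys[a] + v_t * dt * sin_f(rad(hs[a]))
                xs[a], ys[a], hs[a] = _bounce(x, y, hs[a], side)
                bend = abs(params.run_bend_noise_deg * z_bend[a][t])
                bd = 1 if z_bend[a][t] >= 0 else -1
                mode_arr[t, a] = MODE_RUN

            bend = min(bend, 179.0)
            pos[t, a, 0] = xs[a]
            pos[t, a, 1] = ys[a]
            heading[t, a] = hs[a]
            bend_arr[t, a] = bend
            bdir_arr[t, a] = bd
            hx, hy, tx, ty = body_endpoints(xs[a], ys[a], hs[a], bend, bd, L)
            head_arr[t, a, 0] = hx
            head_arr[t, a, 1] = hy
            tail_arr[t, a, 0] = tx
            tail_arr[t, a, 1] = ty

            # state transitions take effect at the next frame
            if modes[a] == MODE_TURN and turn_remaining[a] == 0:
                turn_rows.append(
                    (a, turn_start[a], t, "left" if turn_dir[a] > 0 else "right", turn_size[a])
                )
                modes[a] = MODE_RUN
            elif (
                modes[a] == MODE_RUN
                and mode_arr[t, a] == MODE_RUN
                and a != carry
                and ts >= feed_until[a]
            ):
                if taxis:
                    cospsi = cos_f(rad(hs[a] - axis_deg))
                    lam = lam0_s * (1.0 + gain * max(0.0, -cospsi))
                    p_turn = -math.expm1(-lam * dt)
                else:
                    p_turn = p_turn0
                if u_turn[a][t] < p_turn:
                    size = draw_turn_size(animal_rngs[a], params)
                    d = 1 if animal_rngs[a].random() < params.handedness_bias else -1
                    modes[a] = MODE_TURN
                    turn_remaining[a] = turn_frames_total
                    turn_rate[a] = d * size / params.turn_duration_s
                    turn_size[a] = size
                    turn_dir[a] = d
                    turn_start[a] = t + 1
                    bend_peak[a] = max(45.0, min(size, 120.0))

        # scheduled feeding
        if controller is not None and ts >= next_feed:
            for a in range(A):
                if a == carry:
                    continue
                feed_until[a] = ts + controller.feed_duration_s
                events.append(
                    RobotEvent(ts, t, a, "feed", (xs[a], ys[a]), (xs[a], ys[a]), 1, True)
                )
                events.append(
                    RobotEvent(
                        ts + controller.feed_duration_s,
                        t + int(round(controller.feed_duration_s * fr)),
                        a,
                        "rinse",
                        (xs[a], ys[a]),
                        (xs[a], ys[a]),
                        1,
                        True,
                    )
                )
            next_feed += controller.feed_interval_s

        # edge-triggered transport (one manipulation at a time)
        if controller is not None and not robot_busy and carry < 0:
            occ = int(round(controller.occlusion_s * fr))
            for a in range(A):
                if ts < feed_until[a] or t < cooldown[a]:
                    continue
                if min(xs[a], ys[a], side - xs[a], side - ys[a]) < margin:
                    n_up, ok_up = attempt_sequence(
                        ctrl_rng,
                        controller.p_first_pickup,
                        controller.max_attempts,
                        controller.perturb_after,
                        controller.p_boost,
                    )
                    here = (xs[a], ys[a])
                    events.append(RobotEvent(ts, t, a, "pickup", here, None, n_up, ok_up))
                    busy_until = t + occ
                    if ok_up:
                        n_dn, ok_dn = attempt_sequence(
                            ctrl_rng,
                            controller.p_first_dropoff,
                            controller.max_attempts,
                            controller.perturb_after,
                            controller.p_boost,
                        )
                        jit = ctrl_rng.normal(0.0, controller.drop_jitter_mm, 2)
                        target = (
                            min(max(cx0 + jit[0], margin), side - margin),
                            min(max(cy0 + jit[1], margin), side - margin),
                        )
                        events.append(
                            RobotEvent(ts, t, a, "dropoff", here, target, n_dn, ok_dn)
                        )
                        carry = a
                        release_frame = t + occ
                        drop_xy = target
                        if modes[a] == MODE_TURN:
                            # turn aborted by the manipulation
                            turn_rows.append(
                                (
                                    a,
                                    turn_start[a],
                                    t,
                                    "left" if turn_dir[a] > 0 else "right",
                                    turn_size[a],
                                )
                            )
                            modes[a] = MODE_RUN
                            turn_remaining[a] = 0
                    else:
                        cooldown[a] = t + int(round(controller.retrigger_cooldown_s * fr))
                    break

    turn_events = pd.DataFrame(
        turn_rows, columns=["animal_id", "start_frame", "end_frame", "direction", "size_deg"]
    )
    return GroundTruth(
        arena=arena,
        params=params,
        thermal=thermal,
        n_frames=T,
        n_animals=A,
        positions=pos,
        heading_deg=heading,
        mode=mode_arr,
        bend_deg=bend_arr,
        bend_dir=bdir_arr,
        head_mm=head_arr,
        tail_mm=tail_arr,
        turn_events=turn_events,
        events=events,
        dropped=dropped,
    )


def _bounce(x: float, y: float, heading_deg: float, side: float):
    """Reflect a position (and its heading) off the arena walls."""
    h = heading_deg
    if x < 0.0:
        x = -x
        h = 180.0 - h
    elif x > side:
        x = 2.0 * side - x
        h = 180.0 - h
    if y < 0.0:
        y = -y
        h = -h
    elif y > side:
        y = 2.0 * side - y
        h = -h
    # pathological overshoot (should not occur at larval speeds)
    x = min(max(x, 0.0), side)
    y = min(max(y, 0.0), side)
    return x, y, h


def synthetic_speed_series(
    n_frames: int,
    frame_rate_hz: float,
    event_frames,
    baseline_mm_s: float = 0.3,
    noise_sd_mm_s: float = 0.05,
    boost_mm_s: float = 0.1,
    boost_duration_s: float = 90.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Speed series with a transient boost after each event.

    Default noise model: iid Gaussian frame noise around a constant
    baseline, with a ``boost_mm_s`` elevation for ``boost_duration_s``
    after each event — the shape of the post-manipulation transient.
    """
    rng = rng or np.random.default_rng(0)
    v = baseline_mm_s + noise_sd_mm_s * rng.standard_normal(n_frames)
    k = int(round(boost_duration_s * frame_rate_hz))
    for f in np.atleast_1d(np.asarray(event_frames, dtype=int)):
        v[f : min(n_frames, f + k)] += boost_mm_s
    return np.maximum(v, 0.0)
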