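"""Experiment configuration: arena geometry, thermal field, locomotion model.

All spatial quantities are in millimeters in an arena coordinate frame whose
origin is the lower-left corner, x rightward and y upward.  The warm end of
the thermal gradient points along +x by convention.  Pixel coordinates are
0-based, half-open, row-major; conversion to/from mm goes through
``ArenaConfig.pixel_scale_mm`` (see :mod:`larvatrack.geometry`).
"""
from __future__ import annotations

import dataclasses
import hashlib
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path


class OutOfArenaError(ValueError):
    """A position fell outside the arena bounds."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and acquisition parameters of the crawling arena.

    The default arena is a 22 x 22 cm agar gel filmed at 10 Hz by an
    overhead camera; ``pixel_scale_mm`` is chosen so a ~1 mm larva covers
    about 30 pixels.
    """

    side_length_mm: float = 220.0
    frame_rate_hz: float = 10.0
    pixel_scale_mm: float = 0.09
    edge_margin_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.side_length_mm <= 0:
            raise ValueError("side_length_mm must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_scale_mm <= 0:
            raise ValueError("pixel_scale_mm must be positive")
        if not (0 < self.edge_margin_mm < self.side_length_mm / 2):
            raise ValueError("edge_margin_mm must be in (0, side_length/2)")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def center_mm(self) -> tuple[float, float]:
        return (self.side_length_mm / 2.0, self.side_length_mm / 2.0)

    @property
    def size_px(self) -> int:
        """Image side length in pixels (square sensor region of interest)."""
        return int(round(self.side_length_mm / self.pixel_scale_mm))

    def contains(self, x_mm: float, y_mm: float) -> bool:
        return 0.0 <= x_mm <= self.side_length_mm and 0.0 <= y_mm <= self.side_length_mm


@dataclass(frozen=True)
class ThermalField:
    """Linear 1D thermal gradient across the arena.

    Temperature is an affine function of the signed distance from the arena
    center along ``axis`` (the warm direction): ``T(p) = center_temp +
    steepness * (p - center) . axis``.  The default gradient is 0.035 degC/mm
    centered at 17 degC, spanning roughly 13 degC to 21 degC across a 220 mm
    arena.
    """

    steepness_c_per_mm: float = 0.035
    center_temp_c: float = 17.0
    axis: tuple[float, float] = (1.0, 0.0)
    enabled: bool = True

    def __post_init__(self) -> None:
        n = math.hypot(*self.axis)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", (self.axis[0] / n, self.axis[1] / n))

    @property
    def axis_deg(self) -> float:
        return math.degrees(math.atan2(self.axis[1], self.axis[0]))


def thermal_field_at(
    thermal: ThermalField, position_mm: tuple[float, float], arena: ArenaConfig
) -> float:
    """Temperature (degC) at a position in the arena.

    Raises :class:`OutOfArenaError` for positions outside the arena. When the
    field is disabled, returns ``center_temp_c`` everywhere.
    """
    x, y = float(position_mm[0]), float(position_mm[1])
    if not arena.contains(x, y):
        raise OutOfArenaError(f"position {(x, y)} outside {arena.side_length_mm} mm arena")
    if not thermal.enabled:
        return thermal.center_temp_c
    cx, cy = arena.center_mm
    s = (x - cx) * thermal.axis[0] + (y - cy) * thermal.axis[1]
    return thermal.center_temp_c + thermal.steepness_c_per_mm * s


# Klinokinetic gain calibrated so that a robot-mediated gradient experiment
# yields a population navigation index of ~0.13, the magnitude of robust
# larval cold avoidance; 0 disables thermotaxis.
CALIBRATED_THERMOTAXIS_GAIN = 1.25


@dataclass
class SimParams:
    """Generative parameters of the run-and-turn locomotion model.

    Larvae crawl in alternating runs (forward peristalsis with slow heading
    diffusion) and turns (rapid reorientation with near-zero translation).
    Crawl speed declines linearly at ``speed_decline_mm_s2`` for the first
    ``decline_duration_s`` of the experiment and then plateaus; it is floored
    at ``min_speed_mm_s``.  Turns are initiated as a Poisson process with
    rate ``base_turn_rate_per_min``, modulated by heading relative to the
    warm axis when ``thermotaxis_gain > 0`` (klinokinesis: the rate is
    elevated when crawling toward the cold side).
    """

    base_speed_mm_s: float = 0.5
    speed_decline_mm_s2: float = -6.9e-5
    decline_duration_s: float = 3600.0
    min_speed_mm_s: float = 0.1
    base_turn_rate_per_min: float = 2.0
    turn_size_mean_deg: float = 60.0
    turn_size_sd_deg: float = 30.0
    turn_size_min_deg: float = 20.0
    turn_size_max_deg: float = 180.0
    handedness_bias: float = 0.5
    heading_diffusion_deg_rt_s: float = 5.0
    thermotaxis_gain: float = 0.0
    turn_duration_s: float = 2.0
    turn_translation_frac: float = 0.1
    body_length_mm: float = 1.0
    run_bend_noise_deg: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.handedness_bias <= 1.0):
            raise ValueError("handedness_bias must be in [0, 1]")
        if self.min_speed_mm_s <= 0:
            raise ValueError("min_speed_mm_s must be positive")
        if self.thermotaxis_gain < 0:
            raise ValueError("thermotaxis_gain must be >= 0")
        if not (0 < self.turn_size_min_deg <= self.turn_size_max_deg <= 180.0):
            raise ValueError("turn size bounds must satisfy 0 < min <= max <= 180")

    def speed_at(self, t_s: float) -> float:
        """Crawl speed (mm/s) at experiment time ``t_s`` (piecewise-linear decline)."""
        v = self.base_speed_mm_s + self.speed_decline_mm_s2 * min(t_s, self.decline_duration_s)
        return max(self.min_speed_mm_s, v)


@dataclass
class ControllerParams:
    """Stochastic model of the transport-robot feedback controller.

    When a larva enters the edge margin the robot attempts a pick-up
    (Bernoulli per attempt, first-try probability ``p_first_pickup``); after
    ``perturb_after`` consecutive failures the calibration is perturbed and
    the per-attempt probability is nudged upward by ``p_boost``.  A
    successful pick-up is followed by a drop-off attempt sequence at the
    arena center.  Frames during a manipulation are dropped (camera
    occluded by the arm) for ``occlusion_s`` seconds.  If
    ``feed_interval_s`` is set, all animals are paused and fed on that
    schedule for ``feed_duration_s``.
    """

    p_first_pickup: float = 0.90
    p_first_dropoff: float = 0.95
    max_attempts: int = 10
    perturb_after: int = 3
    p_boost: float = 0.05
    occlusion_s: float = 10.0
    retrigger_cooldown_s: float = 30.0
    drop_jitter_mm: float = 2.0
    feed_interval_s: float | None = None
    feed_duration_s: float = 60.0


@dataclass
class RenderParams:
    """Frame-renderer parameters.

    Each larva is drawn as an elongated bright cluster (a stadium around the
    bent body midline) of roughly ``target_area_px`` uniformly bright pixels
    on a dark background.
    """

    intensity: int = 220
    body_width_mm: float = 0.22
    noise_sd: float = 0.0
    target_area_px: float = 30.0


@dataclass
class AnalysisParams:
    """Thresholds for tracking, posture and behavioral-state classification."""

    detect_threshold: int = 100
    min_area_px: int = 8
    max_area_px: int = 400
    gating_radius_mm: float = 3.0
    max_gap_frames: int = 150
    merge_area_factor: float = 1.6
    crop_size_px: int = 64
    midline_points: int = 11
    flip_penalty_factor: float = 3.0
    v_min_mm_s: float = 0.05
    smooth_window_frames: int = 11
    bend_on_deg: float = 30.0
    bend_off_deg: float = 15.0
    heading_rate_on_deg_s: float = 20.0
    bin_min: float = 10.0
    ni_window_min: float = 10.0
    runs_only_ni: bool = False


_SECTIONS: dict[str, type] = {
    "arena": ArenaConfig,
    "thermal": ThermalField,
    "locomotion": SimParams,
    "controller": ControllerParams,
    "render": RenderParams,
    "analysis": AnalysisParams,
}


@dataclass
class RunConfig:
    """Full configuration of a simulated experiment plus its analysis."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    thermal: ThermalField = field(default_factory=lambda: ThermalField(enabled=False))
    locomotion: SimParams = field(default_factory=SimParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    render: RenderParams = field(default_factory=RenderParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    n_animals: int = 5
    duration_s: float = 3600.0
    seed: int = 0
    render_frames: bool = False
    use_robot: bool = True
    outdir: str = "larvatrack_out"

    # -- TOML round trip ---------------------------------------------------

    def to_toml(self) -> str:
        lines: list[str] = ["[run]"]
        for key in ("n_animals", "duration_s", "seed", "render_frames", "use_robot", "outdir"):
            val = getattr(self, key)
            lines.append(f"{key} = {_toml_value(val)}")
        for section, cls in _SECTIONS.items():
            lines.append("")
            lines.append(f"[{section}]")
            obj = getattr(self, _SECTION_ATTR[section])
            for f in fields(cls):
                val = getattr(obj, f.name)
                if val is None:
                    continue  # TOML has no null; absent key means None default
                lines.append(f"{f.name} = {_toml_value(val)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text_or_path: str | Path) -> "RunConfig":
        s = str(text_or_path)
        if isinstance(text_or_path, Path) or ("\n" not in s and "=" not in s):
            text = Path(text_or_path).read_text()
        else:
            text = s
        data = tomllib.loads(text)
        kwargs: dict = {}
        run = data.get("run", {})
        for key in ("n_animals", "duration_s", "seed", "render_frames", "use_robot", "outdir"):
            if key in run:
                kwargs[key] = run[key]
        for section, scls in _SECTIONS.items():
            if section in data:
                sect = dict(data[section])
                if "axis" in sect:
                    sect["axis"] = tuple(sect["axis"])
                kwargs[_SECTION_ATTR[section]] = scls(**sect)
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]


_SECTION_ATTR = {
    "arena": "arena",
    "thermal": "thermal",
    "locomotion": "locomotion",
    "controller": "controller",
    "render": "render",
    "analysis": "analysis",
}


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")
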