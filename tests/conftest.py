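import numpy as np
import pytest
from hypothesis import settings

from larvatrack.config import ArenaConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_arena() -> ArenaConfig:
    """60 mm arena: small enough to render quickly, big enough to roam."""
    return ArenaConfig(side_length_mm=60.0, edge_margin_mm=10.0)


@pytest.fixture(scope="session")
def default_arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def straight_track(
    n_frames: int = 600,
    speed_mm_s: float = 0.3,
    heading_deg: float = 0.0,
    frame_rate_hz: float = 10.0,
    start=(50.0, 50.0),
):
    """Constant-velocity position series (x, y) in mm."""
    t = np.arange(n_frames) / frame_rate_hz
    hx = np.cos(np.radians(heading_deg))
    hy = np.sin(np.radians(heading_deg))
    return start[0] + speed_mm_s * t * hx, start[1] + speed_mm_s * t * hy


def turny_track(
    turn_sizes_deg,
    run_s: float = 30.0,
    speed_mm_s: float = 0.3,
    turn_rate_deg_s: float = 90.0,
    frame_rate_hz: float = 10.0,
    start=(60.0, 60.0),
):
    """Piecewise path: straight runs separated by constant-rate heading sweeps.

    Positive turn sizes are counter-clockwise (left) in y-up coordinates.
    Returns (x, y, heading series, list of (start_frame, end_frame) turns).
    """
    dt = 1.0 / frame_rate_hz
    run_frames = int(round(run_s * frame_rate_hz))
    headings = []
    turn_bounds = []
    h = 0.0
    for size in list(turn_sizes_deg) + [None]:
        headings.extend([h] * run_frames)
        if size is None:
            break
        n_turn = max(1, int(round(abs(size) / turn_rate_deg_s * frame_rate_hz)))
        turn_bounds.append((len(headings), len(headings) + n_turn - 1))
        step = size / n_turn
        for _ in range(n_turn):
            h += step
            headings.append(h)
    headings = np.asarray(headings, dtype=float)
    x = start[0] + np.concatenate(
        [[0.0], np.cumsum(speed_mm_s * dt * np.cos(np.radians(headings[:-1])))]
    )
    y = start[1] + np.concatenate(
        [[0.0], np.cumsum(speed_mm_s * dt * np.sin(np.radians(headings[:-1])))]
    )
    return x, y, headings, turn_bounds
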