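"""Sparse-pixel frame renderer.

Renders each larva as an elongated, uniformly bright cluster of ~30 pixels
on a dark 8-bit background: a stadium of configurable width around the bent
body midline.  Dropped frames (robot-arm occlusion) are emitted fully dark.
Overlapping animals are rendered merged — the tracker has to cope.
"""
from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import tifffile

from .config import ArenaConfig, RenderParams
from .geometry import mm_to_px
from .simulate import MODE_MANIP, GroundTruth, body_midline

_DENSE_POINTS = 40


def draw_larva(
    image: np.ndarray,
    x_mm: float,
    y_mm: float,
    heading_deg: float,
    bend_deg: float,
    bend_dir: int,
    body_length_mm: float,
    arena: ArenaConfig,
    render: RenderParams,
) -> None:
    """Draw one larva in place on an 8-bit image."""
    mid = body_midline(
        x_mm, y_mm, heading_deg, bend_deg, bend_dir, body_length_mm, n_points=_DENSE_POINTS + 1
    )
    h = image.shape[0]
    s = arena.pixel_scale_mm
    rows, cols = mm_to_px(mid[:, 0], mid[:, 1], s, h)
    half_w = 0.5 * render.body_width_mm / s
    r0 = max(0, int(np.floor(rows.min() - half_w - 1)))
    r1 = min(image.shape[0], int(np.ceil(rows.max() + half_w + 2)))
    c0 = max(0, int(np.floor(cols.min() - half_w - 1)))
    c1 = min(image.shape[1], int(np.ceil(cols.max() + half_w + 2)))
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = ((rr[..., None] - rows) ** 2 + (cc[..., None] - cols) ** 2).min(axis=-1)
    mask = d2 <= half_w * half_w
    sub = image[r0:r1, c0:c1]
    sub[mask] = render.intensity


def iter_frames(
    gt: GroundTruth,
    render: RenderParams | None = None,
    frames: Iterable[int] | None = None,
    noise_seed: int = 0,
) -> Iterator[np.ndarray]:
    """Yield rendered 8-bit grayscale frames for a simulated experiment.

    Frames flagged in ``gt.dropped`` are yielded fully dark.  Animals being
    carried by the robot are not on the agar and are not drawn.
    """
    render = render or RenderParams()
    arena = gt.arena
    n = arena.size_px
    rng = np.random.default_rng([noise_seed, 77_003]) if render.noise_sd > 0 else None
    frame_ids = range(gt.n_frames) if frames is None else frames
    L = gt.params.body_length_mm
    for t in frame_ids:
        img = np.zeros((n, n), dtype=np.uint8)
        if gt.dropped[t]:
            yield img
            continue
        for a in range(gt.n_animals):
            if gt.mode[t, a] == MODE_MANIP:
                continue
            draw_larva(
                img,
                gt.positions[t, a, 0],
                gt.positions[t, a, 1],
                gt.heading_deg[t, a],
                gt.bend_deg[t, a],
                int(gt.bend_dir[t, a]),
                L,
                arena,
                render,
            )
        if rng is not None:
            noise = rng.normal(0.0, render.noise_sd, img.shape)
            img = np.clip(img.astype(np.int16) + noise.astype(np.int16), 0, 255).astype(np.uint8)
        yield img


def render_movie(
    gt: GroundTruth, render: RenderParams | None = None, noise_seed: int = 0
) -> np.ndarray:
    """Render the whole experiment into memory, (T, H, W) uint8."""
    return np.stack(list(iter_frames(gt, render, noise_seed=noise_seed)))


def write_tiff(path, frames: Iterable[np.ndarray]) -> None:
    """Write frames as a multi-page 8-bit grayscale TIFF."""
    with tifffile.TiffWriter(str(path), bigtiff=False) as tw:
        for frame in frames:
            tw.write(frame, contiguous=True, photometric="minisblack")


def read_tiff(path) -> Iterator[np.ndarray]:
    """Iterate pages of a multi-page TIFF as 2D uint8 arrays."""
    with tifffile.TiffFile(str(path)) as tf:
        for page in tf.pages:
            yield page.asarray()
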