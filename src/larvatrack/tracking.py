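"""Identity-preserving multi-animal tracking from frame stacks.

Detections are connected components above an intensity threshold; identities
are maintained by greedy mutual-nearest-neighbour linking inside a gating
radius — adequate for a handful of slow-crawling larvae with a fixed, known
animal count.  Dropped frames (robot occlusion) leave gaps that are bridged
by linear interpolation.  Merged blobs (touching animals) are assigned to
all gated tracks with their centroids frozen at last-known offsets until
separation; those frames are flagged ``contact``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from .config import AnalysisParams, ArenaConfig
from .geometry import px_to_mm


@dataclass
class Detection:
    """One thresholded connected component in one frame."""

    frame: int
    centroid_px: tuple[float, float]  # (row, col), intensity-weighted
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    contour: np.ndarray | None = None  # (k, 2) (row, col) on the boundary


@dataclass
class Track:
    """Per-animal track over the whole movie (pixel coordinates)."""

    animal_id: int
    n_frames: int
    centroid_px: np.ndarray  # (T, 2) (row, col), NaN where unknown
    detected: np.ndarray  # (T,) bool: a detection was assigned this frame
    contact: np.ndarray  # (T,) bool: shared (merged) detection
    interpolated: np.ndarray  # (T,) bool, set by interpolate_gaps
    breaks: list[tuple[int, int]] = field(default_factory=list)  # unfilled gaps

    def centroid_mm(self, pixel_scale_mm: float, height_px: int) -> np.ndarray:
        x, y = px_to_mm(self.centroid_px[:, 0], self.centroid_px[:, 1], pixel_scale_mm, height_px)
        return np.column_stack([x, y])


def detect_blobs(
    frame: np.ndarray,
    threshold: int = 100,
    min_area: int = 8,
    max_area: int = 400,
    frame_index: int = 0,
    with_contours: bool = True,
) -> list[Detection]:
    """Connected components above ``threshold`` with area in [min, max].

    Centroids are intensity-weighted means; contours are traced on the
    component boundary.  Returns an empty list on blank frames.
    """
    mask = frame >= threshold
    if not mask.any():
        return []
    lab = measure.label(mask, connectivity=2)
    out: list[Detection] = []
    for p in measure.regionprops(lab, intensity_image=frame):
        if not (min_area <= p.area <= max_area):
            continue
        contour = None
        if with_contours:
            padded = np.pad(p.image, 1)
            cs = measure.find_contours(padded.astype(float), 0.5)
            if cs:
                c = max(cs, key=len)
                contour = c - 1.0 + np.array([p.bbox[0], p.bbox[1]])
        out.append(
            Detection(
                frame=frame_index,
                centroid_px=(float(p.centroid_weighted[0]), float(p.centroid_weighted[1])),
                area=int(p.area),
                bbox=tuple(p.bbox),
                contour=contour,
            )
        )
    return out


def link_identities(
    detections_by_frame: Sequence[list[Detection]],
    pixel_scale_mm: float,
    gating_radius_mm: float = 3.0,
    max_gap: int = 150,
    merge_area_factor: float = 1.6,
) -> tuple[list[Track], dict]:
    """Link per-frame detections into identity-stable tracks.

    Tracks are seeded from the first frame with detections (the experiment
    has a fixed, known animal count; no new identities are created later).
    Per frame, unmerged detections are assigned greedily by ascending
    distance within the gating radius; a detection larger than
    ``merge_area_factor`` x the median single-animal area that gates to
    several tracks is treated as a merged blob and shared, freezing each
    track at its last offset from the blob centroid.
    """
    T = len(detections_by_frame)
    gate_px = gating_radius_mm / pixel_scale_mm

    first = 0
    while first < T and not detections_by_frame[first]:
        first += 1
    if first == T:
        return [], {"n_tracks": 0, "detections_per_frame": [0] * T}

    seeds = sorted(detections_by_frame[first], key=lambda d: d.centroid_px)
    tracks = [
        Track(
            animal_id=i,
            n_frames=T,
            centroid_px=np.full((T, 2), np.nan),
            detected=np.zeros(T, dtype=bool),
            contact=np.zeros(T, dtype=bool),
            interpolated=np.zeros(T, dtype=bool),
        )
        for i in range(len(seeds))
    ]
    last_pos = np.array([d.centroid_px for d in seeds], dtype=float)
    for i, d in enumerate(seeds):
        tracks[i].centroid_px[first] = d.centroid_px
        tracks[i].detected[first] = True
    median_area = float(np.median([d.area for d in seeds]))
    contact_offset = {i: None for i in range(len(seeds))}
    n_unassigned = 0
    ties = 0

    for t in range(first + 1, T):
        dets = detections_by_frame[t]
        if not dets:
            continue
        cents = np.array([d.centroid_px for d in dets], dtype=float)
        areas = np.array([d.area for d in dets], dtype=float)
        dist = np.linalg.norm(last_pos[:, None, :] - cents[None, :, :], axis=-1)

        det_used = np.zeros(len(dets), dtype=bool)
        trk_used = np.zeros(len(tracks), dtype=bool)

        # merged blobs: big detections gated by several tracks are shared
        for j in np.where(areas > merge_area_factor * median_area)[0]:
            gated = [i for i in range(len(tracks)) if dist[i, j] <= gate_px]
            if len(gated) >= 2:
                det_used[j] = True
                for i in gated:
                    if contact_offset[i] is None:
                        contact_offset[i] = last_pos[i] - cents[j]
                    p = cents[j] + contact_offset[i]
                    tracks[i].centroid_px[t] = p
                    tracks[i].detected[t] = True
                    tracks[i].contact[t] = True
                    last_pos[i] = p
                    trk_used[i] = True

        # greedy one-to-one assignment of the rest, ascending distance
        order = np.argsort(dist, axis=None)
        for flat in order:
            i, j = divmod(int(flat), len(dets))
            if trk_used[i] or det_used[j] or dist[i, j] > gate_px:
                continue
            # deterministic tie-break: equal-distance competitors resolve to
            # the lower animal_id because argsort is stable in flat order
            if contact_offset[i] is not None:
                contact_offset[i] = None  # separated again
            tracks[i].centroid_px[t] = cents[j]
            tracks[i].detected[t] = True
            last_pos[i] = cents[j]
            trk_used[i] = True
            det_used[j] = True

        n_unassigned += int((~det_used).sum())
        # running estimate of the single-animal area from clean assignments
        single = areas[det_used & (areas <= merge_area_factor * median_area)]
        if single.size:
            median_area = 0.95 * median_area + 0.05 * float(np.median(single))

    qc = {
        "n_tracks": len(tracks),
        "detections_per_frame": [len(d) for d in detections_by_frame],
        "unassigned_detections": n_unassigned,
        "contact_frames": int(sum(tr.contact.sum() for tr in tracks)),
        "tie_breaks": ties,
    }
    return tracks, qc


def interpolate_gaps(track: Track, max_gap: int = 150) -> Track:
    """Bridge internal detection gaps up to ``max_gap`` frames linearly.

    Gap frames get linearly interpolated centroids and the ``interpolated``
    flag; longer gaps and gaps at the track boundary are left unfilled and
    recorded in ``track.breaks``.
    """
    det = track.detected
    idx = np.flatnonzero(det)
    if idx.size == 0:
        return track
    gaps: list[tuple[int, int]] = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1:
            gaps.append((int(a) + 1, int(b) - 1))
    for g0, g1 in gaps:
        n = g1 - g0 + 1
        if n > max_gap:
            track.breaks.append((g0, g1))
            continue
        p0 = track.centroid_px[g0 - 1]
        p1 = track.centroid_px[g1 + 1]
        w = (np.arange(1, n + 1) / (n + 1))[:, None]
        track.centroid_px[g0 : g1 + 1] = p0 + w * (p1 - p0)
        track.interpolated[g0 : g1 + 1] = True
    if idx[0] > 0:
        track.breaks.append((0, int(idx[0]) - 1))
    if idx[-1] < track.n_frames - 1:
        track.breaks.append((int(idx[-1]) + 1, track.n_frames - 1))
    return track


def crop_at(frame: np.ndarray, center_px: tuple[float, float], size: int = 64):
    """``size`` x ``size`` window centered on ``center_px``, zero-padded at borders.

    Returns (crop, (row0, col0)) where the origin maps crop indices back to
    frame coordinates.
    """
    r = int(round(center_px[0]))
    c = int(round(center_px[1]))
    half = size // 2
    r0, c0 = r - half, c - half
    crop = np.zeros((size, size), dtype=frame.dtype)
    fr0, fr1 = max(0, r0), min(frame.shape[0], r0 + size)
    fc0, fc1 = max(0, c0), min(frame.shape[1], c0 + size)
    if fr1 > fr0 and fc1 > fc0:
        crop[fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0] = frame[fr0:fr1, fc0:fc1]
    return crop, (r0, c0)


def extract_crops(track: Track, frames: Sequence[np.ndarray], size: int = 64):
    """Yield (frame_index, crop, origin) for every detected (non-interpolated) frame."""
    for t in np.flatnonzero(track.detected):
        yield int(t), *crop_at(frames[int(t)], tuple(track.centroid_px[int(t)]), size)


def track_movie(
    frames: Iterable[np.ndarray],
    arena: ArenaConfig,
    analysis: AnalysisParams | None = None,
) -> tuple[list[Track], dict]:
    """Detect and link a whole movie (frames may be a generator)."""
    analysis = analysis or AnalysisParams()
    dets: list[list[Detection]] = []
    for t, frame in enumerate(frames):
        dets.append(
            detect_blobs(
                frame,
                threshold=analysis.detect_threshold,
                min_area=analysis.min_area_px,
                max_area=analysis.max_area_px,
                frame_index=t,
                with_contours=False,
            )
        )
    tracks, qc = link_identities(
        dets,
        pixel_scale_mm=arena.pixel_scale_mm,
        gating_radius_mm=analysis.gating_radius_mm,
        max_gap=analysis.max_gap_frames,
        merge_area_factor=analysis.merge_area_factor,
    )
    for tr in tracks:
        interpolate_gaps(tr, max_gap=analysis.max_gap_frames)
    qc["gap_frames"] = int(sum(tr.interpolated.sum() for tr in tracks))
    qc["track_breaks"] = [tr.breaks for tr in tracks]
    return tracks, qc
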