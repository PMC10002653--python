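"""Midline, endpoint, and head/tail estimation with temporal flip suppression.

The midline is the topological skeleton of the body mask pruned to its
longest geodesic; head/tail assignment maximizes, over the whole series,
the projection of the head-to-tail axis onto the crawling direction minus a
penalty for orientation flips between consecutive frames (solved exactly by
a two-state Viterbi pass).  This is a deterministic, classical stand-in
with the same design intents as learned posture trackers — use of temporal
information (centroid momentum) and an explicit cost for head-tail flips.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage import measure

_MIN_COMPONENT_PX = 8


@dataclass
class Midline:
    """Ordered midline polyline in crop pixel coordinates (row, col)."""

    points_px: np.ndarray  # (n, 2), endpoint-to-endpoint
    valid: bool = True

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points_px[0], self.points_px[-1]


INVALID_MIDLINE = Midline(points_px=np.zeros((0, 2)), valid=False)


def extract_midline(crop: np.ndarray, threshold: int = 100, n_points: int = 11) -> Midline:
    """Midline of the single larva in a crop.

    Returns an invalid :class:`Midline` for blank crops or components
    smaller than 8 px.  The midline is the ridge geodesic between the two
    geodesically farthest pixels of the body mask: shortest path on the
    8-connected pixel graph with steps penalized away from the distance-
    transform ridge, trimmed by the body half-width at the end caps and
    resampled to ``n_points`` by arc length.
    """
    mask = np.asarray(crop) >= threshold
    if not mask.any():
        return INVALID_MIDLINE
    lab = measure.label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    comp = lab == sizes.argmax()
    if comp.sum() < _MIN_COMPONENT_PX:
        return INVALID_MIDLINE
    path = _ridge_geodesic(comp)
    if path is None or len(path) < 2:
        path = _pca_line(comp)
    return Midline(points_px=_resample_polyline(path, n_points))


def _ridge_geodesic(mask: np.ndarray, centrality: float = 2.0) -> np.ndarray | None:
    """End-to-end path through the body mask, biased onto the medial ridge."""
    coords = np.argwhere(mask)
    n = len(coords)
    idx = -np.ones(mask.shape, dtype=int)
    idx[tuple(coords.T)] = np.arange(n)
    dt = ndimage.distance_transform_edt(mask)
    dmax = dt.max()
    rows, cols, weights = [], [], []
    for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1)):
        tgt = coords + (dr, dc)
        ok = (
            (tgt[:, 0] >= 0)
            & (tgt[:, 0] < mask.shape[0])
            & (tgt[:, 1] >= 0)
            & (tgt[:, 1] < mask.shape[1])
        )
        sv, tv = coords[ok], tgt[ok]
        inside = mask[tuple(tv.T)]
        sv, tv = sv[inside], tv[inside]
        step = float(np.hypot(dr, dc))
        cost = step * (1.0 + centrality * (dmax - (dt[tuple(sv.T)] + dt[tuple(tv.T)]) / 2.0))
        rows.append(idx[tuple(sv.T)])
        cols.append(idx[tuple(tv.T)])
        weights.append(cost)
    if not rows or sum(len(r) for r in rows) == 0:
        return None
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    w = np.concatenate(weights)
    graph = sparse.csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(n, n)
    )
    d0 = dijkstra(graph, indices=0)
    a = int(np.argmax(np.where(np.isinf(d0), -1.0, d0)))
    da, pred = dijkstra(graph, indices=a, return_predecessors=True)
    b = int(np.argmax(np.where(np.isinf(da), -1.0, da)))
    chain = [b]
    while chain[-1] != a:
        p = pred[chain[-1]]
        if p < 0:
            return None
        chain.append(int(p))
    pts = coords[chain[::-1]].astype(float)
    # trim the stadium end caps back to the true body endpoints
    half_w = float(np.median(dt[tuple(coords[chain].T)]))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = (s >= half_w) & (s <= s[-1] - half_w)
    if keep.sum() >= 2:
        pts = pts[keep]
    return pts


def _pca_line(mask: np.ndarray) -> np.ndarray:
    """Fallback midline for degenerate skeletons: principal axis of the mask."""
    coords = np.argwhere(mask).astype(float)
    c = coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords - c, full_matrices=False)
    axis = vt[0]
    proj = (coords - c) @ axis
    return np.array([c + proj.min() * axis, c + proj.max() * axis])


def _resample_polyline(path: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(path[:1], n_points, axis=0)
    t = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(t, s, path[:, 0]), np.interp(t, s, path[:, 1])])


def bend_angle(midline_points: np.ndarray) -> float:
    """Body bend angle in degrees: 0 = straight, positive for any bend.

    The angle between the chord from the midline midpoint to one endpoint
    and the chord to the other endpoint, reported as 180 deg minus the
    interior angle.  Invariant under rigid rotation/translation and under
    endpoint order.
    """
    pts = np.asarray(midline_points, dtype=float)
    if len(pts) < 3:
        return float("nan")
    m = pts[len(pts) // 2]
    u = pts[0] - m
    w = pts[-1] - m
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return float("nan")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return 180.0 - float(np.degrees(np.arccos(cosang)))


@dataclass
class HeadTailResult:
    head: np.ndarray  # (T, 2)
    tail: np.ndarray  # (T, 2)
    orientation: np.ndarray  # (T,) 0/1: which normalized endpoint is the head
    n_flips: int
    flip_penalty: float


def assign_head_tail(
    endpoints_a: np.ndarray,
    endpoints_b: np.ndarray,
    velocity: np.ndarray,
    flip_penalty: float | None = None,
    v_min: float = 0.05,
    valid: np.ndarray | None = None,
) -> HeadTailResult:
    """Orient an endpoint series into head/tail using centroid momentum.

    Endpoints (any consistent units, typically mm) arrive in arbitrary
    per-frame order; they are first normalized by frame-to-frame proximity,
    then the per-frame orientation is chosen to maximize the total of
    (head - tail) . velocity minus ``flip_penalty`` per orientation change —
    the exact optimum via a two-state Viterbi pass.  Below ``v_min`` speed
    the motion term is zero and the prior orientation is retained.

    ``flip_penalty=None`` uses 3x the median nonzero motion-evidence
    magnitude; ``flip_penalty=0`` reduces to naive per-frame assignment.
    """
    a = np.array(endpoints_a, dtype=float)
    b = np.array(endpoints_b, dtype=float)
    v = np.asarray(velocity, dtype=float)
    T = len(a)
    if valid is None:
        valid = ~(np.isnan(a[:, 0]) | np.isnan(b[:, 0]))
    valid = np.asarray(valid, bool)

    # normalize endpoint order by temporal proximity
    last = None
    for t in range(T):
        if not valid[t]:
            continue
        if last is not None:
            keep = np.linalg.norm(a[t] - last[0]) + np.linalg.norm(b[t] - last[1])
            swap = np.linalg.norm(a[t] - last[1]) + np.linalg.norm(b[t] - last[0])
            if swap < keep:
                a[t], b[t] = b[t].copy(), a[t].copy()
        last = (a[t], b[t])

    speed = np.linalg.norm(v, axis=1)
    moving = valid & (speed >= v_min)
    # evidence for "a is head": (a - b) . v ; state 1 means b is head
    m = np.zeros(T)
    m[moving] = np.einsum("ij,ij->i", (a - b)[moving], v[moving])

    if flip_penalty is None:
        nz = np.abs(m[m != 0.0])
        flip_penalty = 3.0 * float(np.median(nz)) if nz.size else 1.0

    # Viterbi over 2 states; ties prefer staying (no flip)
    score = np.array([m[0], -m[0]])
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        em = np.array([m[t], -m[t]])
        new = np.empty(2)
        for s in (0, 1):
            stay = score[s]
            move = score[1 - s] - flip_penalty
            if move > stay:
                new[s] = move + em[s]
                back[t, s] = 1
            else:
                new[s] = stay + em[s]
                back[t, s] = 0
        score = new
    states = np.empty(T, dtype=np.int8)
    states[-1] = int(score[1] > score[0])
    for t in range(T - 1, 0, -1):
        states[t - 1] = states[t] ^ back[t, states[t]]

    head = np.where(states[:, None] == 0, a, b)
    tail = np.where(states[:, None] == 0, b, a)
    n_flips = int(np.count_nonzero(np.diff(states.astype(int))))
    return HeadTailResult(
        head=head, tail=tail, orientation=states, n_flips=n_flips, flip_penalty=float(flip_penalty)
    )
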