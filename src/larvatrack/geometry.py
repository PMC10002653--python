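"""Angle arithmetic, smoothing, and pixel/mm coordinate transforms.

Arena coordinates are mm, origin lower-left, x right, y up.  Image arrays
are row-major with row 0 at the top, so the row axis runs against y; all
conversions go through :func:`px_to_mm` / :func:`mm_to_px` with the image
height and the pixel scale.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d


def wrap_deg(a):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    r = (a + 180.0) % 360.0 - 180.0
    r = np.where(r == -180.0, 180.0, r)
    return float(r) if r.ndim == 0 else r


def circmean_deg(a) -> float:
    """Circular mean of angles in degrees (NaN-aware)."""
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    rad = np.radians(a)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def boxcar(x, window: int):
    """Centered moving average with edge replication (time-reversal symmetric)."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    return uniform_filter1d(x, size=int(window), mode="nearest")


def px_to_mm(row, col, pixel_scale_mm: float, height_px: int):
    """Pixel (row, col) centers to arena (x, y) in mm."""
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    x = (col + 0.5) * pixel_scale_mm
    y = (height_px - row - 0.5) * pixel_scale_mm
    return x, y


def mm_to_px(x_mm, y_mm, pixel_scale_mm: float, height_px: int):
    """Arena (x, y) mm to continuous pixel (row, col) coordinates."""
    x_mm = np.asarray(x_mm, dtype=float)
    y_mm = np.asarray(y_mm, dtype=float)
    col = x_mm / pixel_scale_mm - 0.5
    row = height_px - 0.5 - y_mm / pixel_scale_mm
    return row, col
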