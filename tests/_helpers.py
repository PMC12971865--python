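"""Shared constructors and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from gazeskill.aoi import OBJECT, TOOL, DetectedInstance, FrameAnnotation
from gazeskill.gaze import GazeTrace


def triangle(cx: float, cy: float, r: float = 35.0) -> np.ndarray:
    ang = np.deg2rad([90.0, 210.0, 330.0])
    return np.column_stack((cx + r * np.cos(ang), cy + r * np.sin(ang)))


def square(cx: float, cy: float, half: float = 50.0) -> np.ndarray:
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ]
    )


def rect(cx: float, cy: float, w: float = 150.0, h: float = 26.0) -> np.ndarray:
    return np.array(
        [
            [cx - w / 2, cy - h / 2],
            [cx + w / 2, cy - h / 2],
            [cx + w / 2, cy + h / 2],
            [cx - w / 2, cy + h / 2],
        ]
    )


def inst(iid: int, label: str, poly: np.ndarray, conf: float = 0.9) -> DetectedInstance:
    return DetectedInstance(instance_id=iid, label=label, polygon=poly, confidence=conf)


def obj(iid: int, poly: np.ndarray, conf: float = 0.9) -> DetectedInstance:
    return inst(iid, OBJECT, poly, conf)


def tool(iid: int, poly: np.ndarray, conf: float = 0.9) -> DetectedInstance:
    return inst(iid, TOOL, poly, conf)


def frame(i: int, t: float, instances: list) -> FrameAnnotation:
    return FrameAnnotation(frame_index=i, t=t, instances=instances)


def trace_from_xy(x, y, hz: float = 50.0, valid=None) -> GazeTrace:
    x = np.asarray(x, dtype=float)
    n = x.size
    t = np.arange(n) / hz
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrace(t=t, x=x, y=np.asarray(y, dtype=float), valid=np.asarray(valid, bool))


# ---------------------------------------------------------------------------
# Brute-force I-VT segmentation oracle (per-sample threshold scan)
# ---------------------------------------------------------------------------


def brute_ivt_segments(trace: GazeTrace, velocities, threshold, max_gap, min_dur):
    """Naive scan over the velocity series; returns (t_start, t_end) pairs."""
    segments = []
    cur = []
    for i in range(trace.n_samples):
        if not trace.valid[i]:
            continue
        v = velocities[i]
        below = np.isfinite(v) and v < threshold
        if not below:
            if cur:
                segments.append(cur)
                cur = []
            continue
        if cur and trace.t[i] - trace.t[cur[-1]] > max_gap + 1e-12:
            segments.append(cur)
            cur = []
        cur.append(i)
    if cur:
        segments.append(cur)
    return [
        (trace.t[s[0]], trace.t[s[-1]])
        for s in segments
        if trace.t[s[-1]] - trace.t[s[0]] >= min_dur - 1e-12
    ]


# ---------------------------------------------------------------------------
# Rasterized distance-transform oracle for the dilated hit test
# ---------------------------------------------------------------------------


def raster_distance(poly: np.ndarray, points: np.ndarray, scale: int = 4):
    """Distance of each point to a polygon via rasterization + EDT.

    The polygon is rasterized on a 1/scale px grid with matplotlib's
    fill rule; the distance transform of the exterior gives distances to
    the polygon (0 inside), accurate to roughly one grid cell.
    """
    from matplotlib.path import Path
    from scipy.ndimage import distance_transform_edt

    pad = 16.0
    x0, y0 = poly.min(axis=0) - pad
    x1, y1 = poly.max(axis=0) + pad
    nx = int(np.ceil((x1 - x0) * scale))
    ny = int(np.ceil((y1 - y0) * scale))
    xs = x0 + (np.arange(nx) + 0.5) / scale
    ys = y0 + (np.arange(ny) + 0.5) / scale
    gx, gy = np.meshgrid(xs, ys)
    mask = (
        Path(poly)
        .contains_points(np.column_stack((gx.ravel(), gy.ravel())))
        .reshape(ny, nx)
    )
    dist = distance_transform_edt(~mask) / scale
    ix = np.clip(np.round((points[:, 0] - x0) * scale - 0.5).astype(int), 0, nx - 1)
    iy = np.clip(np.round((points[:, 1] - y0) * scale - 0.5).astype(int), 0, ny - 1)
    return dist[iy, ix]
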