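"""Velocity-threshold (I-VT) fixation filtering for raw gaze traces.

A gaze trace is a sequence of timestamped screen-pixel samples with a
per-sample validity flag (typically at a nominal 50 Hz).  The I-VT filter
estimates an angular velocity for every valid sample over a short window,
labels samples below a velocity threshold as fixation samples, and groups
maximal below-threshold runs into :class:`Fixation` intervals, bridging
short dropouts and discarding runs shorter than a minimum duration.

Because the threshold is expressed in degrees per second while the trace
is in pixels, an explicit :class:`ScreenGeometry` (pixels per degree of
visual angle) is required; absolute threshold behavior depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import radians, tan
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeTrace",
    "ScreenGeometry",
    "IVTConfig",
    "Fixation",
    "GazeQualityWarning",
    "angular_velocity",
    "ivt_classify",
    "gaze_sample_percentage",
    "passes_quality",
    "read_gaze_csv",
    "write_gaze_csv",
    "write_fixations_csv",
]


class GazeQualityWarning(UserWarning):
    """Raised for degenerate or low-quality gaze input."""


@dataclass(frozen=True)
class GazeTrace:
    """A raw gaze recording in screen pixels.

    Parameters
    ----------
    t : array-like of float
        Sample timestamps in seconds, strictly increasing and finite.
    x, y : array-like of float
        Gaze position in pixels (origin top-left, x right, y down).
    valid : array-like of bool
        Per-sample validity flag from the tracker.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == valid.shape) or t.ndim != 1:
            raise ValueError("t, x, y, valid must be 1-D arrays of equal length")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "valid", valid)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel-to-visual-angle conversion.

    The default of 38 px/degree is a typical seated-monitor value; use
    :meth:`from_physical` when viewing distance and screen size are known.
    """

    px_per_degree: float = 38.0

    def __post_init__(self) -> None:
        if not self.px_per_degree > 0:
            raise ValueError("px_per_degree must be positive")

    @classmethod
    def from_physical(
        cls, viewing_distance_mm: float, screen_width_mm: float, screen_width_px: int
    ) -> "ScreenGeometry":
        """Derive px/degree from physical setup (small-angle, screen center)."""
        if min(viewing_distance_mm, screen_width_mm, screen_width_px) <= 0:
            raise ValueError("physical dimensions must be positive")
        mm_per_degree = viewing_distance_mm * tan(radians(1.0))
        return cls(px_per_degree=mm_per_degree * screen_width_px / screen_width_mm)


@dataclass(frozen=True)
class IVTConfig:
    """I-VT filter parameters.

    ``velocity_threshold`` is the fixation/saccade cut in deg/s.  The
    velocity at each sample is estimated from the displacement between the
    samples nearest the edges of a ``velocity_window`` centered on it.
    Runs shorter than ``min_fixation_duration`` are discarded and invalid
    gaps up to ``max_gap_fill`` inside a run do not split it.
    """

    velocity_threshold: float = 70.0
    velocity_window: float = 0.020
    min_fixation_duration: float = 0.060
    max_gap_fill: float = 0.075

    def __post_init__(self) -> None:
        for name in ("velocity_threshold", "velocity_window", "min_fixation_duration", "max_gap_fill"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Fixation:
    """A fixation interval with its centroid in pixels."""

    t_start: float
    t_end: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start >= 0):
            raise ValueError("fixation requires t_end > t_start >= 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def angular_velocity(
    trace: GazeTrace,
    geometry: ScreenGeometry | None = None,
    cfg: IVTConfig | None = None,
) -> np.ndarray:
    """Per-sample angular velocity in deg/s.

    For each valid sample the velocity is the angular displacement between
    the valid samples closest to the edges of ``cfg.velocity_window``
    centered on it, divided by their time separation (a two-point
    estimator, which suppresses sample-to-sample noise at 50 Hz relative
    to adjacent differencing).  Invalid samples get NaN.  With fewer than
    two valid samples the result is all-NaN and a
    :class:`GazeQualityWarning` is emitted.
    """
    geometry = geometry or ScreenGeometry()
    cfg = cfg or IVTConfig()
    v = np.full(trace.n_samples, np.nan)
    vi = np.flatnonzero(trace.valid)
    if vi.size < 2:
        warnings.warn(
            "fewer than two valid samples; velocity undefined", GazeQualityWarning
        )
        return v
    tv = trace.t[vi]
    xv = trace.x[vi]
    yv = trace.y[vi]
    half = cfg.velocity_window / 2.0
    idx = np.arange(tv.size)
    a = np.searchsorted(tv, tv - half, side="right") - 1
    b = np.searchsorted(tv, tv + half, side="left")
    # At the trace edges fall back to the nearest valid neighbor.
    a = np.where(a >= 0, a, np.maximum(idx - 1, 0))
    b = np.where(b <= tv.size - 1, b, np.minimum(idx + 1, tv.size - 1))
    dt = tv[b] - tv[a]
    disp = np.hypot(xv[b] - xv[a], yv[b] - yv[a])
    with np.errstate(invalid="ignore", divide="ignore"):
        vv = disp / dt / geometry.px_per_degree
    vv[a >= b] = np.nan
    v[vi] = vv
    return v


def ivt_classify(
    trace: GazeTrace,
    geometry: ScreenGeometry | None = None,
    cfg: IVTConfig | None = None,
) -> list[Fixation]:
    """Classify a gaze trace into fixations with the I-VT rule.

    Maximal runs of valid samples whose angular velocity is strictly below
    ``cfg.velocity_threshold`` become fixations.  A run is split wherever
    the time gap between consecutive member samples exceeds
    ``cfg.max_gap_fill`` (i.e. dropouts longer than the bridgeable gap).
    Runs whose span is shorter than ``cfg.min_fixation_duration`` are
    discarded.  The fixation centroid is the mean position of the member
    samples.
    """
    cfg = cfg or IVTConfig()
    if trace.n_samples == 0:
        return []
    v = angular_velocity(trace, geometry, cfg)
    vi = np.flatnonzero(trace.valid)
    if vi.size == 0:
        return []
    with np.errstate(invalid="ignore"):
        below = v[vi] < cfg.velocity_threshold  # NaN compares False
    fixations: list[Fixation] = []
    run: list[int] = []  # indices into trace arrays

    def _flush() -> None:
        if not run:
            return
        t0 = trace.t[run[0]]
        t1 = trace.t[run[-1]]
        if t1 - t0 >= cfg.min_fixation_duration - 1e-12:
            fixations.append(
                Fixation(
                    t_start=float(t0),
                    t_end=float(t1),
                    cx=float(np.mean(trace.x[run])),
                    cy=float(np.mean(trace.y[run])),
                )
            )
        run.clear()

    for k in range(vi.size):
        if not below[k]:
            _flush()
            continue
        i = int(vi[k])
        if run and trace.t[i] - trace.t[run[-1]] > cfg.max_gap_fill + 1e-12:
            _flush()
        run.append(i)
    _flush()
    return fixations


def gaze_sample_percentage(trace: GazeTrace) -> float:
    """Percent of valid samples, ``100 * valid / total``.

    Raises ``ValueError`` on an empty trace (the quantity is undefined).
    """
    if trace.n_samples == 0:
        raise ValueError("gaze sample percentage is undefined for an empty trace")
    return 100.0 * float(np.count_nonzero(trace.valid)) / trace.n_samples


def passes_quality(trace: GazeTrace, min_percent: float = 80.0) -> bool:
    """QC gate: True iff the valid-sample percentage reaches ``min_percent``."""
    ok = gaze_sample_percentage(trace) >= min_percent
    if not ok:
        warnings.warn(
            f"trace below quality gate ({gaze_sample_percentage(trace):.1f}% "
            f"< {min_percent:.1f}%); session flagged excluded",
            GazeQualityWarning,
        )
    return ok


# ---------------------------------------------------------------------------
# I/O: gaze CSV (columns t_s, x_px, y_px, valid) and fixation tables
# ---------------------------------------------------------------------------

GAZE_COLUMNS = ("t_s", "x_px", "y_px", "valid")


def read_gaze_csv(path: str | Path, delimiter: str = ",") -> GazeTrace:
    """Read a gaze trace from delimited text with a required header."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gaze columns {missing}")
    return GazeTrace(
        t=df["t_s"].to_numpy(float),
        x=df["x_px"].to_numpy(float),
        y=df["y_px"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
    )


def write_gaze_csv(trace: GazeTrace, path: str | Path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "x_px": trace.x,
            "y_px": trace.y,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, sep=delimiter, index=False)


def write_fixations_csv(fixations: Sequence[Fixation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_start": [f.t_start for f in fixations],
            "t_end": [f.t_end for f in fixations],
            "cx": [f.cx for f in fixations],
            "cy": [f.cy for f in fixations],
            "duration": [f.duration for f in fixations],
        }
    ).to_csv(path, index=False)
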