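"""Per-session behavioral metrics.

Six metrics summarize a session: five AOI-dependent fixation rates in
frames/second (tools, all objects, object-one-tool, object-two-tools,
not-moving objects) and one motion metric, tool speed in px/second.  A
fixation rate is the number of distinct video frames in which a fixation
point hit the category, divided by task completion time; counting
distinct frames keeps every rate bounded by the frame rate and makes the
three object subcategories an exact partition of the overall object rate.

Frame-by-frame agreement between two categorical annotation streams is
quantified with Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gazeskill import aoi
from gazeskill.aoi import AOICategory, AOIConfig, FrameAnnotation, HitRecord
from gazeskill.gaze import GazeTrace, IVTConfig, ScreenGeometry, ivt_classify

__all__ = [
    "SessionMetrics",
    "FEATURE_COLUMNS",
    "fixation_rates",
    "tool_speed",
    "cohen_kappa",
    "compute_session_metrics",
    "extract_cohort_metrics",
    "metrics_table",
    "write_metrics_csv",
    "read_metrics_csv",
]

#: The six features used by the clustering and prediction stages.
FEATURE_COLUMNS = [
    "fr_tools",
    "fr_objects",
    "fr_obj_1tool",
    "fr_obj_2tools",
    "fr_not_moving",
    "tool_speed",
]

_OBJ_RANK = {
    AOICategory.OBJ_NOT_MOVING: 0,
    AOICategory.OBJ_1TOOL: 1,
    AOICategory.OBJ_2TOOLS: 2,
}
_RANK_TO_RATE = {0: "fr_not_moving", 1: "fr_obj_1tool", 2: "fr_obj_2tools"}


@dataclass
class SessionMetrics:
    session_id: str
    participant_id: str
    trainer: str
    completion_time: float
    errors: int
    fr_tools: float
    fr_objects: float
    fr_obj_1tool: float
    fr_obj_2tools: float
    fr_not_moving: float
    tool_speed: float

    def __post_init__(self) -> None:
        if not self.completion_time > 0:
            raise ValueError("completion_time must be positive")
        if self.trainer not in ("pediatric", "adult"):
            raise ValueError(f"unknown trainer type {self.trainer!r}")


def fixation_rates(hits: Iterable[HitRecord], completion_time: float) -> dict[str, float]:
    """Five fixation rates (frames/second) from hit records.

    A frame is credited at most once per category; when hits place one
    frame in more than one object subcategory, the highest hold state
    wins (so the subcategories partition the object-hit frames exactly
    and ``fr_objects`` equals their sum).
    """
    if not completion_time > 0:
        raise ValueError("completion_time must be positive")
    obj_frames: dict[int, int] = {}
    tool_frames: set[int] = set()
    for h in hits:
        rank = _OBJ_RANK.get(h.category)
        if rank is not None:
            prev = obj_frames.get(h.frame_index)
            if prev is None or rank > prev:
                obj_frames[h.frame_index] = rank
        elif h.category is AOICategory.TOOL_ONLY:
            tool_frames.add(h.frame_index)
    counts = {name: 0 for name in _RANK_TO_RATE.values()}
    for rank in obj_frames.values():
        counts[_RANK_TO_RATE[rank]] += 1
    return {
        "fr_tools": len(tool_frames) / completion_time,
        "fr_objects": len(obj_frames) / completion_time,
        "fr_obj_1tool": counts["fr_obj_1tool"] / completion_time,
        "fr_obj_2tools": counts["fr_obj_2tools"] / completion_time,
        "fr_not_moving": counts["fr_not_moving"] / completion_time,
    }


def tool_speed(frames: Sequence[FrameAnnotation]) -> float:
    """Summed average grasper speed in px/second.

    For each grasper (left/right identity from :func:`gazeskill.aoi.track_tools`)
    the speed is averaged over consecutive frame pairs where the grasper
    is detected in both frames (Euclidean centroid displacement divided by
    the timestamp difference); pairs spanning a missed detection are
    skipped rather than interpolated.  The result is the sum of the left
    and right averages.  NaN (with a warning) if neither grasper has a
    usable pair.
    """
    if len(frames) < 2:
        warnings.warn("tool speed undefined: fewer than two frames", UserWarning)
        return float("nan")
    t, left, right = aoi.track_tools(frames)
    total = 0.0
    usable = 0
    for track in (left, right):
        ok = ~np.isnan(track[:, 0])
        pair = ok[:-1] & ok[1:]
        if not pair.any():
            continue
        d = np.linalg.norm(track[1:] - track[:-1], axis=1)[pair]
        dt = np.diff(t)[pair]
        total += float(np.mean(d / dt))
        usable += 1
    if usable == 0:
        warnings.warn("tool speed undefined: no grasper detected in two consecutive frames", UserWarning)
        return float("nan")
    return total


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two equal-length categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal label distributions.  Defined as 1.0 in the degenerate case
    where both sequences are the same constant (p_e = 1).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("kappa is undefined for empty sequences")
    union = np.unique(np.concatenate([np.unique(a), np.unique(b)]))
    a_codes = np.searchsorted(union, a)
    b_codes = np.searchsorted(union, b)
    k = union.size
    table = np.zeros((k, k))
    np.add.at(table, (a_codes, b_codes), 1.0)
    n = a.size
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def compute_session_metrics(
    frames: Sequence[FrameAnnotation],
    trace: GazeTrace,
    *,
    completion_time: float,
    session_id: str = "session",
    participant_id: str = "anon",
    trainer: str = "adult",
    errors: int = 0,
    geometry: ScreenGeometry | None = None,
    ivt_cfg: IVTConfig | None = None,
    aoi_cfg: AOIConfig | None = None,
) -> SessionMetrics:
    """Run the full per-session pipeline and return one metrics row.

    The confidence filter is applied to ``frames`` first so in-memory
    sessions behave identically to annotation files run through the
    loader.
    """
    aoi_cfg = aoi_cfg or AOIConfig()
    frames = aoi.filter_frames(frames, aoi_cfg)
    fixations = ivt_classify(trace, geometry, ivt_cfg) if trace.n_samples else []
    hits = (
        aoi.map_fixations_to_frames(fixations, frames, aoi_cfg, trace=trace)
        if fixations
        else []
    )
    rates = fixation_rates(hits, completion_time)
    return SessionMetrics(
        session_id=session_id,
        participant_id=participant_id,
        trainer=trainer,
        completion_time=completion_time,
        errors=errors,
        tool_speed=tool_speed(frames),
        **rates,
    )


def extract_cohort_metrics(
    sessions: Iterable,
    *,
    geometry: ScreenGeometry | None = None,
    ivt_cfg: IVTConfig | None = None,
    aoi_cfg: AOIConfig | None = None,
) -> pd.DataFrame:
    """Metrics table for an iterable of simulated (or equivalent) sessions.

    Each session must expose ``frames``, ``gaze``, ``completion_time``,
    ``errors``, ``trainer``, ``participant_id`` and ``session_id``.
    """
    rows = [
        compute_session_metrics(
            s.frames,
            s.gaze,
            completion_time=s.completion_time,
            session_id=s.session_id,
            participant_id=s.participant_id,
            trainer=s.trainer,
            errors=s.errors,
            geometry=geometry,
            ivt_cfg=ivt_cfg,
            aoi_cfg=aoi_cfg,
        )
        for s in sessions
    ]
    return metrics_table(rows)


def metrics_table(rows: Sequence[SessionMetrics]) -> pd.DataFrame:
    cols = [f.name for f in fields(SessionMetrics)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows], columns=cols)


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metric columns {missing}")
    return df
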