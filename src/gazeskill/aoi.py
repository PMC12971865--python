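"""Dynamic area-of-interest (AOI) engine.

Ingests per-frame instance annotations (polygon masks for task objects and
grasper tools with a detection confidence), derives per-object holding
states from polygon overlap with the tools, and scores fixations against
the instances with a dilated-contour hit test: a point hits an instance if
it lies inside the polygon or within ``dilation_radius`` pixels of its
boundary.

Each (fixation, frame) pair is assigned exactly one category:

* ``OBJ_1TOOL``     -- fixation on an object held by one tool
* ``OBJ_2TOOLS``    -- fixation on an object held by two tools
* ``OBJ_NOT_MOVING``-- fixation on an object held by no tool
* ``TOOL_ONLY``     -- fixation on a tool but on no object
* ``NONE``          -- fixation on neither

Under the default ``object_state`` semantics the category of an object hit
is determined by the hold state of the hit object (precedence
HELD_TWO > HELD_ONE > NOT_HELD across all hit objects), which makes the
three object subcategories an exact partition of the object hits.  The
alternative ``pixel_intersection`` semantics instead uses the literal
overlap region containing the point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from gazeskill.gaze import Fixation, GazeTrace

__all__ = [
    "AOICategory",
    "HoldState",
    "DetectedInstance",
    "FrameAnnotation",
    "AOIConfig",
    "HitRecord",
    "load_annotations",
    "write_annotations",
    "filter_frame",
    "filter_frames",
    "object_states",
    "dilated_hit",
    "classify_fixation_frame",
    "map_fixations_to_frames",
    "track_tools",
    "write_hits_csv",
]

OBJECT = "object"
TOOL = "tool"
_INTERSECTION_AREA_TOL = 1e-6  # px^2; overlap below this does not count as holding


def _area_centroid(poly: np.ndarray) -> tuple[float, float]:
    """Area (shoelace) centroid; falls back to the vertex mean if degenerate."""
    pts = poly.tolist()
    n = len(pts)
    area2 = cx = cy = 0.0
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        cross = x1 * y2 - x2 * y1
        area2 += cross
        cx += (x1 + x2) * cross
        cy += (y1 + y2) * cross
    if abs(area2) < 1e-12:
        return (
            sum(p[0] for p in pts) / n,
            sum(p[1] for p in pts) / n,
        )
    return (cx / (3.0 * area2), cy / (3.0 * area2))


def _point_polygon_distance(px: float, py: float, poly: np.ndarray) -> float:
    """Distance from (px, py) to a simple polygon; 0 when the point is inside."""
    pts = poly.tolist()
    n = len(pts)
    best = float("inf")
    crossings = 0
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        ex = x2 - x1
        ey = y2 - y1
        l2 = ex * ex + ey * ey
        tpar = 0.0 if l2 == 0 else ((px - x1) * ex + (py - y1) * ey) / l2
        tpar = 0.0 if tpar < 0.0 else (1.0 if tpar > 1.0 else tpar)
        dx = x1 + tpar * ex - px
        dy = y1 + tpar * ey - py
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
        # even-odd containment rule
        if (y1 > py) != (y2 > py) and px < x1 + (py - y1) * ex / ey:
            crossings += 1
    if crossings % 2 == 1:
        return 0.0
    return best**0.5


class AOICategory(str, Enum):
    OBJ_1TOOL = "obj_one_tool"
    OBJ_2TOOLS = "obj_two_tools"
    OBJ_NOT_MOVING = "obj_not_moving"
    TOOL_ONLY = "tool_only"
    NONE = "none"


OBJECT_CATEGORIES = (
    AOICategory.OBJ_NOT_MOVING,
    AOICategory.OBJ_1TOOL,
    AOICategory.OBJ_2TOOLS,
)


class HoldState(IntEnum):
    NOT_HELD = 0
    HELD_ONE = 1
    HELD_TWO = 2


_STATE_TO_CATEGORY = {
    HoldState.NOT_HELD: AOICategory.OBJ_NOT_MOVING,
    HoldState.HELD_ONE: AOICategory.OBJ_1TOOL,
    HoldState.HELD_TWO: AOICategory.OBJ_2TOOLS,
}


@dataclass(eq=False)
class DetectedInstance:
    """A single detected instance in one frame.

    ``polygon`` is an (n, 2) vertex array in arena pixel coordinates
    (origin top-left, x right, y down).  ``confidence`` is the detector
    score in [0, 1].
    """

    instance_id: int
    label: str
    polygon: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError(
                f"instance {self.instance_id}: polygon needs >= 3 (x, y) vertices"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"instance {self.instance_id}: confidence not in [0, 1]")
        if self.label not in (OBJECT, TOOL):
            raise ValueError(f"instance {self.instance_id}: unknown label {self.label!r}")
        self.polygon = poly

    @cached_property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)

    @cached_property
    def centroid(self) -> tuple[float, float]:
        return _area_centroid(self.polygon)

    @cached_property
    def bounds(self) -> tuple[float, float, float, float]:
        pts = self.polygon.tolist()
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        return (min(xs), min(ys), max(xs), max(ys))

    def distance(self, px: float, py: float) -> float:
        """Euclidean distance from a point to the polygon (0 inside)."""
        return _point_polygon_distance(px, py, self.polygon)

    def validate(self, where: str = "") -> None:
        """Strict geometric validation (simple, non-degenerate polygon)."""
        if not self.shape.is_valid or self.shape.area <= 0:
            raise ValueError(
                f"{where}instance {self.instance_id}: polygon is degenerate or "
                "self-intersecting"
            )


@dataclass(eq=False)
class FrameAnnotation:
    """All detected instances of one video frame."""

    frame_index: int
    t: float
    instances: list[DetectedInstance] = field(default_factory=list)

    def by_label(self, label: str) -> list[DetectedInstance]:
        return [i for i in self.instances if i.label == label]

    def hold_state(self, obj: DetectedInstance) -> "HoldState":
        """Hold state of one object, memoized on the frame."""
        cache = self.__dict__.setdefault("_state_cache", {})
        state = cache.get(obj.instance_id)
        if state is None:
            state = _hold_state(obj, self.by_label(TOOL))
            cache[obj.instance_id] = state
        return state

    def instances_near(
        self, point: tuple[float, float], radius: float
    ) -> list[DetectedInstance]:
        """Instances whose expanded bounding box contains ``point``.

        Sound prefilter for the dilated hit test: a point outside the
        bbox expanded by ``radius`` is farther than ``radius`` from the
        polygon.
        """
        px, py = point
        out = []
        for inst in self.instances:
            x0, y0, x1, y1 = inst.bounds
            if x0 - radius <= px <= x1 + radius and y0 - radius <= py <= y1 + radius:
                out.append(inst)
        return out


@dataclass(frozen=True)
class AOIConfig:
    """Hit-test configuration.

    ``dilation_radius`` extends every contour outward by the given number
    of pixels; ``confidence_min`` drops detections at or below the
    threshold (a detection is valid only with score strictly greater).

    ``hit_point`` selects the gaze coordinate tested per spanned frame:
    ``per_frame`` (default) uses the mean of the fixation's member samples
    nearest the frame timestamp, which tracks moving AOIs during smooth
    pursuit; ``centroid`` uses the whole-fixation centroid for every
    frame.  ``per_frame`` needs the raw trace and falls back to the
    centroid when it is unavailable.
    """

    dilation_radius: float = 5.0
    confidence_min: float = 0.5
    category_semantics: str = "object_state"  # or "pixel_intersection"
    hit_point: str = "per_frame"  # or "centroid"

    def __post_init__(self) -> None:
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ValueError("confidence_min must be in [0, 1]")
        if self.category_semantics not in ("object_state", "pixel_intersection"):
            raise ValueError(f"unknown category_semantics {self.category_semantics!r}")
        if self.hit_point not in ("per_frame", "centroid"):
            raise ValueError(f"unknown hit_point {self.hit_point!r}")


@dataclass(frozen=True)
class HitRecord:
    frame_index: int
    category: AOICategory
    fixation_id: int


# ---------------------------------------------------------------------------
# Annotation I/O (COCO-style dialect)
# ---------------------------------------------------------------------------


def load_annotations(path: str | Path, cfg: AOIConfig | None = None) -> list[FrameAnnotation]:
    """Load per-frame annotations from a COCO-style JSON file.

    Expected layout::

        {"images": [{"id": ..., "frame_index": ..., "t": ...}, ...],
         "categories": [{"id": ..., "name": "object" | "tool"}, ...],
         "annotations": [{"id": ..., "image_id": ..., "category_id": ...,
                          "segmentation": [[x0, y0, x1, y1, ...]],
                          "score": ...}, ...]}

    Detections with score <= ``cfg.confidence_min`` are dropped; retained
    polygons are validated (>= 3 vertices, simple).  Malformed entries
    raise ``ValueError`` with the offending frame index.
    """
    cfg = cfg or AOIConfig()
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed annotation JSON ({exc})") from exc
    cat_names: dict[int, str] = {}
    for cat in doc.get("categories", []):
        name = cat.get("name")
        if name not in (OBJECT, TOOL):
            raise ValueError(f"{path}: unknown class label {name!r} (category id {cat.get('id')})")
        cat_names[cat["id"]] = name
    images = sorted(doc.get("images", []), key=lambda im: im.get("frame_index", im["id"]))
    frames: dict[int, FrameAnnotation] = {}
    for im in images:
        fi = int(im.get("frame_index", im["id"]))
        if "t" not in im:
            raise ValueError(f"{path}: image for frame {fi} lacks a timestamp 't'")
        if fi in frames:
            raise ValueError(f"{path}: duplicate frame_index {fi}")
        frames[fi] = FrameAnnotation(frame_index=fi, t=float(im["t"]))
    by_image = {im["id"]: int(im.get("frame_index", im["id"])) for im in images}
    for ann in doc.get("annotations", []):
        fi = by_image.get(ann.get("image_id"))
        if fi is None:
            raise ValueError(f"{path}: annotation {ann.get('id')} references unknown image")
        score = float(ann.get("score", 1.0))
        if score <= cfg.confidence_min:
            continue
        seg = ann.get("segmentation")
        if not seg or not seg[0] or len(seg[0]) % 2 != 0 or len(seg[0]) < 6:
            raise ValueError(
                f"{path}: frame {fi}: annotation {ann.get('id')} has a degenerate polygon"
            )
        poly = np.asarray(seg[0], dtype=float).reshape(-1, 2)
        inst = DetectedInstance(
            instance_id=int(ann.get("instance_id", ann.get("id", 0))),
            label=cat_names[ann["category_id"]],
            polygon=poly,
            confidence=score,
        )
        inst.validate(where=f"{path}: frame {fi}: ")
        frames[fi].instances.append(inst)
    out = [frames[fi] for fi in sorted(frames)]
    ts = [f.t for f in out]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"{path}: frame timestamps decrease with frame index")
    return out


def write_annotations(frames: Sequence[FrameAnnotation], path: str | Path) -> None:
    """Write frames back to the COCO-style JSON dialect read by ``load_annotations``."""
    images = [{"id": f.frame_index, "frame_index": f.frame_index, "t": f.t} for f in frames]
    categories = [{"id": 1, "name": OBJECT}, {"id": 2, "name": TOOL}]
    annotations = []
    aid = 0
    for f in frames:
        for inst in f.instances:
            annotations.append(
                {
                    "id": aid,
                    "image_id": f.frame_index,
                    "category_id": 1 if inst.label == OBJECT else 2,
                    "segmentation": [np.round(inst.polygon, 3).ravel().tolist()],
                    "score": round(float(inst.confidence), 4),
                    "instance_id": inst.instance_id,
                }
            )
            aid += 1
    Path(path).write_text(
        json.dumps({"images": images, "categories": categories, "annotations": annotations})
    )


def filter_frame(frame: FrameAnnotation, cfg: AOIConfig) -> FrameAnnotation:
    """Apply the confidence threshold to an in-memory frame (loader-equivalent)."""
    kept = [i for i in frame.instances if i.confidence > cfg.confidence_min]
    if len(kept) == len(frame.instances):
        return frame
    return FrameAnnotation(frame_index=frame.frame_index, t=frame.t, instances=kept)


def filter_frames(frames: Iterable[FrameAnnotation], cfg: AOIConfig) -> list[FrameAnnotation]:
    return [filter_frame(f, cfg) for f in frames]


# ---------------------------------------------------------------------------
# Hold states and hit testing
# ---------------------------------------------------------------------------


def _bounds_overlap(a: DetectedInstance, b: DetectedInstance) -> bool:
    ax0, ay0, ax1, ay1 = a.bounds
    bx0, by0, bx1, by1 = b.bounds
    return ax0 <= bx1 and bx0 <= ax1 and ay0 <= by1 and by0 <= ay1


def _hold_state(obj: DetectedInstance, tools: Sequence[DetectedInstance]) -> HoldState:
    n = 0
    for tool in tools:
        if not _bounds_overlap(obj, tool):
            continue
        if obj.shape.intersection(tool.shape).area > _INTERSECTION_AREA_TOL:
            n += 1
            if n >= 2:
                break
    return HoldState(min(n, 2))


def object_states(frame: FrameAnnotation) -> dict[int, HoldState]:
    """Hold state of every object in a frame.

    The state is the number of tool polygons whose intersection area with
    the object polygon exceeds a small tolerance, clamped at two.
    """
    tools = frame.by_label(TOOL)
    return {o.instance_id: _hold_state(o, tools) for o in frame.by_label(OBJECT)}


def dilated_hit(
    point: tuple[float, float], inst: DetectedInstance, radius: float
) -> bool:
    """True iff ``point`` is inside the polygon or within ``radius`` px of its boundary."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    px, py = point
    x0, y0, x1, y1 = inst.bounds
    if not (x0 - radius <= px <= x1 + radius and y0 - radius <= py <= y1 + radius):
        return False
    return inst.distance(px, py) <= radius


def classify_fixation_frame(
    fix: Fixation,
    frame: FrameAnnotation,
    states: Mapping[int, HoldState] | None = None,
    cfg: AOIConfig | None = None,
    fixation_id: int = 0,
    point: tuple[float, float] | None = None,
) -> HitRecord:
    """Assign one AOI category to a (fixation, frame) pair.

    The test point defaults to the fixation centroid; callers may pass a
    frame-specific ``point`` (see ``AOIConfig.hit_point``).  If it hits
    any object, the category follows the hit object's hold state with
    precedence HELD_TWO > HELD_ONE > NOT_HELD; otherwise a tool hit
    yields ``TOOL_ONLY``; otherwise ``NONE``.  Hold states are computed
    lazily for the hit objects unless a precomputed ``states`` map is
    supplied.
    """
    cfg = cfg or AOIConfig()
    if point is None:
        point = (fix.cx, fix.cy)
    r = cfg.dilation_radius
    near = frame.instances_near(point, r)
    hit_objects = [
        o for o in near if o.label == OBJECT and o.distance(*point) <= r
    ]
    if hit_objects:
        category = _object_hit_category(point, hit_objects, frame, states, cfg)
    else:
        tool_hit = any(t.label == TOOL and t.distance(*point) <= r for t in near)
        category = AOICategory.TOOL_ONLY if tool_hit else AOICategory.NONE
    return HitRecord(frame_index=frame.frame_index, category=category, fixation_id=fixation_id)


def _object_hit_category(
    point: tuple[float, float],
    hit_objects: Sequence[DetectedInstance],
    frame: FrameAnnotation,
    states: Mapping[int, HoldState] | None,
    cfg: AOIConfig,
) -> AOICategory:
    tools = frame.by_label(TOOL)
    if cfg.category_semantics == "object_state":
        if states is not None:
            best = max(states.get(o.instance_id, HoldState.NOT_HELD) for o in hit_objects)
        else:
            best = max(frame.hold_state(o) for o in hit_objects)
        return _STATE_TO_CATEGORY[HoldState(best)]
    # pixel_intersection: count tools whose literal overlap region with a
    # hit object contains the point (within the dilation radius).
    pt = Point(point)
    best_k = 0
    for obj in hit_objects:
        k = 0
        for tool in tools:
            if not _bounds_overlap(obj, tool):
                continue
            inter = obj.shape.intersection(tool.shape)
            if inter.area > _INTERSECTION_AREA_TOL and inter.distance(pt) <= cfg.dilation_radius:
                k += 1
        best_k = max(best_k, min(k, 2))
    return _STATE_TO_CATEGORY[HoldState(best_k)]


def map_fixations_to_frames(
    fixations: Sequence[Fixation],
    frames: Sequence[FrameAnnotation],
    cfg: AOIConfig | None = None,
    trace: "GazeTrace | None" = None,
) -> list[HitRecord]:
    """Score every fixation against every frame it spans in time.

    A fixation covers all frames whose timestamp lies in the closed
    interval [t_start, t_end]; each (fixation, frame) pair yields exactly
    one :class:`HitRecord`.  With ``cfg.hit_point == 'per_frame'`` and a
    ``trace`` supplied, the point tested against a frame is the mean of
    the fixation's valid member samples within half a frame period of
    the frame timestamp (so hits follow moving AOIs during pursuit);
    otherwise the whole-fixation centroid is used.  Frame-level
    deduplication (a frame credited at most once per category) is applied
    downstream when rates are computed.
    """
    cfg = cfg or AOIConfig()
    if not fixations or not frames:
        return []
    ft = np.asarray([f.t for f in frames])
    half_period = 0.5 * float(np.median(np.diff(ft))) if ft.size > 1 else 0.02
    per_frame = cfg.hit_point == "per_frame" and trace is not None
    if per_frame:
        tv = trace.t[trace.valid]
        xv = trace.x[trace.valid]
        yv = trace.y[trace.valid]
    records: list[HitRecord] = []
    for fid, fix in enumerate(fixations):
        lo = int(np.searchsorted(ft, fix.t_start, side="left"))
        hi = int(np.searchsorted(ft, fix.t_end, side="right"))
        for j in range(lo, hi):
            frame = frames[j]
            point = None
            if per_frame:
                a = int(np.searchsorted(tv, max(frame.t - half_period, fix.t_start)))
                b = int(np.searchsorted(tv, min(frame.t + half_period, fix.t_end), side="right"))
                if b > a:
                    point = (float(xv[a:b].mean()), float(yv[a:b].mean()))
            records.append(
                classify_fixation_frame(
                    fix, frame, states=None, cfg=cfg, fixation_id=fid, point=point
                )
            )
    if not records and (
        max(f.t_end for f in fixations) < ft[0] or min(f.t_start for f in fixations) > ft[-1]
    ):
        warnings.warn(
            "no fixation overlaps the frame time span; check that gaze and "
            "annotations share a clock",
            UserWarning,
        )
    return records


def write_hits_csv(hits: Sequence[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": [h.frame_index for h in hits],
            "category": [h.category.value for h in hits],
            "fixation_id": [h.fixation_id for h in hits],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tool identity tracking (left/right graspers)
# ---------------------------------------------------------------------------


def track_tools(
    frames: Sequence[FrameAnnotation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign per-frame left/right identity to the detected tools.

    Identity is by centroid x-order on first sight, then maintained by
    nearest-centroid continuity so identities survive tools crossing.
    Returns ``(t, left, right)`` where ``left``/``right`` are (n, 2)
    centroid arrays with NaN rows where the grasper was not detected.
    """
    from math import hypot

    n = len(frames)
    t = np.asarray([f.t for f in frames], dtype=float)
    left = np.full((n, 2), np.nan)
    right = np.full((n, 2), np.nan)
    prev_l: tuple[float, float] | None = None
    prev_r: tuple[float, float] | None = None
    for i, frame in enumerate(frames):
        tools = frame.by_label(TOOL)
        if len(tools) > 2:
            tools = sorted(tools, key=lambda x: -x.confidence)[:2]
        cents = [tl.centroid for tl in tools]
        if len(cents) == 2:
            a, b = cents
            if prev_l is not None and prev_r is not None:
                keep = hypot(a[0] - prev_l[0], a[1] - prev_l[1]) + hypot(
                    b[0] - prev_r[0], b[1] - prev_r[1]
                )
                swap = hypot(b[0] - prev_l[0], b[1] - prev_l[1]) + hypot(
                    a[0] - prev_r[0], a[1] - prev_r[1]
                )
                if swap < keep:
                    a, b = b, a
            elif a[0] > b[0]:
                a, b = b, a
            left[i] = a
            right[i] = b
            prev_l, prev_r = a, b
        elif len(cents) == 1:
            c = cents[0]
            if prev_l is not None and prev_r is not None:
                if hypot(c[0] - prev_l[0], c[1] - prev_l[1]) <= hypot(
                    c[0] - prev_r[0], c[1] - prev_r[1]
                ):
                    left[i] = c
                    prev_l = c
                else:
                    right[i] = c
                    prev_r = c
            elif prev_l is not None or prev_r is not None or c[0] <= _midline(frames):
                left[i] = c
                prev_l = c
            else:
                right[i] = c
                prev_r = c
    return t, left, right


def _midline(frames: Sequence[FrameAnnotation]) -> float:
    xs = [
        inst.bounds[2]
        for f in frames[: min(len(frames), 50)]
        for inst in f.instances
    ]
    return 0.5 * max(xs) if xs else np.inf
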