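"""Synthetic peg-transfer session generator.

Produces complete sessions -- per-frame polygon annotations, a raw gaze
trace and session metadata -- for three skill archetypes (HIGH / MID /
LOW) with known ground truth, so every downstream stage of the pipeline
can be exercised and benchmarked without real recordings.

A session scripts six object transfers: the left grasper approaches an
object, picks it up, carries it (with exploratory wander) to the center,
hands it off mid-air to the right grasper (both tools on the object), and
the right grasper carries and places it on the opposite side.  Tool tips
move piecewise-linearly at the archetype's ``speed_scale``; idle time is
filled with wander at the same speed so the measured mean tool speed
tracks ``speed_scale``.  Gaze is a sequence of dwells whose targets are
drawn from the archetype's gaze policy over {held object, next object,
tool, background}, with isotropic Gaussian jitter.  Drops (errors)
teleport the object to a free location and pull gaze onto it while it is
not held.

Archetype parameter defaults are design choices (not measured values);
they are set up so that object-directed fixation rates decrease and
tool-following rate, not-moving rate and tool speed increase from HIGH to
LOW, with MID close to LOW on the object-directed metrics and close to
HIGH on the tool-related ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from gazeskill import aoi as aoi_mod
from gazeskill import gaze as gaze_mod
from gazeskill.aoi import OBJECT, TOOL, DetectedInstance, FrameAnnotation
from gazeskill.gaze import GazeTrace

__all__ = [
    "ARCHETYPES",
    "ArchetypeParams",
    "SimConfig",
    "SimSession",
    "simulate_session",
    "simulate_cohort",
    "write_fixtures",
    "read_fixtures",
]

ARCHETYPES = ("HIGH", "MID", "LOW")
GAZE_TARGETS = ("held", "next", "tool", "background")

# Fixed scene geometry (fractions of arena size; shapes in absolute px).
_TRIANGLE_SIDE = 60.0
_TRIANGLE_R = _TRIANGLE_SIDE / np.sqrt(3.0)
_TOOL_LENGTH = 150.0
_TOOL_WIDTH = 26.0
_GRASP_PAUSE = 0.20
_TRANSFER_PAUSE = 0.40
_PLACE_PAUSE = 0.20
_WANDER_RADIUS = 70.0
_SHAFT_OFFSET = 60.0  # gaze-at-tool point, behind the tip along the shaft


@dataclass(frozen=True)
class ArchetypeParams:
    """Behavioral parameters of one skill archetype."""

    gaze_policy: dict[str, float]
    speed_scale: float
    duration_mean: float
    duration_sd: float
    error_rate: float

    def __post_init__(self) -> None:
        if set(self.gaze_policy) != set(GAZE_TARGETS):
            raise ValueError(f"gaze_policy must have keys {GAZE_TARGETS}")
        probs = np.array([self.gaze_policy[k] for k in GAZE_TARGETS])
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("gaze_policy probabilities must be in [0,1] and sum to 1")
        if self.speed_scale <= 0 or self.duration_mean <= 0 or self.duration_sd < 0:
            raise ValueError("speed_scale and durations must be positive")
        if self.error_rate < 0:
            raise ValueError("error_rate must be >= 0")


def _default_archetypes() -> dict[str, ArchetypeParams]:
    return {
        "HIGH": ArchetypeParams(
            gaze_policy={"held": 0.60, "next": 0.04, "tool": 0.10, "background": 0.26},
            speed_scale=300.0,
            duration_mean=120.0,
            duration_sd=15.0,
            error_rate=0.4,
        ),
        "MID": ArchetypeParams(
            gaze_policy={"held": 0.30, "next": 0.08, "tool": 0.14, "background": 0.48},
            speed_scale=330.0,
            duration_mean=233.0,
            duration_sd=35.0,
            error_rate=0.8,
        ),
        "LOW": ArchetypeParams(
            gaze_policy={"held": 0.25, "next": 0.22, "tool": 0.45, "background": 0.08},
            speed_scale=480.0,
            duration_mean=282.0,
            duration_sd=40.0,
            error_rate=1.2,
        ),
    }


def _default_mix() -> dict[str, float]:
    return {"HIGH": 5 / 24, "MID": 14 / 24, "LOW": 5 / 24}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation configuration."""

    n_sessions: int = 24
    archetype_mix: dict[str, float] = field(default_factory=_default_mix)
    fps: float = 25.0
    gaze_hz: float = 50.0
    arena: tuple[int, int] = (1920, 1080)
    archetypes: dict[str, ArchetypeParams] = field(default_factory=_default_archetypes)
    jitter_sd: float = 8.0
    invalid_rate: float = 0.025
    ghost_rate: float = 0.01
    tool_miss_rate: float = 0.01
    drop_dwell: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.fps <= 0 or self.gaze_hz <= 0:
            raise ValueError("fps and gaze_hz must be positive")
        if not self.archetype_mix:
            raise ValueError("archetype_mix must not be empty")
        unknown = set(self.archetype_mix) - set(self.archetypes)
        if unknown:
            raise ValueError(f"archetype_mix references unknown archetypes {sorted(unknown)}")
        vals = np.array(list(self.archetype_mix.values()), dtype=float)
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must be >= 0 and sum to 1")

    @classmethod
    def fast(cls, **overrides) -> "SimConfig":
        """Short sessions for tests/benchmarks.

        Durations are scaled down and tool speeds scaled up (preserving
        the between-archetype ratios, i.e. the effect sizes) so that a
        24-session cohort simulates and extracts in seconds.
        """
        arch = _default_archetypes()
        fast_arch = {
            "HIGH": dataclasses.replace(
                arch["HIGH"], speed_scale=1200.0, duration_mean=24.0, duration_sd=2.5
            ),
            "MID": dataclasses.replace(
                arch["MID"], speed_scale=1320.0, duration_mean=40.0, duration_sd=9.0
            ),
            "LOW": dataclasses.replace(
                arch["LOW"], speed_scale=1920.0, duration_mean=48.0, duration_sd=10.0
            ),
        }
        kwargs = {"archetypes": fast_arch}
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["arena"] = list(self.arena)
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "archetypes" in doc:
            doc["archetypes"] = {
                k: ArchetypeParams(**v) for k, v in doc["archetypes"].items()
            }
        if "arena" in doc:
            doc["arena"] = tuple(doc["arena"])
        return cls(**doc)


@dataclass
class SimSession:
    """One simulated session with its ground truth."""

    session_id: str
    participant_id: str
    trainer: str
    truth_archetype: str
    completion_time: float
    errors: int
    frames: list[FrameAnnotation]
    gaze: GazeTrace


# ---------------------------------------------------------------------------
# Piecewise-linear keyframe tracks
# ---------------------------------------------------------------------------


class _Track:
    """A 2-D position as piecewise-linear keyframes in time."""

    def __init__(self, t0: float, p0) -> None:
        self.tk: list[float] = [float(t0)]
        self.xk: list[float] = [float(p0[0])]
        self.yk: list[float] = [float(p0[1])]
        self._ta = None

    @property
    def t(self) -> float:
        return self.tk[-1]

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.xk[-1], self.yk[-1]])

    def add(self, t: float, p) -> None:
        if t <= self.tk[-1] + 1e-9:
            return
        self.tk.append(float(t))
        self.xk.append(float(p[0]))
        self.yk.append(float(p[1]))

    def teleport(self, p) -> None:
        self.add(self.tk[-1] + 1e-3, p)

    def hold(self, until: float) -> None:
        self.add(until, self.pos)

    def move_to(self, p, speed: float) -> float:
        d = float(np.hypot(p[0] - self.xk[-1], p[1] - self.yk[-1]))
        self.add(self.t + d / speed, p)
        return self.t

    def wander(self, duration: float, anchor, radius: float, speed: float, rng) -> None:
        t_end = self.t + duration
        while self.t < t_end - 1e-6:
            r = radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            target = np.array([anchor[0] + r * np.cos(th), anchor[1] + r * np.sin(th)])
            d = float(np.linalg.norm(target - self.pos))
            leg = d / speed
            remain = t_end - self.t
            if leg >= remain:
                target = self.pos + (target - self.pos) * (remain / max(leg, 1e-12))
                leg = remain
            self.add(self.t + leg, target)

    def at(self, tq: np.ndarray) -> np.ndarray:
        if self._ta is None:
            self._ta = np.asarray(self.tk)
            self._xa = np.asarray(self.xk)
            self._ya = np.asarray(self.yk)
        return np.column_stack(
            (np.interp(tq, self._ta, self._xa), np.interp(tq, self._ta, self._ya))
        )


def _move_group(tracks: Sequence[_Track], p, speed: float) -> float:
    arrival = None
    lead = tracks[0]
    d = float(np.linalg.norm(np.asarray(p, dtype=float) - lead.pos))
    arrival = lead.t + d / speed
    for tr in tracks:
        tr.add(arrival, p)
    return arrival


def _wander_group(tracks: Sequence[_Track], duration, anchor, radius, speed, rng) -> None:
    lead = tracks[0]
    start = len(lead.tk)
    lead.wander(duration, anchor, radius, speed, rng)
    for tr in tracks[1:]:
        for t, x, y in zip(lead.tk[start:], lead.xk[start:], lead.yk[start:]):
            tr.add(t, (x, y))


def _bridge(track: _Track, t_until: float, dest, anchor, speed: float, rng) -> None:
    """Wander near ``anchor`` then arrive at ``dest`` at about ``t_until``."""
    while True:
        direct = float(np.linalg.norm(np.asarray(dest, dtype=float) - track.pos)) / speed
        slack = t_until - track.t - direct
        if slack < 0.2:
            break
        track.wander(min(slack * 0.6, 1.0), anchor, _WANDER_RADIUS, speed, rng)
    track.move_to(dest, speed)
    track.hold(t_until)


# ---------------------------------------------------------------------------
# Session scripting
# ---------------------------------------------------------------------------


def _scene(arena: tuple[int, int]) -> dict:
    w, h = arena
    rows = np.linspace(0.15, 0.85, 6) * h
    return {
        "starts": [np.array([0.17 * w, y]) for y in rows],
        "targets": [np.array([0.83 * w, y]) for y in rows],
        "center": np.array([0.50 * w, 0.52 * h]),
        "left_home": np.array([0.36 * w, 0.90 * h]),
        "right_home": np.array([0.64 * w, 0.90 * h]),
        "left_port": np.array([0.03 * w, 1.02 * h]),
        "right_port": np.array([0.97 * w, 1.02 * h]),
        "right_anchor": np.array([0.66 * w, 0.64 * h]),
        "wait_offset": np.array([0.09 * w, 0.03 * h]),
    }


def _estimate_scripted_time(scene: dict, speed: float) -> float:
    est = float(np.linalg.norm(scene["starts"][0] - scene["left_home"])) / speed
    hop = float(np.linalg.norm(scene["wait_offset"]))
    for i in range(6):
        est += _GRASP_PAUSE + _TRANSFER_PAUSE + _PLACE_PAUSE
        est += float(np.linalg.norm(scene["center"] - scene["starts"][i])) / speed
        est += float(np.linalg.norm(scene["targets"][i] - scene["center"])) / speed
        if i < 5:
            est += hop / speed
    return est


def _free_drop_point(scene: dict, arena, rng) -> np.ndarray:
    w, h = arena
    keep_away = scene["starts"] + scene["targets"] + [scene["center"]]
    for _ in range(30):
        p = np.array([rng.uniform(0.30 * w, 0.70 * w), rng.uniform(0.62 * h, 0.86 * h)])
        if all(np.linalg.norm(p - q) >= 140.0 for q in keep_away):
            return p
    return p


def _build_script(params: ArchetypeParams, cfg: SimConfig, rng):
    scene = _scene(cfg.arena)
    v = params.speed_scale
    duration_target = max(
        rng.normal(params.duration_mean, params.duration_sd),
        _estimate_scripted_time(scene, v) + 1.0,
    )
    fill = max(duration_target - _estimate_scripted_time(scene, v), 1.0)
    per_wander = fill / 12.0

    n_drops = int(min(rng.poisson(params.error_rate), 3))
    drop_cycles = set(rng.choice(6, size=n_drops, replace=False).tolist())

    left = _Track(0.0, scene["left_home"])
    right = _Track(0.0, scene["right_home"])
    objs = [_Track(0.0, s) for s in scene["starts"]]

    left_carry: list[tuple[float, float]] = []
    right_carry: list[tuple[float, float]] = []
    cycles: list[tuple[float, float, int]] = []  # (start, end, object index)
    pick_times: list[float] = []
    drop_windows: list[tuple[float, float, int]] = []

    for i in range(6):
        o = objs[i]
        t_cycle0 = left.t
        left.move_to(scene["starts"][i], v)
        t_arrive = left.t
        pick_times.append(t_arrive)
        left.hold(t_arrive + _GRASP_PAUSE)
        o.hold(t_arrive + _GRASP_PAUSE)
        # left carry with exploratory wander, then to center
        mid_l = 0.5 * (scene["starts"][i] + scene["center"])
        _wander_group([left, o], per_wander, mid_l, _WANDER_RADIUS, v, rng)
        t_c = _move_group([left, o], scene["center"], v)
        # right grasper arrives for the mid-air transfer
        _bridge(right, t_c, scene["center"], scene["right_anchor"], v, rng)
        t_tr_end = t_c + _TRANSFER_PAUSE
        for tr in (left, right, o):
            tr.hold(t_tr_end)
        left_carry.append((t_arrive, t_tr_end))
        # right carry
        if i in drop_cycles:
            mid = 0.5 * (scene["center"] + scene["targets"][i])
            _move_group([right, o], mid, v)
            t_d = right.t
            d_point = _free_drop_point(scene, cfg.arena, rng)
            o.teleport(d_point)
            drop_windows.append((t_d, t_d + cfg.drop_dwell, i))
            stand_off = d_point + np.array([0.0, -150.0])
            right.move_to(stand_off, v)
            right.wander(
                max(t_d + cfg.drop_dwell - right.t, 0.0), stand_off, 60.0, v, rng
            )
            right.move_to(d_point, v)
            t_regrasp = right.t + _GRASP_PAUSE
            right.hold(t_regrasp)
            o.hold(t_regrasp)
            t_place = _move_group([right, o], scene["targets"][i], v)
        else:
            mid_r = 0.5 * (scene["center"] + scene["targets"][i])
            _wander_group([right, o], per_wander, mid_r, _WANDER_RADIUS, v, rng)
            t_place = _move_group([right, o], scene["targets"][i], v)
        t_end = t_place + _PLACE_PAUSE
        right.hold(t_end)
        o.hold(t_end)
        right_carry.append((t_c, t_end))
        cycles.append((t_cycle0, t_end, i))
        # left repositions near the next start while the right grasper works
        if i < 5:
            next_anchor = scene["starts"][i + 1] + scene["wait_offset"]
            _bridge(left, t_end, next_anchor, next_anchor, v, rng)
        else:
            left.wander(max(t_end - left.t, 0.0), scene["left_home"], _WANDER_RADIUS, v, rng)
            left.hold(t_end)

    completion = cycles[-1][1]
    return {
        "scene": scene,
        "left": left,
        "right": right,
        "objects": objs,
        "left_carry": left_carry,
        "right_carry": right_carry,
        "cycles": cycles,
        "pick_times": pick_times,
        "drop_windows": drop_windows,
        "completion": completion,
        "n_drops": n_drops,
    }


# ---------------------------------------------------------------------------
# Rendering: frames and gaze
# ---------------------------------------------------------------------------

_TRI_OFFSETS = _TRIANGLE_R * np.column_stack(
    (np.cos(np.deg2rad([90.0, 210.0, 330.0])), np.sin(np.deg2rad([90.0, 210.0, 330.0])))
)


def _tool_quads(tips: np.ndarray, port: np.ndarray) -> np.ndarray:
    """(n, 4, 2) rectangle vertices for a grasper with given tip positions."""
    vec = tips - port
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    u = vec / norm
    nvec = np.column_stack((-u[:, 1], u[:, 0]))
    hw = 0.5 * _TOOL_WIDTH
    c0 = tips + hw * nvec
    c1 = tips - hw * nvec
    c2 = tips - _TOOL_LENGTH * u - hw * nvec
    c3 = tips - _TOOL_LENGTH * u + hw * nvec
    return np.stack((c0, c1, c2, c3), axis=1)


def _render_frames(script: dict, cfg: SimConfig, rng) -> list[FrameAnnotation]:
    T = script["completion"]
    n_frames = max(int(round(T * cfg.fps)), 2)
    tf = np.arange(n_frames) / cfg.fps
    obj_pos = [tr.at(tf) for tr in script["objects"]]
    left_tip = script["left"].at(tf)
    right_tip = script["right"].at(tf)
    scene = script["scene"]
    left_quads = _tool_quads(left_tip, scene["left_port"])
    right_quads = _tool_quads(right_tip, scene["right_port"])
    conf = rng.uniform(0.62, 0.99, size=(n_frames, 8))
    miss = rng.random((n_frames, 2)) < cfg.tool_miss_rate
    ghost = rng.random(n_frames) < cfg.ghost_rate
    w, h = cfg.arena
    frames: list[FrameAnnotation] = []
    for k in range(n_frames):
        instances: list[DetectedInstance] = []
        for j in range(6):
            instances.append(
                DetectedInstance(
                    instance_id=j,
                    label=OBJECT,
                    polygon=_TRI_OFFSETS + obj_pos[j][k],
                    confidence=float(conf[k, j]),
                )
            )
        if not miss[k, 0]:
            instances.append(
                DetectedInstance(
                    instance_id=10, label=TOOL, polygon=left_quads[k], confidence=float(conf[k, 6])
                )
            )
        if not miss[k, 1]:
            instances.append(
                DetectedInstance(
                    instance_id=11, label=TOOL, polygon=right_quads[k], confidence=float(conf[k, 7])
                )
            )
        if ghost[k]:
            gp = np.array([rng.uniform(0.05 * w, 0.95 * w), rng.uniform(0.05 * h, 0.95 * h)])
            instances.append(
                DetectedInstance(
                    instance_id=99,
                    label=OBJECT,
                    polygon=_TRI_OFFSETS + gp,
                    confidence=float(rng.uniform(0.05, 0.45)),
                )
            )
        frames.append(FrameAnnotation(frame_index=k, t=float(tf[k]), instances=instances))
    return frames


def _interval_lookup(intervals: Sequence[tuple[float, float]], t: float) -> bool:
    return any(a <= t <= b for a, b in intervals)


def _render_gaze(script: dict, params: ArchetypeParams, cfg: SimConfig, rng) -> GazeTrace:
    T = script["completion"]
    scene = script["scene"]
    n = int(np.floor(T * cfg.gaze_hz)) + 1
    ts = np.arange(n) / cfg.gaze_hz
    x = np.empty(n)
    y = np.empty(n)

    probs = np.array([params.gaze_policy[k] for k in GAZE_TARGETS])
    events: list[tuple[float, float, str]] = []
    t = 0.0
    while t < T:
        d = rng.uniform(0.12, 0.32)
        cat = GAZE_TARGETS[int(rng.choice(4, p=probs))]
        events.append((t, min(t + d, T), cat))
        t += d

    cycles = script["cycles"]
    cycle_starts = np.array([c[0] for c in cycles])
    pick_times = script["pick_times"]
    objects = script["objects"]
    targets = scene["targets"]
    w, h = cfg.arena
    keep_away = scene["starts"] + scene["targets"] + [scene["center"]]

    def active_object(tm: float) -> int:
        j = int(np.searchsorted(cycle_starts, tm, side="right")) - 1
        return cycles[max(j, 0)][2]

    def next_pending(tm: float) -> np.ndarray:
        for j, pt in enumerate(pick_times):
            if pt > tm:
                return scene["starts"][j]
        return targets[0]

    def idle_tool(tm: float) -> tuple[_Track, np.ndarray]:
        if _interval_lookup(script["right_carry"], tm) and not _interval_lookup(
            script["left_carry"], tm
        ):
            return script["left"], scene["left_port"]
        return script["right"], scene["right_port"]

    def background_point() -> np.ndarray:
        for _ in range(20):
            p = np.array([rng.uniform(0.06 * w, 0.94 * w), rng.uniform(0.06 * h, 0.94 * h)])
            if all(np.linalg.norm(p - q) >= 150.0 for q in keep_away):
                return p
        return p

    for e, (t0, t1, cat) in enumerate(events):
        lo = int(np.searchsorted(ts, t0, side="left"))
        hi = n if e == len(events) - 1 else int(np.searchsorted(ts, t1, side="left"))
        if hi <= lo:
            continue
        seg = ts[lo:hi]
        tm = 0.5 * (t0 + t1)
        if cat == "held":
            pos = objects[active_object(tm)].at(seg)
        elif cat == "next":
            pos = np.broadcast_to(next_pending(tm), (seg.size, 2))
        elif cat == "tool":
            track, port = idle_tool(tm)
            tips = track.at(seg)
            vec = tips - port
            nrm = np.linalg.norm(vec, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            pos = tips - _SHAFT_OFFSET * vec / nrm
        else:
            pos = np.broadcast_to(background_point(), (seg.size, 2))
        x[lo:hi] = pos[:, 0]
        y[lo:hi] = pos[:, 1]

    # Drops pull gaze onto the (not moving) dropped object.
    for td0, td1, j in script["drop_windows"]:
        mask = (ts >= td0) & (ts <= min(td1, T))
        if mask.any():
            pos = objects[j].at(ts[mask])
            x[mask] = pos[:, 0]
            y[mask] = pos[:, 1]

    jitter = rng.normal(0.0, cfg.jitter_sd, size=(n, 2))
    x += jitter[:, 0]
    y += jitter[:, 1]
    valid = rng.random(n) >= cfg.invalid_rate
    return GazeTrace(t=ts, x=x, y=y, valid=valid)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def simulate_session(
    archetype: str,
    config: SimConfig,
    seed: int,
    *,
    trainer: str = "adult",
    participant_id: str = "P000",
    session_id: str = "S000",
) -> SimSession:
    """Simulate one session of the given archetype.

    Identical ``(archetype, config, seed)`` always produce identical
    sessions.
    """
    if archetype not in config.archetypes:
        raise ValueError(
            f"invalid archetype {archetype!r}; expected one of {sorted(config.archetypes)}"
        )
    rng = np.random.default_rng(seed)
    params = config.archetypes[archetype]
    script = _build_script(params, config, rng)
    frames = _render_frames(script, config, rng)
    trace = _render_gaze(script, params, config, rng)
    return SimSession(
        session_id=session_id,
        participant_id=participant_id,
        trainer=trainer,
        truth_archetype=archetype,
        completion_time=float(script["completion"]),
        errors=int(script["n_drops"]),
        frames=frames,
        gaze=trace,
    )


def _archetype_counts(config: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_sessions over the mix."""
    names = list(config.archetype_mix)
    quotas = np.array([config.archetype_mix[a] * config.n_sessions for a in names])
    counts = np.floor(quotas).astype(int)
    rem = config.n_sessions - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for j in order[:rem]:
        counts[j] += 1
    return dict(zip(names, counts.tolist()))


def simulate_cohort(config: SimConfig) -> tuple[list[SimSession], pd.DataFrame]:
    """Simulate a cohort; returns the sessions and a ground-truth table."""
    counts = _archetype_counts(config)
    labels = [a for a in counts for _ in range(counts[a])]
    rng = np.random.default_rng(config.seed)
    rng.shuffle(labels)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_sessions, dtype=np.uint64)
    sessions = []
    for i, arch in enumerate(labels):
        sessions.append(
            simulate_session(
                arch,
                config,
                int(seeds[i]),
                trainer="pediatric" if i % 2 else "adult",
                participant_id=f"P{i:03d}",
                session_id=f"S{i:03d}",
            )
        )
    truth = pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "participant_id": [s.participant_id for s in sessions],
            "archetype": [s.truth_archetype for s in sessions],
            "trainer": [s.trainer for s in sessions],
            "completion_time_s": [s.completion_time for s in sessions],
            "errors": [s.errors for s in sessions],
        }
    )
    return sessions, truth


def write_fixtures(sessions: Iterable[SimSession], out_dir: str | Path) -> list[Path]:
    """Write one annotation JSON, one gaze CSV per session plus metadata.csv."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    meta_rows = []
    for s in sessions:
        ann = out_dir / f"{s.session_id}_annotations.json"
        gz = out_dir / f"{s.session_id}_gaze.csv"
        try:
            aoi_mod.write_annotations(s.frames, ann)
            gaze_mod.write_gaze_csv(s.gaze, gz)
        except OSError as exc:
            raise OSError(f"failed writing fixtures for {s.session_id} under {out_dir}: {exc}") from exc
        written += [ann, gz]
        meta_rows.append(
            {
                "session_id": s.session_id,
                "participant_id": s.participant_id,
                "trainer": s.trainer,
                "completion_time_s": s.completion_time,
                "errors": s.errors,
                "truth_archetype": s.truth_archetype,
            }
        )
    meta = out_dir / "metadata.csv"
    pd.DataFrame(
        meta_rows,
        columns=[
            "session_id",
            "participant_id",
            "trainer",
            "completion_time_s",
            "errors",
            "truth_archetype",
        ],
    ).to_csv(meta, index=False)
    written.append(meta)
    return written


def read_fixtures(fixture_dir: str | Path, aoi_cfg=None) -> list[SimSession]:
    """Load sessions previously written by :func:`write_fixtures`."""
    fixture_dir = Path(fixture_dir)
    meta = pd.read_csv(fixture_dir / "metadata.csv")
    sessions = []
    for row in meta.itertuples():
        frames = aoi_mod.load_annotations(
            fixture_dir / f"{row.session_id}_annotations.json", aoi_cfg
        )
        trace = gaze_mod.read_gaze_csv(fixture_dir / f"{row.session_id}_gaze.csv")
        sessions.append(
            SimSession(
                session_id=row.session_id,
                participant_id=row.participant_id,
                trainer=row.trainer,
                truth_archetype=getattr(row, "truth_archetype", ""),
                completion_time=float(row.completion_time_s),
                errors=int(row.errors),
                frames=frames,
                gaze=trace,
            )
        )
    return sessions
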