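"""Detection-free online multi-target tracking.

Targets (tissues/organs or boluses) are registered manually with a
first-frame box — there is no detection-based birth model and no data
association: each target runs its own independent tracker, frames are
processed strictly in order with no lookahead, and inter-target
geometry (center distances, box overlaps) is compiled after tracking
from the stored trajectories, in the spine-rotated coordinate frame if
a rotation is supplied.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .bolus import init_bolus, step_bolus
from .config import RunConfig
from .core import BBox, Trajectory, VideoSequence
from .correlation import combined_init, combined_step
from .preprocess import RotationSpec, rotate_about

__all__ = ["TargetEntry", "TargetRegistry", "RelationRecord",
           "RelationReport", "register_target", "run_online"]


@dataclass
class TargetEntry:
    target_id: str
    kind: str                  # "organ" | "bolus"
    start_frame: int
    init_box: BBox
    state: object | None = None
    terminated: bool = False
    lost_streak: int = 0


@dataclass
class TargetRegistry:
    entries: list[TargetEntry] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [e.target_id for e in self.entries]


@dataclass(frozen=True)
class RelationRecord:
    frame_index: int
    id_a: str
    id_b: str
    distance: float            # center distance, px, rotated frame
    overlap: float             # box IoU


@dataclass
class RelationReport:
    records: list[RelationRecord] = field(default_factory=list)

    def pair(self, id_a: str, id_b: str) -> list[RelationRecord]:
        a, b = sorted((id_a, id_b))
        return [r for r in self.records if (r.id_a, r.id_b) == (a, b)]


def register_target(reg: TargetRegistry, target_id: str, kind: str,
                    frame_index: int, box: BBox) -> TargetRegistry:
    """Add a target; trackers are initialized lazily at their start frame."""
    if kind not in ("organ", "bolus"):
        raise ValueError(f"unknown target kind {kind!r}")
    if target_id in reg.ids():
        raise ValueError(f"duplicate target id {target_id!r}")
    if frame_index < 0:
        raise ValueError("start frame must be >= 0")
    reg.entries.append(TargetEntry(target_id, kind, frame_index, box))
    return reg


def _target_rng(seed: int, target_id: str) -> np.random.Generator:
    # per-target stream so any subset of targets reruns identically
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  zlib.crc32(target_id.encode())])


def run_online(reg: TargetRegistry, seq: VideoSequence,
               rot: RotationSpec | None = None,
               cfg: RunConfig | None = None,
               seed: int = 0) -> tuple[dict[str, Trajectory], RelationReport]:
    """Track every registered target online; relations compiled post-hoc.

    The result for frame ``t`` depends only on frames up to ``t``
    (prefix property), and each target's trajectory is identical to the
    one produced by running that target alone (independence).  A target
    whose tracker stays lost/occluded for more than
    ``cfg.max_lost_frames`` consecutive frames is terminated and never
    revived.
    """
    if not reg.entries:
        raise ValueError("no targets registered")
    cfg = cfg or RunConfig()
    frames = [rotate_about(f, rot) if rot is not None else f for f in seq]
    trajs: dict[str, Trajectory] = {e.target_id: Trajectory(e.target_id)
                                    for e in reg.entries}
    rngs = {e.target_id: _target_rng(seed, e.target_id) for e in reg.entries}
    for i, frame in enumerate(frames):
        for e in reg.entries:
            if e.terminated or i < e.start_frame:
                continue
            traj = trajs[e.target_id]
            if e.state is None:
                if e.kind == "organ":
                    e.state = combined_init(frame, e.init_box, cfg)
                else:
                    e.state = init_bolus(frame, e.init_box, cfg,
                                         rngs[e.target_id])
                traj.append(i, e.init_box, score=1.0)
                continue
            if e.kind == "organ":
                box, flags = combined_step(e.state, frame)
                lost = flags["occluded"]
                traj.append(i, box, score=flags["peak"])
            else:
                e.state = step_bolus(e.state, frame, cfg, rngs[e.target_id])
                lost = e.state.lost
                st = e.state
                ys, xs = np.nonzero(st.mask)
                centroid = (float(xs.mean()), float(ys.mean())) if ys.size \
                    else st.box.center
                traj.append(i, st.box, centroid,
                            score=0.0 if lost else 1.0)
            e.lost_streak = e.lost_streak + 1 if lost else 0
            if e.lost_streak > cfg.max_lost_frames:
                e.terminated = True
    report = RelationReport()
    by_frame = {tid: t.by_frame() for tid, t in trajs.items()}
    ids = sorted(trajs)
    for i in range(len(frames)):
        for a_idx in range(len(ids)):
            for b_idx in range(a_idx + 1, len(ids)):
                ra = by_frame[ids[a_idx]].get(i)
                rb = by_frame[ids[b_idx]].get(i)
                if ra is None or rb is None:
                    continue
                d = float(np.hypot(ra.centroid[0] - rb.centroid[0],
                                   ra.centroid[1] - rb.centroid[1]))
                report.records.append(RelationRecord(
                    i, ids[a_idx], ids[b_idx], d, ra.box.iou(rb.box)))
    return trajs, report
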