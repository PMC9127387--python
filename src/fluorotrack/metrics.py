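"""Evaluation metrics and the method-comparison harnesses.

APE (average pixel error) is the mean Euclidean distance between
predicted and true centers over common frames; AOR (average overlap
ratio) is the mean intersection-over-union of predicted and true boxes
or masks; accuracy is the fraction of frames with overlap at or above a
success threshold (0.5 by default, the standard tracking-benchmark
convention).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .background import egmm_masks, vibe_masks
from .config import RunConfig
from .core import BBox, Trajectory, VideoSequence
from .correlation import mosse_track, track_combined
from .framediff import track_improved_diff
from .synthetic import GroundTruth, TargetTruth

__all__ = [
    "EvalResult", "ape", "aor", "accuracy", "truth_trajectory",
    "mask_metrics", "compare_detectors", "compare_trackers",
    "DETECTOR_METHODS", "TRACKER_METHODS",
]


@dataclass(frozen=True)
class EvalResult:
    ape: float
    aor: float
    accuracy: float
    n_frames: int
    fps: float = float("nan")
    detection_rate: float = 1.0


def _common(pred: Trajectory, truth: Trajectory):
    p = pred.by_frame()
    t = truth.by_frame()
    common = sorted(set(p) & set(t))
    if not common:
        raise ValueError("trajectories share no frame indices")
    return [(p[i], t[i]) for i in common]


def ape(pred: Trajectory, truth: Trajectory) -> float:
    """Mean Euclidean center distance over matched frames (px)."""
    pairs = _common(pred, truth)
    d = [np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
         for a, b in pairs]
    return float(np.mean(d))


def aor(pred: Trajectory, truth: Trajectory) -> float:
    """Mean box IoU over matched frames; degenerate truth boxes skipped."""
    vals = []
    for a, b in _common(pred, truth):
        if b.box.area == 0:
            continue
        vals.append(a.box.iou(b.box))
    if not vals:
        raise ValueError("no valid truth boxes")
    return float(np.mean(vals))


def accuracy(pred: Trajectory, truth: Trajectory,
             threshold: float = 0.5) -> float:
    """Fraction of matched frames with box IoU >= ``threshold``."""
    vals = [a.box.iou(b.box) for a, b in _common(pred, truth)
            if b.box.area > 0]
    if not vals:
        raise ValueError("no valid truth boxes")
    return float(np.mean(np.asarray(vals) >= threshold))


def truth_trajectory(tt: TargetTruth) -> Trajectory:
    """Ground-truth record stream as a Trajectory for the metrics."""
    traj = Trajectory(tt.target_id)
    for i in tt.active_frames():
        traj.append(i, tt.boxes[i], tt.centroids[i], score=1.0)
    return traj


# ---------------------------------------------------------------------------
# detector comparison (improved frame difference vs ViBe vs EGMM)

def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask > 0)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def mask_metrics(pred_masks: list[np.ndarray], tt: TargetTruth,
                 frames: list[int] | None = None) -> EvalResult:
    """Centroid APE and mask IoU of per-frame masks against truth.

    Each predicted mask is reduced to its largest connected component
    (identical post-processing for every method).  Every frame scores:
    an empty prediction contributes IoU 0 and predicts its last known
    centroid (the frame center before any detection), so a method that
    detects rarely cannot win the error metric on its few hits.  The
    fraction of non-empty frames is reported as the detection rate.
    """
    if frames is None:
        frames = [i for i in tt.active_frames() if 1 <= i < len(pred_masks)]
    if not frames:
        raise ValueError("no evaluable frames")
    h, w = pred_masks[0].shape
    last_centroid = (w / 2.0, h / 2.0)
    errs, ious, hits = [], [], 0
    for i in frames:
        truth_mask = tt.masks[i]
        pm = _largest_component(pred_masks[i])
        inter = np.logical_and(pm, truth_mask).sum()
        union = np.logical_or(pm, truth_mask).sum()
        ious.append(inter / union if union else 0.0)
        if pm.any():
            hits += 1
            ys, xs = np.nonzero(pm)
            last_centroid = (float(xs.mean()), float(ys.mean()))
        tx, ty = tt.centroids[i]
        errs.append(np.hypot(last_centroid[0] - tx, last_centroid[1] - ty))
    return EvalResult(
        ape=float(np.mean(errs)),
        aor=float(np.mean(ious)),
        accuracy=float(np.mean(np.asarray(ious) >= 0.5)),
        n_frames=len(frames),
        detection_rate=hits / len(frames))


DETECTOR_METHODS = ("improved", "vibe", "egmm")


def compare_detectors(seq: VideoSequence, truth: GroundTruth,
                      target_id: str = "bolus",
                      methods=DETECTOR_METHODS,
                      cfg: RunConfig | None = None,
                      init_box: BBox | None = None,
                      seed: int = 0) -> dict[str, EvalResult]:
    """Run each detector on the same sequence and score it against truth."""
    cfg = cfg or RunConfig()
    tt = truth[target_id]
    if init_box is None:
        first = tt.active_frames()[0]
        init_box = tt.boxes[first].expand(1.6, seq.shape)
    results: dict[str, EvalResult] = {}
    frames = [i for i in tt.active_frames() if i >= 1]
    for method in methods:
        if method == "improved":
            _, masks = track_improved_diff(seq, init_box, cfg, seed=seed)
        elif method == "vibe":
            masks = vibe_masks(seq, cfg, seed=seed)
        elif method == "egmm":
            masks = egmm_masks(seq, cfg)
        else:
            raise ValueError(f"unknown detector {method!r}")
        results[method] = mask_metrics(masks, tt, frames)
    return results


# ---------------------------------------------------------------------------
# tracker comparison (MOSSE / CSK-like / KCF / DSST-like / combined)

TRACKER_METHODS = ("mosse", "csk_like", "kcf", "dsst_like", "combined")


def _run_tracker(method: str, seq: VideoSequence, box: BBox,
                 cfg: RunConfig) -> Trajectory:
    if method == "mosse":
        return mosse_track(seq, box, cfg)
    if method == "csk_like":       # kernelized, raw gray only, no scale
        return track_combined(seq, box,
                              cfg.replace(features="gray", correction=False),
                              use_scale=False)
    if method == "kcf":            # gray+HOG position filter only
        return track_combined(seq, box, cfg.replace(correction=False),
                              use_scale=False)
    if method == "dsst_like":      # position + scale, no edge correction
        return track_combined(seq, box, cfg.replace(correction=False),
                              use_scale=True)
    if method == "combined":       # position + scale + watershed correction
        return track_combined(seq, box, cfg, use_scale=True)
    raise ValueError(f"unknown tracker {method!r}")


def compare_trackers(seq: VideoSequence, truth: GroundTruth,
                     target_id: str = "organ",
                     methods=TRACKER_METHODS,
                     cfg: RunConfig | None = None,
                     init_box: BBox | None = None,
                     success_iou: float = 0.5) -> dict[str, EvalResult]:
    """Run each tracker from the same first-frame box and score it.

    Speed (frames/s) is measured and reported but is hardware-bound and
    never part of any assertion.
    """
    cfg = cfg or RunConfig()
    tt = truth[target_id]
    gt = truth_trajectory(tt)
    if init_box is None:
        init_box = tt.boxes[tt.active_frames()[0]]
    results: dict[str, EvalResult] = {}
    for method in methods:
        t0 = time.perf_counter()
        pred = _run_tracker(method, seq, init_box, cfg)
        dt = time.perf_counter() - t0
        results[method] = EvalResult(
            ape=ape(pred, gt), aor=aor(pred, gt),
            accuracy=accuracy(pred, gt, success_iou),
            n_frames=len(pred), fps=len(pred) / dt if dt > 0 else float("inf"))
    return results
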