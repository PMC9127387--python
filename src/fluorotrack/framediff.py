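"""Classical and improved inter-frame differencing.

The classical method marks a pixel foreground when the absolute
difference of consecutive frames exceeds a threshold.  Its weakness on
slow radiograph sequences is the *residual image*: pixels the target
vacated still differ strongly and show up as a false-positive ghost.
The improved method keeps the previous region of interest ``seg_p``,
computes a residual mask ``d_seg`` (old-region pixels that now look
like bright background), and combines

    seg_c = clip01(d_frame + seg_p - d_seg)

so the vacated area is explicitly subtracted.  Only the previous frame,
the previous region and the tracking box persist — no background model
is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import RunConfig
from .core import BBox, Trajectory, VideoSequence
from .preprocess import bilateral_denoise

__all__ = [
    "DiffMask", "RoiMasks", "classical_diff", "residual_mask",
    "eq12_combine", "improved_diff", "track_improved_diff",
    "classical_diff_masks",
]


@dataclass
class DiffMask:
    d_frame: np.ndarray          # binary {0,1}
    threshold: float
    pair: tuple[int, int] = (0, 1)


@dataclass
class RoiMasks:
    seg_p: np.ndarray            # previous region of interest
    d_seg: np.ndarray            # background residual to subtract
    seg_c: np.ndarray            # current region of interest (post-processed)
    seg_c_raw: np.ndarray        # raw arithmetic combination, pre-morphology
    d_frame: np.ndarray
    lost: bool = False


def classical_diff(f_prev: np.ndarray, f_cur: np.ndarray,
                   m: float) -> DiffMask:
    """Binary difference of two frames: foreground iff |cur - prev| > m."""
    if f_prev.shape != f_cur.shape:
        raise ValueError("frame shapes differ")
    d = np.abs(f_cur.astype(int) - f_prev.astype(int))
    return DiffMask((d > m).astype(np.uint8), float(m))


def residual_mask(seg_p: np.ndarray, f_cur: np.ndarray,
                  t_p: float) -> np.ndarray:
    """Old-region pixels that now read as bright background.

    ``d_seg[x, y] = 1`` iff the pixel was in the previous region and its
    current gray exceeds ``t_p`` — the point was vacated by the (dark)
    target and must be subtracted from the difference.
    """
    if seg_p.shape != f_cur.shape:
        raise ValueError("mask/frame shapes differ")
    return ((seg_p > 0) & (f_cur.astype(float) > t_p)).astype(np.uint8)


def eq12_combine(d_frame: np.ndarray, seg_p: np.ndarray,
                 d_seg: np.ndarray) -> np.ndarray:
    """Set combination ``(d_frame | seg_p) & ~d_seg``.

    Masks are sets: the difference and previous region are added up
    (union; 1 + 1 saturates at 1) and the residual is then subtracted,
    so a vacated pixel — present in all three masks — is removed.
    Plain elementwise ``d_frame + seg_p - d_seg`` would keep it
    (1 + 1 - 1 = 1) and the residual image would survive.
    """
    s = np.clip(d_frame.astype(int) + seg_p.astype(int), 0, 1) \
        - d_seg.astype(int)
    return np.clip(s, 0, 1).astype(np.uint8)


def _open_close(mask: np.ndarray) -> np.ndarray:
    se = np.ones((3, 3), dtype=bool)
    m = ndimage.binary_opening(mask > 0, structure=se)
    return ndimage.binary_closing(m, structure=se).astype(np.uint8)


def improved_diff(f_prev: np.ndarray, f_cur: np.ndarray, seg_p: np.ndarray,
                  box: BBox, cfg: RunConfig | None = None,
                  points: np.ndarray | None = None,
                  g_avg: float | None = None) -> RoiMasks:
    """One step of the improved inter-frame difference inside a box.

    Pipeline: bilateral denoise of the box in both frames, contrast
    stretch of the box, thresholded difference (``>= t_diff``),
    residual mask at ``t_p`` (Otsu of the box if unset), the clipped
    combination, then one morphological open-close.  If discrete-point
    positions and/or a target mean gray are supplied, connected
    components are kept only when they contain a point or their mean
    gray is within ``fuse_gray_tol`` of ``g_avg``.
    """
    cfg = cfg or RunConfig()
    box = box.clip(f_cur.shape)
    if box.area == 0:
        raise ValueError("empty tracking box")
    prev = bilateral_denoise(f_prev, box, cfg.bilateral_sigma_s,
                             cfg.bilateral_sigma_r)
    cur = bilateral_denoise(f_cur, box, cfg.bilateral_sigma_s,
                            cfg.bilateral_sigma_r)
    sl = box.slices()
    sub_prev = prev[sl].astype(float)
    sub_cur = cur[sl].astype(float)
    # joint-limit stretch: one linear map for both crops, so static pixels
    # stay static after enhancement
    lo = min(sub_prev.min(), sub_cur.min())
    hi = max(sub_prev.max(), sub_cur.max())
    if hi > lo:
        sub_prev = np.trunc((sub_prev - lo) * 255.0 / (hi - lo))
        sub_cur = np.trunc((sub_cur - lo) * 255.0 / (hi - lo))
    d_box = np.abs(sub_cur - sub_prev) >= cfg.t_diff
    d_frame = np.zeros(f_cur.shape, dtype=np.uint8)
    d_frame[sl] = d_box.astype(np.uint8)
    if cfg.t_p is not None:
        t_p = cfg.t_p
    elif g_avg is not None:
        # brightness relative to the tracked target's own gray level
        t_p = g_avg + cfg.gray_margin
    else:
        wide = box.expand(2.0, f_cur.shape)
        t_p = float(threshold_otsu(f_cur[wide.slices()]))
    d_seg = residual_mask((seg_p > 0).astype(np.uint8), f_cur, t_p)
    raw = eq12_combine(d_frame, (seg_p > 0).astype(np.uint8), d_seg)
    raw_box = raw.copy()
    raw_box[~_box_mask(f_cur.shape, box)] = 0
    fused = raw_box
    if g_avg is not None:
        # gray-information fusion: pixels in the box within the target's
        # gray band belong to the region even where the difference is silent
        band = (f_cur.astype(float) <= g_avg + cfg.gray_margin) \
            & _box_mask(f_cur.shape, box)
        fused = (raw_box | band.astype(np.uint8))
    seg_c = _open_close(fused)
    seg_c = _fuse_components(seg_c, f_cur, points, g_avg, cfg.fuse_gray_tol)
    return RoiMasks(seg_p=(seg_p > 0).astype(np.uint8), d_seg=d_seg,
                    seg_c=seg_c, seg_c_raw=raw, d_frame=d_frame,
                    lost=not bool(seg_c.any()))


def _box_mask(shape, box: BBox) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[box.slices()] = True
    return m


def _fuse_components(mask: np.ndarray, frame: np.ndarray,
                     points: np.ndarray | None, g_avg: float | None,
                     gray_tol: float) -> np.ndarray:
    """Keep components that hold a discrete point or match the target gray."""
    if points is None and g_avg is None:
        return mask
    labels, n = ndimage.label(mask > 0)
    if n == 0:
        return mask
    keep = np.zeros(n + 1, dtype=bool)
    if points is not None and len(points):
        xs = np.clip(points[:, 0], 0, frame.shape[1] - 1)
        ys = np.clip(points[:, 1], 0, frame.shape[0] - 1)
        for lab in labels[ys, xs]:
            if lab > 0:
                keep[lab] = True
    if g_avg is not None:
        means = ndimage.mean(frame.astype(float), labels,
                             index=np.arange(1, n + 1))
        for i, mg in enumerate(np.atleast_1d(means), start=1):
            if abs(mg - g_avg) <= gray_tol:
                keep[i] = True
    out = keep[labels]
    if not out.any():           # never discard everything on fusion alone
        return mask
    return out.astype(np.uint8)


def track_improved_diff(seq: VideoSequence, init_box: BBox,
                        cfg: RunConfig | None = None,
                        seed: int = 0) -> tuple[Trajectory, list[np.ndarray]]:
    """Run the improved difference detector through a sequence.

    Frame 1 is initialized with the discrete-point segmentation
    (dark-region watershed inside the box); the tracking box then
    follows the detected region with the last centroid displacement,
    which makes the method a detector-tracker requiring only
    {previous frame, previous region, box} as state.
    """
    from .bolus import init_bolus, sample_points  # local to avoid cycle

    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    state = init_bolus(seq[0], init_box, cfg, rng)
    seg_p = state.mask.astype(np.uint8)
    box = state.box.expand(cfg.expand_factor, seq.shape)
    points = state.points
    velocity = (0.0, 0.0)
    traj = Trajectory("improved_diff")
    masks = [seg_p.copy()]
    ys, xs = np.nonzero(seg_p)
    traj.append(0, state.box, (float(xs.mean()), float(ys.mean())), 1.0)
    prev_centroid = (float(xs.mean()), float(ys.mean()))
    for i in range(1, len(seq)):
        roi = improved_diff(seq[i - 1], seq[i], seg_p, box, cfg,
                            points=points.points, g_avg=points.g_avg)
        masks.append(roi.seg_c.copy())
        if roi.lost:
            h, w = seq.shape
            nx = float(np.clip(box.x + velocity[0], 0, max(0, w - box.w)))
            ny = float(np.clip(box.y + velocity[1], 0, max(0, h - box.h)))
            box = BBox(nx, ny, box.w, box.h).clip(seq.shape)
            traj.append(i, box, box.center, 0.0)
            continue
        seg_p = roi.seg_c
        ys, xs = np.nonzero(seg_p)
        centroid = (float(xs.mean()), float(ys.mean()))
        velocity = (centroid[0] - prev_centroid[0],
                    centroid[1] - prev_centroid[1])
        prev_centroid = centroid
        tight = BBox.from_mask(seg_p)
        h, w = seq.shape
        nx = float(np.clip(tight.x + velocity[0], 0, max(0, w - tight.w)))
        ny = float(np.clip(tight.y + velocity[1], 0, max(0, h - tight.h)))
        box = BBox(nx, ny, tight.w, tight.h).expand(cfg.expand_factor,
                                                    seq.shape)
        points = sample_points(seg_p > 0, seq[i], cfg.gamma_p, rng)
        traj.append(i, tight, centroid, 1.0)
    return traj, masks


def classical_diff_masks(seq: VideoSequence, m: float) -> list[np.ndarray]:
    """Classical frame difference over a sequence (first mask empty)."""
    masks = [np.zeros(seq.shape, dtype=np.uint8)]
    for i in range(1, len(seq)):
        masks.append(classical_diff(seq[i - 1], seq[i], m).d_frame)
    return masks
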