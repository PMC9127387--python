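"""Discrete-point tracking of the amorphous barium bolus.

The bolus flows and deforms, so no fixed appearance template exists.
The tracker instead keeps a set of random points sampled inside the
current bolus region.  Each frame it predicts the search box from the
last displacement, expands it, partitions it by watershed, and scores
every region by a weighted sum of (share of points captured, point
density, gray-level distance to the running bolus mean).  Rejected
regions are recursively re-segmented at lower levels until a floor
``c_min``, where plain gray-band thresholding takes over.  Accepted
pixels are united, cleaned by one morphological open-close, and the
points are resampled from the new mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import RunConfig
from .core import BBox, Trajectory, VideoSequence
from .preprocess import watershed_segment

__all__ = [
    "DiscretePointSet", "EvaParams", "BolusState",
    "sample_points", "expand_box", "evaluate_region",
    "threshold_segment", "init_bolus", "step_bolus", "track_bolus",
]


@dataclass
class DiscretePointSet:
    """Random points inside the bolus region plus its mean gray."""

    points: np.ndarray          # (k, 2) integer (x, y)
    gamma_p: float
    g_avg: float


@dataclass(frozen=True)
class EvaParams:
    """Weights and bands of the region-acceptance score."""

    theta0: float = 0.0
    theta1: float = 0.5
    theta2: float = 0.3
    theta3: float = -0.01
    e0: float = 0.25
    e1: float = np.inf
    beta_img: float = 0.5
    c_min: int = 1
    g0: float = 0.0
    g1: float = 255.0

    def __post_init__(self) -> None:
        if self.e0 >= self.e1:
            raise ValueError("need e0 < e1")
        if self.g0 >= self.g1:
            raise ValueError("need g0 < g1")
        if not (0 < self.beta_img <= 1):
            raise ValueError("beta_img in (0, 1]")
        if self.c_min < 1:
            raise ValueError("c_min >= 1")

    @staticmethod
    def from_config(cfg: RunConfig, g_avg: float) -> "EvaParams":
        return EvaParams(cfg.theta0, cfg.theta1, cfg.theta2, cfg.theta3,
                         cfg.e0, cfg.e1, cfg.beta_img, cfg.c_min,
                         g0=0.0, g1=min(255.0, g_avg + cfg.gray_margin))


@dataclass
class BolusState:
    box: BBox
    mask: np.ndarray            # frame-shaped bool
    points: DiscretePointSet
    velocity: tuple[float, float] = (0.0, 0.0)
    lost: bool = False
    level: int = 4


def sample_points(mask: np.ndarray, frame: np.ndarray, gamma_p: float,
                  rng: np.random.Generator) -> DiscretePointSet:
    """Uniform random points (without replacement) inside a region.

    The point count is ``round(gamma_p * |S_p|)``; a region too small to
    support that falls back to one point at the region centroid.  The
    set also carries the mean gray of the region.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot sample points from an empty region")
    g_avg = float(frame[ys, xs].mean())
    k = int(round(gamma_p * ys.size))
    if k < 1:
        cx, cy = float(xs.mean()), float(ys.mean())
        pts = np.array([[int(round(cx)), int(round(cy))]])
        return DiscretePointSet(pts, gamma_p, g_avg)
    idx = rng.choice(ys.size, size=k, replace=False)
    pts = np.stack([xs[idx], ys[idx]], axis=1)
    return DiscretePointSet(pts, gamma_p, g_avg)


def expand_box(box: BBox, factor: float, frame_shape: tuple[int, int]) -> BBox:
    """Scale a box about its center and clip to the frame."""
    return box.expand(factor, frame_shape)


def evaluate_region(region_mask: np.ndarray, points: DiscretePointSet,
                    frame: np.ndarray, p: EvaParams) -> float:
    """Weighted acceptance score of one watershed region.

    ``theta0 + theta1 * (points in region / all points) + theta2 *
    (points in region / region area) + theta3 * |region mean gray -
    g_avg|``.  Empty regions score NaN (always rejected).
    """
    area = int(region_mask.sum())
    if area == 0 or len(points.points) == 0:
        return float("nan")
    xs, ys = points.points[:, 0], points.points[:, 1]
    h, w = region_mask.shape
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    n_in = int(region_mask[ys[inside], xs[inside]].sum())
    mean_gray = float(frame[region_mask].mean())
    return (p.theta0
            + p.theta1 * n_in / len(points.points)
            + p.theta2 * n_in / area
            + p.theta3 * abs(mean_gray - points.g_avg))


def threshold_segment(frame: np.ndarray, region_mask: np.ndarray,
                      p: EvaParams) -> np.ndarray:
    """Gray-band threshold segmentation: keep pixels with gray in [g0, g1]."""
    keep = (frame >= p.g0) & (frame <= p.g1)
    return region_mask & keep


def _accept_regions(frame: np.ndarray, box: BBox, c: int,
                    points: DiscretePointSet, p: EvaParams,
                    h_base: float) -> np.ndarray:
    """Watershed the box at level ``c`` and collect accepted pixels.

    A rejected region larger than ``beta_img`` of the box restarts the
    whole box at ``c - 1``; smaller rejected regions are refined
    individually; below ``c_min`` the gray-band threshold decides.
    """
    shape = frame.shape
    while True:
        seg = watershed_segment(frame, box, c, h_base=h_base, lines=False)
        accepted = np.zeros(shape, dtype=bool)
        restart = False
        for label in seg.regions:
            rmask = seg.region_mask(label, shape)
            eva = evaluate_region(rmask, points, frame, p)
            if np.isnan(eva):
                continue
            if p.e0 <= eva <= p.e1:
                accepted |= rmask
            elif seg.regions[label].area / max(box.area, 1) > p.beta_img:
                restart = True
                break
            else:
                accepted |= _refine_region(frame, rmask, c - 1, points, p, h_base)
        if not restart:
            return accepted
        if c - 1 < p.c_min:
            return threshold_segment(frame, np.ones(shape, bool), p) \
                & _box_mask(shape, box)
        c -= 1


def _box_mask(shape, box: BBox) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[box.clip(shape).slices()] = True
    return m


def _refine_region(frame: np.ndarray, region_mask: np.ndarray, c: int,
                   points: DiscretePointSet, p: EvaParams,
                   h_base: float) -> np.ndarray:
    """Recursively re-segment a rejected region at level ``c``."""
    if c < p.c_min:
        return threshold_segment(frame, region_mask, p)
    try:
        sub_box = BBox.from_mask(region_mask)
    except ValueError:
        return np.zeros_like(region_mask)
    if sub_box.w < 3 or sub_box.h < 3:
        return threshold_segment(frame, region_mask, p)
    seg = watershed_segment(frame, sub_box, c, h_base=h_base, lines=False)
    accepted = np.zeros_like(region_mask)
    for label in seg.regions:
        rmask = seg.region_mask(label, frame.shape) & region_mask
        if not rmask.any():
            continue
        eva = evaluate_region(rmask, points, frame, p)
        if not np.isnan(eva) and p.e0 <= eva <= p.e1:
            accepted |= rmask
        else:
            accepted |= _refine_region(frame, rmask, c - 1, points, p, h_base)
    return accepted


def _open_close(mask: np.ndarray) -> np.ndarray:
    se = np.ones((3, 3), dtype=bool)
    m = ndimage.binary_opening(mask, structure=se)
    return ndimage.binary_closing(m, structure=se)


def init_bolus(frame: np.ndarray, box: BBox, cfg: RunConfig,
               rng: np.random.Generator | None = None) -> BolusState:
    """Locate the bolus inside the user box on the first frame.

    Watershed at ``c_init`` partitions the box; the union of regions
    darker than the Otsu level of the box content is taken as the bolus
    mask ``S_p``.  Raises if nothing dark is found.
    """
    rng = rng or np.random.default_rng(0)
    box = box.clip(frame.shape)
    if box.area == 0:
        raise ValueError("initial box outside frame")
    sub = frame[box.slices()]
    if sub.max() == sub.min():
        raise ValueError("no bolus found: uniform box content")
    otsu = threshold_otsu(sub)
    mask = np.zeros(frame.shape, dtype=bool)
    # lower the segmentation level until something darker than the box's
    # Otsu split shows up (coarse levels can merge a small bolus away)
    for c in range(cfg.c_init, cfg.c_min - 1, -1):
        seg = watershed_segment(frame, box, c, h_base=cfg.h_base, lines=False)
        for label, st in seg.regions.items():
            if st.mean_gray < otsu:
                mask |= seg.region_mask(label, frame.shape)
        mask = _open_close(mask)
        if mask.any():
            break
    if not mask.any():
        raise ValueError("no bolus found: no dark region inside the box")
    points = sample_points(mask, frame, cfg.gamma_p, rng)
    return BolusState(box=BBox.from_mask(mask), mask=mask, points=points,
                      velocity=(0.0, 0.0), level=cfg.c_init)


def step_bolus(state: BolusState, frame: np.ndarray, cfg: RunConfig,
               rng: np.random.Generator | None = None) -> BolusState:
    """Advance the bolus state by one frame.

    The search box is the previous box shifted by the last displacement
    and expanded; accepted watershed pixels are united and cleaned; the
    new centroid updates the velocity; points are resampled from the
    new mask.  An empty result flags the state ``lost`` and coasts the
    box along the frozen velocity.
    """
    rng = rng or np.random.default_rng(0)
    vx, vy = state.velocity
    pred = BBox(state.box.x + vx, state.box.y + vy, state.box.w, state.box.h)
    search = expand_box(pred.clip(frame.shape), cfg.expand_factor, frame.shape)
    if search.w < 3 or search.h < 3:
        return replace(state, lost=True)
    p = EvaParams.from_config(cfg, state.points.g_avg)
    accepted = _accept_regions(frame, search, state.level, state.points, p,
                               cfg.h_base)
    accepted = _open_close(accepted)
    if not accepted.any():
        coasted = pred.clip(frame.shape)
        return BolusState(box=coasted, mask=state.mask, points=state.points,
                          velocity=state.velocity, lost=True, level=state.level)
    ys, xs = np.nonzero(state.mask)
    old_c = (float(xs.mean()), float(ys.mean())) if ys.size else pred.center
    ys, xs = np.nonzero(accepted)
    new_c = (float(xs.mean()), float(ys.mean()))
    velocity = (new_c[0] - old_c[0], new_c[1] - old_c[1])
    points = sample_points(accepted, frame, cfg.gamma_p, rng)
    return BolusState(box=BBox.from_mask(accepted), mask=accepted,
                      points=points, velocity=velocity, lost=False,
                      level=state.level)


def track_bolus(seq: VideoSequence, init_box: BBox, cfg: RunConfig | None = None,
                seed: int = 0) -> tuple[Trajectory, list[np.ndarray]]:
    """Track the bolus through a sequence; returns trajectory + masks."""
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    state = init_bolus(seq[0], init_box, cfg, rng)
    traj = Trajectory("bolus")
    masks = [state.mask.copy()]
    ys, xs = np.nonzero(state.mask)
    traj.append(0, state.box, (float(xs.mean()), float(ys.mean())), score=1.0)
    for i in range(1, len(seq)):
        state = step_bolus(state, seq[i], cfg, rng)
        masks.append(state.mask.copy())
        ys, xs = np.nonzero(state.mask)
        centroid = (float(xs.mean()), float(ys.mean())) if ys.size \
            else state.box.center
        traj.append(i, state.box, centroid, score=0.0 if state.lost else 1.0)
    return traj, masks
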