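"""Correlation-filter tracking of rigid tissue/organ targets.

The combined tracker couples

* a kernelized position filter: ridge regression over all cyclic shifts
  of the search window (Gaussian kernel, gray and/or HOG channels),
  solved in the Fourier domain, with response
  ``res = Re(ifft2(alpha_hat * fft2(k)))``;
* a one-dimensional scale filter over a pyramid of patches at factors
  ``a**s`` around the located center (each resized to a fixed model
  size, normalized, projected, cosine-tapered);
* an exponential template update ``alpha_hat <- (1-theta)*alpha_hat +
  theta*alpha_new`` applied to both filters;
* optional watershed edge correction that snaps the reported box to the
  dominant segmented region when it overlaps the box well;
* an occlusion guard: when the response peak falls below a fraction of
  its running mean, updates freeze and the box coasts on the last
  confident displacement until the target is reacquired.

A single-channel MOSSE tracker is included as the classical baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hog as skimage_hog
from skimage.transform import resize

from .config import RunConfig
from .core import BBox, Trajectory, VideoSequence
from .preprocess import watershed_segment

__all__ = [
    "correlate", "gaussian_kernel_correlation",
    "PositionFilter", "pf_init", "pf_detect", "pf_update",
    "ScaleFilter", "sf_init", "sf_estimate", "sf_update",
    "CombinedTracker", "combined_init", "combined_step", "track_combined",
    "MosseFilter", "mosse_track",
]


# ---------------------------------------------------------------------------
# correlation primitives

def correlate(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Circular cross-correlation via the frequency domain.

    ``y(tau) = sum_t x(t + tau) * m(t)``, computed as
    ``Re(ifft2(fft2(x) * conj(fft2(m))))`` and summed over channels.
    """
    x = np.atleast_3d(x)
    m = np.atleast_3d(m)
    if x.shape != m.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {m.shape}")
    acc = np.zeros(x.shape[:2])
    for c in range(x.shape[2]):
        acc += np.real(np.fft.ifft2(np.fft.fft2(x[..., c])
                                    * np.conj(np.fft.fft2(m[..., c]))))
    return acc


def gaussian_kernel_correlation(x: np.ndarray, z: np.ndarray,
                                sigma: float) -> np.ndarray:
    """Gaussian kernel evaluated against all cyclic shifts of ``z``.

    ``k(tau) = exp(-(||x||^2 + ||z||^2 - 2 corr(x, z)(tau)) /
    (sigma^2 * numel))``, clamped at zero distance, via FFT.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_3d(x)
    z = np.atleast_3d(z)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z.shape}")
    cc = correlate(x, z)
    d2 = np.maximum(0.0, float((x ** 2).sum()) + float((z ** 2).sum()) - 2.0 * cc)
    return np.exp(-d2 / (sigma ** 2 * x.size))


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    hy = np.hanning(shape[0]) if shape[0] > 1 else np.ones(1)
    hx = np.hanning(shape[1]) if shape[1] > 1 else np.ones(1)
    return np.outer(hy, hx)


def get_subwindow(frame: np.ndarray, center: tuple[float, float],
                  size: tuple[int, int],
                  out_size: tuple[int, int] | None = None) -> np.ndarray:
    """Crop a (w, h) window at ``center`` with edge replication.

    Out-of-frame coordinates clamp to the border ("filled with
    assignment").  Optionally resized to ``out_size`` (w, h).
    """
    w, h = size
    cx, cy = center
    xs = np.clip(int(np.floor(cx)) - w // 2 + np.arange(w), 0,
                 frame.shape[1] - 1)
    ys = np.clip(int(np.floor(cy)) - h // 2 + np.arange(h), 0,
                 frame.shape[0] - 1)
    patch = frame[np.ix_(ys, xs)].astype(float)
    if out_size is not None and (out_size[1], out_size[0]) != patch.shape:
        patch = resize(patch, (out_size[1], out_size[0]), order=1,
                       anti_aliasing=False, preserve_range=True)
    return patch


def extract_features(patch: np.ndarray, features: str = "gray+hog",
                     cell: int = 4, orientations: int = 9,
                     window: np.ndarray | None = None) -> np.ndarray:
    """Stack gray and/or HOG channels at pixel resolution, cosine-tapered.

    HOG cell histograms are computed at ``cell``-pixel resolution and
    replicated back to the pixel grid so all channels share one spatial
    shape.
    """
    p = patch.astype(float) / 255.0
    chans = []
    if "gray" in features:
        chans.append(p - p.mean())
    if "hog" in features:
        ch = skimage_hog(p, orientations=orientations,
                         pixels_per_cell=(cell, cell),
                         cells_per_block=(1, 1), feature_vector=False)
        ch = ch.reshape(ch.shape[0], ch.shape[1], orientations)
        up = np.repeat(np.repeat(ch, cell, axis=0), cell, axis=1)
        up = up[:p.shape[0], :p.shape[1], :]
        if up.shape[:2] != p.shape:   # pad if patch not a cell multiple
            pad = ((0, p.shape[0] - up.shape[0]),
                   (0, p.shape[1] - up.shape[1]), (0, 0))
            up = np.pad(up, pad, mode="edge")
        chans.append(up)
    if not chans:
        raise ValueError(f"unknown feature set {features!r}")
    fmap = np.dstack(chans)
    if window is None:
        window = _hann2d(fmap.shape[:2])
    return fmap * window[..., None]


def _gaussian_peak_at_zero(shape: tuple[int, int], sigma: float) -> np.ndarray:
    h, w = shape
    ys = np.arange(h) - h // 2
    xs = np.arange(w) - w // 2
    g = np.exp(-0.5 * (ys[:, None] ** 2 + xs[None, :] ** 2) / sigma ** 2)
    return np.roll(np.roll(g, -(h // 2), axis=0), -(w // 2), axis=1)


def _wrapped_argmax(resp: np.ndarray) -> tuple[float, float, float]:
    """Peak of a wrapped response with parabolic sub-pixel refinement.

    Returns (dy, dx, peak value); displacements in (-N/2, N/2].
    """
    h, w = resp.shape
    iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
    peak = float(resp[iy, ix])

    def _refine(vm, v0, vp):
        denom = vm - 2.0 * v0 + vp
        if denom >= 0 or abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dy = iy if iy <= h // 2 else iy - h
    dx = ix if ix <= w // 2 else ix - w
    dy += _refine(resp[(iy - 1) % h, ix], resp[iy, ix], resp[(iy + 1) % h, ix])
    dx += _refine(resp[iy, (ix - 1) % w], resp[iy, ix], resp[iy, (ix + 1) % w])
    return dy, dx, peak


# ---------------------------------------------------------------------------
# kernelized position filter

@dataclass
class PositionFilter:
    alpha_f: np.ndarray            # frequency-domain dual coefficients
    template: np.ndarray           # learned feature map z
    window_size: tuple[int, int]   # (w, h) of the search window, px
    target_size: tuple[int, int]   # (w, h) of the target, px
    sigma_k: float
    lam: float
    y_f: np.ndarray                # fft of the regression target
    features: str
    cell: int
    orientations: int
    cos_window: np.ndarray


def _pf_features(pf: PositionFilter, frame: np.ndarray,
                 center: tuple[float, float],
                 scale: float = 1.0) -> np.ndarray:
    w, h = pf.window_size
    size = (max(8, int(round(w * scale))), max(8, int(round(h * scale))))
    patch = get_subwindow(frame, center, size, out_size=(w, h))
    return extract_features(patch, pf.features, pf.cell, pf.orientations,
                            pf.cos_window)


def pf_init(frame: np.ndarray, box: BBox, cfg: RunConfig | None = None) -> PositionFilter:
    """Train the position filter on the first frame's box."""
    cfg = cfg or RunConfig()
    if box.w < 8 or box.h < 8:
        raise ValueError(f"degenerate box {box}: need w, h >= 8")
    if box.clip(frame.shape).area == 0:
        raise ValueError("box outside frame")
    ww = int(round(box.w * cfg.search_scale))
    wh = int(round(box.h * cfg.search_scale))
    cos_win = _hann2d((wh, ww))
    sigma_y = np.sqrt(box.w * box.h) * cfg.output_sigma_factor
    y_f = np.fft.fft2(_gaussian_peak_at_zero((wh, ww), sigma_y))
    pf = PositionFilter(alpha_f=np.zeros((wh, ww), complex),
                        template=np.zeros((wh, ww, 1)),
                        window_size=(ww, wh), target_size=(box.w, box.h),
                        sigma_k=cfg.sigma_k, lam=cfg.lam, y_f=y_f,
                        features=cfg.features, cell=cfg.hog_cell,
                        orientations=cfg.hog_orientations, cos_window=cos_win)
    x = _pf_features(pf, frame, box.center)
    k = gaussian_kernel_correlation(x, x, pf.sigma_k)
    pf.alpha_f = pf.y_f / (np.fft.fft2(k) + pf.lam)
    pf.template = x
    return pf


def pf_detect(pf: PositionFilter, frame: np.ndarray,
              center: tuple[float, float],
              scale: float = 1.0) -> tuple[tuple[float, float], float]:
    """Locate the target near ``center``; returns (new center, peak)."""
    x = _pf_features(pf, frame, center, scale)
    k = gaussian_kernel_correlation(x, pf.template, pf.sigma_k)
    res = np.real(np.fft.ifft2(pf.alpha_f * np.fft.fft2(k)))
    dy, dx, peak = _wrapped_argmax(res)
    return (center[0] + dx * scale, center[1] + dy * scale), peak


def pf_update(pf: PositionFilter, frame: np.ndarray,
              center: tuple[float, float], theta: float,
              scale: float = 1.0) -> None:
    """Blend in a filter trained at the new position (convex in theta)."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    x = _pf_features(pf, frame, center, scale)
    k = gaussian_kernel_correlation(x, x, pf.sigma_k)
    alpha_new = pf.y_f / (np.fft.fft2(k) + pf.lam)
    pf.alpha_f = (1.0 - theta) * pf.alpha_f + theta * alpha_new
    pf.template = (1.0 - theta) * pf.template + theta * x


# ---------------------------------------------------------------------------
# scale filter

@dataclass
class ScaleFilter:
    factors: np.ndarray            # symmetric a**s ladder, middle = 1
    base_size: tuple[int, int]     # (w, h) at scale 1
    model_size: int
    projection: np.ndarray | None  # (p, d) fixed projection from init
    num: np.ndarray                # per-dim numerator (p, n) complex
    den: np.ndarray                # shared denominator (n,) real
    y_f: np.ndarray                # fft of the 1-D scale target
    window: np.ndarray             # cosine taper over scales
    lam: float


def _scale_features(frame: np.ndarray, center, base_size, factors,
                    model_size: int) -> np.ndarray:
    """(d, n) matrix: one normalized patch descriptor per scale factor."""
    feats = []
    for f in factors:
        w = max(4, int(round(base_size[0] * f)))
        h = max(4, int(round(base_size[1] * f)))
        patch = get_subwindow(frame, center, (w, h),
                              out_size=(model_size, model_size))
        v = patch.ravel() / 255.0
        v = v - v.mean()
        nrm = np.linalg.norm(v)
        if nrm > 0:
            v = v / nrm
            v = np.clip(v, -0.2, 0.2)       # limit single-pixel dominance
            nrm2 = np.linalg.norm(v)
            if nrm2 > 0:
                v = v / nrm2
        feats.append(v)
    return np.stack(feats, axis=1)


def sf_init(frame: np.ndarray, box: BBox, cfg: RunConfig | None = None) -> ScaleFilter:
    cfg = cfg or RunConfig()
    n = cfg.n_scales
    exps = np.arange(n) - n // 2
    factors = cfg.scale_step ** exps
    win = np.hanning(n) if (cfg.scale_window == "hann" and n > 1) else (
        np.hamming(n) if n > 1 else np.ones(1))
    # regression target over scale indices, peaked at the unit factor
    sigma_s = 0.25 * np.sqrt(n)
    ys = np.exp(-0.5 * (exps ** 2) / sigma_s ** 2)
    sf = ScaleFilter(factors=factors, base_size=(box.w, box.h),
                     model_size=cfg.scale_model_size, projection=None,
                     num=np.zeros((1, n), complex), den=np.zeros(n),
                     y_f=np.fft.fft(ys), window=win, lam=cfg.lam)
    F = _scale_features(frame, box.center, sf.base_size, factors,
                        sf.model_size)
    p = min(cfg.pca_dims, F.shape[0], n)
    U, _, _ = np.linalg.svd(F - F.mean(axis=1, keepdims=True),
                            full_matrices=False)
    sf.projection = U[:, :p].T
    sf_update(sf, frame, box.center, theta=1.0)
    return sf


def _sf_sample(sf: ScaleFilter, frame: np.ndarray, center) -> np.ndarray:
    F = _scale_features(frame, center, sf.base_size, sf.factors,
                        sf.model_size)
    Fp = sf.projection @ F
    return np.fft.fft(Fp * sf.window[None, :], axis=1)


def sf_update(sf: ScaleFilter, frame: np.ndarray, center,
              theta: float) -> None:
    Zf = _sf_sample(sf, frame, center)
    num_new = sf.y_f[None, :] * np.conj(Zf)
    den_new = (Zf * np.conj(Zf)).real.sum(axis=0)
    if theta >= 1.0 or sf.num.shape != num_new.shape:
        sf.num, sf.den = num_new, den_new
    else:
        sf.num = (1.0 - theta) * sf.num + theta * num_new
        sf.den = (1.0 - theta) * sf.den + theta * den_new


def sf_estimate(sf: ScaleFilter, frame: np.ndarray, center) -> float:
    """Best relative scale factor at ``center`` (1.0 = unchanged)."""
    n = len(sf.factors)
    if n == 1:
        return 1.0
    Zf = _sf_sample(sf, frame, center)
    resp = np.real(np.fft.ifft((sf.num * Zf).sum(axis=0)
                               / (sf.den + sf.lam)))
    # response index maps directly onto the factor ladder
    return float(sf.factors[int(np.argmax(resp))])


# ---------------------------------------------------------------------------
# combined tracker

@dataclass
class CombinedTracker:
    position: PositionFilter
    scale: ScaleFilter | None
    box: BBox
    theta: float
    conf_floor: float
    correction: bool
    correction_level: int
    correction_min_overlap: float
    h_base: float
    frame_shape: tuple[int, int]
    center: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (0.0, 0.0)    # float (w, h)
    velocity: tuple[float, float] = (0.0, 0.0)
    mean_peak: float = 0.0
    occluded: bool = False
    lost_count: int = 0


def combined_init(frame: np.ndarray, box: BBox,
                  cfg: RunConfig | None = None,
                  use_scale: bool = True) -> CombinedTracker:
    """Step 1 of the framework: calibrate the box, train both filters."""
    cfg = cfg or RunConfig()
    pf = pf_init(frame, box, cfg)
    sf = sf_init(frame, box, cfg) if use_scale and cfg.n_scales > 1 else None
    return CombinedTracker(position=pf, scale=sf, box=box, theta=cfg.learning_rate,
                           conf_floor=cfg.conf_floor,
                           correction=cfg.correction,
                           correction_level=cfg.correction_level,
                           correction_min_overlap=cfg.correction_min_overlap,
                           h_base=cfg.h_base, frame_shape=frame.shape,
                           center=box.center, size=(float(box.w), float(box.h)))


def _current_scale(tr: CombinedTracker) -> float:
    return tr.size[0] / tr.position.target_size[0]


def combined_step(tr: CombinedTracker, frame: np.ndarray) -> tuple[BBox, dict]:
    """Steps 2-6: detect position, estimate scale, update, correct.

    Returns the reported box and a flags dict with keys ``occluded``,
    ``peak`` and ``corrected``.
    """
    flags = {"occluded": False, "peak": 0.0, "corrected": False}
    pred_center = (tr.center[0] + tr.velocity[0], tr.center[1] + tr.velocity[1])
    scale = _current_scale(tr)
    new_center, peak = pf_detect(tr.position, frame, pred_center, scale)
    flags["peak"] = peak
    if tr.mean_peak == 0.0:
        tr.mean_peak = peak
    if peak < tr.conf_floor * tr.mean_peak:
        # occlusion: freeze templates, coast on the last displacement
        tr.occluded = True
        tr.lost_count += 1
        flags["occluded"] = True
        tr.center = (float(np.clip(pred_center[0], 0, frame.shape[1] - 1)),
                     float(np.clip(pred_center[1], 0, frame.shape[0] - 1)))
        tr.box = _center_box(tr.center, tr.size, frame.shape)
        return tr.box, flags
    tr.velocity = (new_center[0] - tr.center[0], new_center[1] - tr.center[1])
    tr.center = new_center
    tr.occluded = False
    tr.lost_count = 0
    tr.mean_peak = 0.9 * tr.mean_peak + 0.1 * peak
    if tr.scale is not None:
        rel = sf_estimate(tr.scale, frame, tr.center)
        w = float(np.clip(tr.size[0] * rel, 8, frame.shape[1]))
        h = float(np.clip(tr.size[1] * rel, 8, frame.shape[0]))
        tr.size = (w, h)
        # scale-filter base tracks the current size
        tr.scale.base_size = (w, h)
    tr.box = _center_box(tr.center, tr.size, frame.shape)
    report = tr.box
    if tr.correction:
        snapped = _watershed_correct(tr, frame)
        if snapped is not None:
            report = snapped
            flags["corrected"] = True
    pf_update(tr.position, frame, tr.center, tr.theta, _current_scale(tr))
    if tr.scale is not None:
        sf_update(tr.scale, frame, tr.center, tr.theta)
    return report, flags


def _center_box(center, size, shape) -> BBox:
    return BBox(center[0] - size[0] / 2.0, center[1] - size[1] / 2.0,
                size[0], size[1]).clip(shape)


def _watershed_correct(tr: CombinedTracker, frame: np.ndarray) -> BBox | None:
    """Snap the reported box to the watershed support of the target.

    The dominant region is the union of watershed regions that lie
    mostly (>= 60% of their area) inside the current box — i.e. the
    segmented fragments of the target itself; the box snaps to that
    union's bounding box when it overlaps the tracked box by at least
    ``correction_min_overlap`` IoU.
    """
    search = tr.box.expand(1.3, tr.frame_shape)
    if search.w < 3 or search.h < 3:
        return None
    try:
        seg = watershed_segment(frame, search, tr.correction_level,
                                h_base=tr.h_base)
    except ValueError:
        return None
    inner = tr.box.clip(tr.frame_shape)
    union = np.zeros(frame.shape, dtype=bool)
    for label, st in seg.regions.items():
        if st.area == 0:
            continue
        rm = seg.region_mask(label, frame.shape)
        if rm[inner.slices()].sum() / st.area >= 0.6:
            union |= rm
    if not union.any():
        return None
    snapped = BBox.from_mask(union)
    if snapped.iou(tr.box) >= tr.correction_min_overlap:
        return snapped
    return None


def track_combined(seq: VideoSequence, box: BBox,
                   cfg: RunConfig | None = None,
                   use_scale: bool = True) -> Trajectory:
    """Run the combined tracker through a sequence."""
    cfg = cfg or RunConfig()
    tr = combined_init(seq[0], box, cfg, use_scale=use_scale)
    traj = Trajectory("organ")
    traj.append(0, box, box.center, score=1.0)
    for i in range(1, len(seq)):
        rep, flags = combined_step(tr, seq[i])
        traj.append(i, rep, rep.center, score=flags["peak"])
    return traj


# ---------------------------------------------------------------------------
# MOSSE baseline

@dataclass
class MosseFilter:
    num: np.ndarray
    den: np.ndarray
    y_f: np.ndarray
    window_size: tuple[int, int]
    cos_window: np.ndarray
    lam: float


def _mosse_prep(patch: np.ndarray, window: np.ndarray) -> np.ndarray:
    p = np.log1p(patch.astype(float))
    p = (p - p.mean()) / (p.std() + 1e-5)
    return p * window


def mosse_init(frame: np.ndarray, box: BBox,
               cfg: RunConfig | None = None) -> MosseFilter:
    cfg = cfg or RunConfig()
    if box.w < 8 or box.h < 8:
        raise ValueError(f"degenerate box {box}")
    ww = int(round(box.w * cfg.search_scale))
    wh = int(round(box.h * cfg.search_scale))
    win = _hann2d((wh, ww))
    sigma = np.sqrt(box.w * box.h) * cfg.output_sigma_factor
    y = _gaussian_peak_at_zero((wh, ww), sigma)
    y_f = np.fft.fft2(y)
    f = np.fft.fft2(_mosse_prep(get_subwindow(frame, box.center, (ww, wh)), win))
    return MosseFilter(num=y_f * np.conj(f), den=(f * np.conj(f)).real,
                       y_f=y_f, window_size=(ww, wh), cos_window=win,
                       lam=cfg.lam)


def mosse_track(seq: VideoSequence, box: BBox,
                cfg: RunConfig | None = None,
                rate: float = 0.125) -> Trajectory:
    """Single-channel MOSSE tracking baseline."""
    cfg = cfg or RunConfig()
    filt = mosse_init(seq[0], box, cfg)
    center = box.center
    traj = Trajectory("mosse")
    traj.append(0, box, center, score=1.0)
    ww, wh = filt.window_size
    for i in range(1, len(seq)):
        f = np.fft.fft2(_mosse_prep(get_subwindow(seq[i], center, (ww, wh)),
                                    filt.cos_window))
        resp = np.real(np.fft.ifft2(filt.num / (filt.den + filt.lam) * f))
        dy, dx, peak = _wrapped_argmax(resp)
        center = (float(np.clip(center[0] + dx, 0, seq.shape[1] - 1)),
                  float(np.clip(center[1] + dy, 0, seq.shape[0] - 1)))
        f = np.fft.fft2(_mosse_prep(get_subwindow(seq[i], center, (ww, wh)),
                                    filt.cos_window))
        filt.num = (1 - rate) * filt.num + rate * filt.y_f * np.conj(f)
        filt.den = (1 - rate) * filt.den + rate * (f * np.conj(f)).real
        traj.append(i, _center_box(center, (box.w, box.h), seq.shape),
                    center, score=peak)
    return traj
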