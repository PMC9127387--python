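"""Background-subtraction baselines: ViBe and a balloon-estimator EGMM.

ViBe keeps ``n`` intensity samples per pixel, initialized from the
8-neighborhood of a single frame.  A pixel is background when at least
``n_min`` samples lie within radius ``R`` of its current value; the
model updates stochastically (1-in-phi) in both time (own samples) and
space (a random neighbor's samples), which slowly absorbs objects that
stop moving.

The EGMM baseline is the non-parametric variant: a per-pixel FIFO
history and a balloon kernel whose half-width grows until it covers the
``k`` nearest history samples; the pixel is background when that width
stays below a bound (equivalently, when the balloon density estimate is
high enough).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .core import VideoSequence

__all__ = [
    "ViBeModel", "vibe_init", "vibe_classify", "vibe_update", "vibe_masks",
    "EGMMModel", "egmm_init", "egmm_classify_update", "egmm_masks",
]


@dataclass
class ViBeModel:
    samples: np.ndarray        # (n, H, W) uint8
    r: float
    n_min: int
    phi: int

    @property
    def n(self) -> int:
        return self.samples.shape[0]


_NEIGH = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)])


def vibe_init(frame: np.ndarray, n: int = 20, seed: int = 0,
              r: float = 20.0, n_min: int = 2, phi: int = 16) -> ViBeModel:
    """Build the sample model from one frame's 8-neighborhoods.

    Each pixel draws ``n`` samples (with replacement) from its clamped
    8-neighborhood in the given frame.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    h, w = frame.shape
    Y, X = np.mgrid[0:h, 0:w]
    samples = np.empty((n, h, w), dtype=frame.dtype)
    for i in range(n):
        pick = rng.integers(0, 8, size=(h, w))
        dy = _NEIGH[pick, 0]
        dx = _NEIGH[pick, 1]
        yy = np.clip(Y + dy, 0, h - 1)
        xx = np.clip(X + dx, 0, w - 1)
        samples[i] = frame[yy, xx]
    return ViBeModel(samples, float(r), int(n_min), int(phi))


def vibe_classify(model: ViBeModel, frame: np.ndarray) -> np.ndarray:
    """Foreground mask: 1 where fewer than ``n_min`` samples match.

    A sample matches when ``|v - v_i| < R`` (strict), the grayscale
    specialization of the Euclidean sphere test.
    """
    if frame.shape != model.samples.shape[1:]:
        raise ValueError("frame shape does not match model")
    dist = np.abs(model.samples.astype(int) - frame.astype(int))
    matches = (dist < model.r).sum(axis=0)
    return (matches < model.n_min).astype(np.uint8)


def vibe_update(model: ViBeModel, frame: np.ndarray, mask: np.ndarray,
                seed: int = 0) -> ViBeModel:
    """Stochastic in-place model update for background pixels.

    Each background pixel, with probability ``1/phi``, overwrites one of
    its own random samples with its current value; independently, with
    probability ``1/phi``, it overwrites a random sample of a random
    8-neighbor's model with that neighbor's current value (the spatial
    "protection" update).  Foreground pixels never initiate updates, but
    a foreground pixel bordering background can receive protection
    updates — this is what slowly integrates objects that stop moving
    into the background model.
    """
    rng = np.random.default_rng(seed)
    h, w = frame.shape
    bg = mask == 0
    n = model.n
    # temporal update
    sel = bg & (rng.integers(0, model.phi, size=(h, w)) == 0)
    ys, xs = np.nonzero(sel)
    if ys.size:
        si = rng.integers(0, n, size=ys.size)
        model.samples[si, ys, xs] = frame[ys, xs]
    # spatial protection update: refresh a random neighbor's model with
    # the neighbor's own current value
    sel = bg & (rng.integers(0, model.phi, size=(h, w)) == 0)
    ys, xs = np.nonzero(sel)
    if ys.size:
        pick = rng.integers(0, 8, size=ys.size)
        ny = np.clip(ys + _NEIGH[pick, 0], 0, h - 1)
        nx = np.clip(xs + _NEIGH[pick, 1], 0, w - 1)
        si = rng.integers(0, n, size=ys.size)
        model.samples[si, ny, nx] = frame[ny, nx]
    return model


def vibe_masks(seq: VideoSequence, cfg: RunConfig | None = None,
               seed: int = 0) -> list[np.ndarray]:
    """Run ViBe over a sequence; mask for frame 0 is all background."""
    cfg = cfg or RunConfig()
    model = vibe_init(seq[0], cfg.vibe_n, seed, cfg.vibe_r, cfg.vibe_nmin,
                      cfg.vibe_phi)
    masks = [np.zeros(seq.shape, dtype=np.uint8)]
    for i in range(1, len(seq)):
        mask = vibe_classify(model, seq[i])
        vibe_update(model, seq[i], mask, seed=seed + i)
        masks.append(mask)
    return masks


@dataclass
class EGMMModel:
    history: np.ndarray        # (L, H, W) float
    filled: int                # frames currently in the buffer
    k: int
    d_max: float

    @property
    def capacity(self) -> int:
        return self.history.shape[0]


def egmm_init(frame: np.ndarray, buffer_len: int = 50, k: int = 5,
              d_max: float = 20.0) -> EGMMModel:
    h, w = frame.shape
    hist = np.zeros((buffer_len, h, w), dtype=float)
    hist[0] = frame
    return EGMMModel(hist, 1, int(k), float(d_max))


def egmm_classify_update(model: EGMMModel, frame: np.ndarray) -> np.ndarray:
    """Balloon-estimator classification, then conditional FIFO update.

    For each pixel the kernel half-width ``D`` expands to the distance
    of the ``k``-th nearest history sample; the balloon density
    ``k / (2 L D)`` is high (background) exactly when ``D <= d_max``.
    Background pixels push their current value into the FIFO buffer;
    foreground pixels keep their history (conditional update).
    """
    if model.filled == 0:
        return np.ones(frame.shape, dtype=np.uint8)
    f = frame.astype(float)
    hist = model.history[:model.filled]
    dist = np.abs(hist - f[None])
    k_eff = min(model.k, model.filled)
    d_k = np.partition(dist, k_eff - 1, axis=0)[k_eff - 1]
    mask = (d_k > model.d_max).astype(np.uint8)
    # FIFO update for background pixels
    bg = mask == 0
    if model.filled < model.capacity:
        new = np.where(bg, f, model.history[model.filled - 1])
        model.history[model.filled] = new
        model.filled += 1
    else:
        model.history[:-1] = model.history[1:]
        model.history[-1] = np.where(bg, f, model.history[-1])
    return mask


def egmm_masks(seq: VideoSequence, cfg: RunConfig | None = None) -> list[np.ndarray]:
    """Run the EGMM baseline over a sequence (frame 0 seeds the buffer)."""
    cfg = cfg or RunConfig()
    model = egmm_init(seq[0], cfg.egmm_buffer, cfg.egmm_k, cfg.egmm_dmax)
    masks = [np.zeros(seq.shape, dtype=np.uint8)]
    for i in range(1, len(seq)):
        masks.append(egmm_classify_update(model, seq[i]))
    return masks
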