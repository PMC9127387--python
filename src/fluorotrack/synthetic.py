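"""Seeded generator of fluoroscopy-like test sequences with ground truth.

The generator emulates low-contrast 8-bit radiograph frames of a
swallowing study: a dark deformable bolus advecting along a smooth path
with changing size and intensity, rigid textured tissue patches under
translation and mild scale change, transient bright occluders (e.g. a
helper's hand entering the field), and additive Gaussian plus
signal-dependent (Poisson-like) noise.  Ground truth (per-frame mask,
box, centroid, occlusion flag per target) is recorded before noise and
occluders are composited, so metric ceilings are exact.

Everything is reproducible from ``(SceneSpec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.transform import resize

from .core import BBox, VideoSequence

__all__ = [
    "BlobSpec", "OrganSpec", "OccluderSpec", "SceneSpec",
    "TargetTruth", "GroundTruth", "render", "make_scene", "preset_suite",
    "PRESET_NAMES",
]


def path_from_points(points, n_frames: int) -> np.ndarray:
    """Smooth (n_frames, 2) path through control points (natural cubic)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return np.tile(pts[0], (n_frames, 1))
    t = np.linspace(0.0, 1.0, len(pts))
    cs = CubicSpline(t, pts, axis=0)
    return cs(np.linspace(0.0, 1.0, n_frames))


@dataclass
class BlobSpec:
    """Amorphous dark target (barium bolus)."""

    name: str
    path: np.ndarray                 # (n_frames, 2) centers (x, y)
    radius: np.ndarray               # (n_frames,) base radius, px
    intensity: np.ndarray            # (n_frames,) gray level of the blob
    deform: float = 0.15             # relative radius jitter amplitude
    start: int = 0
    end: int | None = None           # exclusive; None = all frames


@dataclass
class OrganSpec:
    """Rigid textured patch (tissue/organ)."""

    name: str
    size: tuple[int, int]            # (w, h) at scale 1
    path: np.ndarray                 # (n_frames, 2) centers
    scale: np.ndarray | None = None  # (n_frames,); None = all ones
    contrast: float = 55.0           # texture amplitude around the base gray
    base_gray: float = 120.0


@dataclass
class OccluderSpec:
    """Bright bar drawn over everything during its active frames."""

    box: BBox
    frames: tuple[int, int]          # [first, last] inclusive
    intensity: float = 235.0


@dataclass
class SceneSpec:
    preset: str
    shape: tuple[int, int] = (128, 128)     # (height, width)
    n_frames: int = 50
    blobs: list[BlobSpec] = field(default_factory=list)
    organs: list[OrganSpec] = field(default_factory=list)
    occluders: list[OccluderSpec] = field(default_factory=list)
    noise_sigma: float = 3.0
    noise_poisson: float = 0.03
    bg_low: float = 140.0
    bg_high: float = 205.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        for b in self.blobs:
            r = np.max(b.radius) * (1.0 + b.deform + 0.1)
            if (b.path[:, 0] - r).min() < 0 or (b.path[:, 0] + r).max() >= w \
                    or (b.path[:, 1] - r).min() < 0 or (b.path[:, 1] + r).max() >= h:
                raise ValueError(f"blob {b.name!r} path exits the frame")
        for o in self.organs:
            s = 1.0 if o.scale is None else float(np.max(o.scale))
            hw, hh = s * o.size[0] / 2, s * o.size[1] / 2
            if (o.path[:, 0] - hw).min() < 0 or (o.path[:, 0] + hw).max() >= w \
                    or (o.path[:, 1] - hh).min() < 0 or (o.path[:, 1] + hh).max() >= h:
                raise ValueError(f"organ {o.name!r} path exits the frame")


@dataclass
class TargetTruth:
    target_id: str
    kind: str                              # "bolus" | "organ"
    masks: list[np.ndarray | None]
    boxes: list[BBox | None]
    centroids: list[tuple[float, float] | None]
    occluded: list[bool]

    def active_frames(self) -> list[int]:
        return [i for i, b in enumerate(self.boxes) if b is not None]


@dataclass
class GroundTruth:
    targets: dict[str, TargetTruth]

    def __getitem__(self, key: str) -> TargetTruth:
        return self.targets[key]


def _background(shape, rng, lo, hi) -> np.ndarray:
    h, w = shape
    tex = gaussian_filter(rng.normal(size=(h, w)), 10.0)
    tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
    bg = lo + tex * (hi - lo)
    # faint vertical spine band, as in a lateral radiograph
    x = np.arange(w)
    band = 18.0 * np.exp(-((x - 0.78 * w) ** 2) / (2 * (0.06 * w) ** 2))
    return bg - band[None, :]


def _organ_texture(size, rng, base, contrast) -> np.ndarray:
    w, h = size
    tex = gaussian_filter(rng.normal(size=(h, w)), 1.2)
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    return np.clip(base + contrast * tex, 10, 245)


def _ellipse_mask(shape, cx, cy, rx, ry, phi) -> np.ndarray:
    h, w = shape
    Y, X = np.mgrid[0:h, 0:w]
    dx, dy = X - cx, Y - cy
    c, s = np.cos(phi), np.sin(phi)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def render(spec: SceneSpec) -> tuple[VideoSequence, GroundTruth]:
    """Render a scene spec into frames plus exact ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    n = spec.n_frames
    bg = _background(spec.shape, rng, spec.bg_low, spec.bg_high)

    # smooth per-frame deformation series for each blob
    blob_jit = {}
    for b in spec.blobs:
        j = gaussian_filter1d(rng.normal(size=(3, n)), 3.0, axis=1)
        blob_jit[b.name] = j
    organ_tex = {o.name: _organ_texture(o.size, rng, o.base_gray, o.contrast)
                 for o in spec.organs}

    truths = {
        t.name: TargetTruth(t.name, kind, [None] * n, [None] * n,
                            [None] * n, [False] * n)
        for t, kind in [(b, "bolus") for b in spec.blobs]
        + [(o, "organ") for o in spec.organs]
    }

    frames = []
    for i in range(n):
        canvas = bg.copy()
        # organs first (the bolus flows in front of tissue)
        for o in spec.organs:
            s = 1.0 if o.scale is None else float(o.scale[i])
            tw = max(4, int(round(o.size[0] * s)))
            th = max(4, int(round(o.size[1] * s)))
            patch = resize(organ_tex[o.name], (th, tw), order=1,
                           anti_aliasing=False, preserve_range=True)
            cx, cy = o.path[i]
            x0, y0 = int(round(cx - tw / 2)), int(round(cy - th / 2))
            box = BBox(x0, y0, tw, th).clip((h, w))
            canvas[box.slices()] = patch[box.y - y0:box.y - y0 + box.h,
                                         box.x - x0:box.x - x0 + box.w]
            mask = np.zeros((h, w), dtype=bool)
            mask[box.slices()] = True
            tt = truths[o.name]
            tt.masks[i] = mask
            tt.boxes[i] = box
            ys, xs = np.nonzero(mask)
            tt.centroids[i] = (float(xs.mean()), float(ys.mean()))
        for b in spec.blobs:
            end = b.end if b.end is not None else n
            if not (b.start <= i < end):
                continue
            j1, j2, j3 = blob_jit[b.name][:, i]
            rx = float(b.radius[i]) * (1.0 + b.deform * j1)
            ry = float(b.radius[i]) * (1.0 + b.deform * j2)
            phi = 4.0 * b.deform * j3  # orientation wobble scales with deform
            cx, cy = b.path[i]
            mask = _ellipse_mask((h, w), cx, cy, max(rx, 1.5), max(ry, 1.5), phi)
            canvas[mask] = float(b.intensity[i])
            tt = truths[b.name]
            tt.masks[i] = mask
            tt.boxes[i] = BBox.from_mask(mask)
            ys, xs = np.nonzero(mask)
            tt.centroids[i] = (float(xs.mean()), float(ys.mean()))
        # occluders go on top; truth already recorded
        for occ in spec.occluders:
            if occ.frames[0] <= i <= occ.frames[1]:
                obox = occ.box.clip((h, w))
                canvas[obox.slices()] = occ.intensity
                for tt in truths.values():
                    bx = tt.boxes[i]
                    if bx is None or bx.area == 0:
                        continue
                    ix = max(0, min(bx.x2, obox.x2) - max(bx.x, obox.x))
                    iy = max(0, min(bx.y2, obox.y2) - max(bx.y, obox.y))
                    if ix * iy / bx.area > 0.5:
                        tt.occluded[i] = True
        noisy = canvas + rng.normal(0.0, spec.noise_sigma, size=(h, w)) \
            + rng.normal(size=(h, w)) * np.sqrt(np.maximum(canvas, 0.0)
                                                * spec.noise_poisson)
        frames.append(np.clip(np.round(noisy), 0, 255).astype(np.uint8))
    return VideoSequence(frames, source_id=f"synthetic:{spec.preset}"), \
        GroundTruth(truths)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = [
    "clean_translation", "occlusion_pass", "forward_lean",
    "bolus_interference", "scale_change", "elevation_small_target",
]


def make_scene(name: str, seed: int = 0) -> SceneSpec:
    """Build a named scene spec.

    Besides the six suite presets, ``side_view`` (50 frames) and
    ``elevation_view`` (30 frames, small dwell-then-dart target) mirror
    the two acquisition geometries of a swallowing study.
    """
    if name in ("clean_translation",):
        nf = 40
        path = path_from_points([(24, 30), (55, 52), (96, 82)], nf)
        spec = SceneSpec(name, (128, 128), nf, seed=seed, blobs=[BlobSpec(
            "bolus", path, radius=9.0 + 1.5 * np.sin(np.linspace(0, 3, nf)),
            intensity=np.linspace(58, 78, nf))],
            noise_sigma=2.0, noise_poisson=0.02)
    elif name == "side_view":
        # lateral swallow: oral hold (dwell), then transport down the
        # pharynx; moderate bolus/background contrast
        nf = 50
        dwell = 12
        moving = path_from_points([(24, 26), (48, 48), (62, 78), (92, 98)],
                                  nf - dwell)
        path = np.vstack([np.tile(moving[0], (dwell, 1)), moving])
        spec = SceneSpec(name, (128, 128), nf, seed=seed, blobs=[BlobSpec(
            "bolus", path, radius=10.0 + 2.0 * np.sin(np.linspace(0, 4, nf)),
            intensity=np.linspace(78, 100, nf), deform=0.18)],
            noise_sigma=3.0, noise_poisson=0.03)
    elif name == "occlusion_pass":
        nf = 40
        path = path_from_points([(36, 62), (52, 66), (72, 72)], nf)
        spec = SceneSpec(name, (128, 128), nf, seed=seed, organs=[OrganSpec(
            "organ", (26, 26), path)],
            occluders=[OccluderSpec(BBox(38, 0, 34, 128), (16, 21))],
            noise_sigma=2.5, noise_poisson=0.02)
    elif name == "forward_lean":
        nf = 45
        chin = path_from_points([(40, 44), (52, 50), (74, 64)], nf)
        anchor = path_from_points([(100, 70)], nf)
        spec = SceneSpec(name, (128, 128), nf, seed=seed, organs=[
            OrganSpec("chin", (24, 24), chin),
            OrganSpec("anchor", (20, 20), anchor)],
            noise_sigma=2.5, noise_poisson=0.02)
    elif name == "bolus_interference":
        nf = 40
        organ = path_from_points([(64, 60), (68, 62)], nf)
        bolus = path_from_points([(24, 28), (58, 52), (96, 92)], nf)
        spec = SceneSpec(name, (128, 128), nf, seed=seed,
                         organs=[OrganSpec("organ", (26, 26), organ)],
                         blobs=[BlobSpec("bolus", bolus,
                                         radius=np.full(nf, 8.0),
                                         intensity=np.full(nf, 65.0))],
                         noise_sigma=2.5, noise_poisson=0.02)
    elif name == "scale_change":
        nf = 40
        path = path_from_points([(46, 50), (62, 64), (80, 76)], nf)
        spec = SceneSpec(name, (128, 128), nf, seed=seed, organs=[OrganSpec(
            "organ", (24, 24), path, scale=np.linspace(1.0, 1.35, nf))],
            noise_sigma=2.5, noise_poisson=0.02)
    elif name in ("elevation_small_target", "elevation_view"):
        nf = 30
        dwell = 18
        pts = [(30.0, 40.0)] * dwell + [
            (30.0 + 4.0 * (i + 1), 40.0 + 3.0 * (i + 1))
            for i in range(nf - dwell)]
        path = np.array(pts)
        spec = SceneSpec("elevation_small_target", (96, 96), nf, seed=seed,
                         blobs=[BlobSpec("bolus", path,
                                         radius=np.full(nf, 5.0),
                                         intensity=np.full(nf, 62.0),
                                         deform=0.10)],
                         noise_sigma=3.0, noise_poisson=0.03)
    else:
        raise ValueError(f"unknown preset {name!r}; "
                         f"known: {PRESET_NAMES + ['side_view', 'elevation_view']}")
    return spec


def preset_suite(seed: int = 0) -> list[tuple[str, VideoSequence, GroundTruth]]:
    """Render the fixed six-scenario suite used by the comparison harness."""
    out = []
    for name in PRESET_NAMES:
        seq, truth = render(make_scene(name, seed))
        out.append((name, seq, truth))
    return out
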