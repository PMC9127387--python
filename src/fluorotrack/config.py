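"""Run configuration: every tunable of the toolkit in one flat record.

``RunConfig`` serializes to/from a flat key-value JSON file so a whole
run is reproducible from (config, seed, input).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # --- discrete-point (bolus) tracker -----------------------------------
    gamma_p: float = 0.1          # ratio of discrete points to region pixels
    c_init: int = 4               # initial watershed segmentation level
    c_min: int = 1                # level floor before threshold segmentation
    expand_factor: float = 1.2    # search-box expansion per frame
    theta0: float = 0.0           # Eva weights (constant, point-share,
    theta1: float = 0.5           # point-density, gray-distance)
    theta2: float = 0.3
    theta3: float = -0.01     # negative: gray distance penalizes a region
    e0: float = 0.25              # Eva acceptance band [e0, e1]
    e1: float = math.inf
    beta_img: float = 0.5         # max region/box area ratio before global redo
    gray_margin: float = 25.0     # g1 = g_avg + gray_margin; g0 = 0 (dark bolus)

    # --- inter-frame differencing -----------------------------------------
    t_diff: float = 15.0          # binarization threshold of the difference
    t_p: float | None = None      # residual threshold; None -> Otsu of the box
    diff_gap: int = 1             # frame gap of the difference
    fuse_gray_tol: float = 20.0   # component kept if |mean gray - g_avg| <= tol
    bilateral_sigma_s: float = 2.0
    bilateral_sigma_r: float = 25.0

    # --- watershed / preprocessing ----------------------------------------
    h_base: float = 4.0           # h-minima depth at level c=1 (doubles per level)
    stretch_window: int = 31      # local contrast-stretch window (odd, px)

    # --- ViBe ---------------------------------------------------------------
    vibe_n: int = 20              # samples per pixel
    vibe_r: float = 20.0          # match radius (intensity)
    vibe_nmin: int = 2            # min matches to call background
    vibe_phi: int = 16            # 1-in-phi stochastic update

    # --- EGMM (balloon-estimator KDE) --------------------------------------
    egmm_buffer: int = 50         # per-pixel history length (frames)
    egmm_k: int = 5               # neighbors covered by the balloon kernel
    egmm_dmax: float = 20.0       # max kernel half-width still called background

    # --- correlation-filter tracker ----------------------------------------
    lam: float = 1e-4             # ridge regularizer
    sigma_k: float = 0.5          # Gaussian-kernel bandwidth (feature-normalized)
    output_sigma_factor: float = 1.0 / 16.0  # regression target bw = sqrt(wh)/16
    hog_cell: int = 4
    hog_orientations: int = 9
    features: str = "gray+hog"    # gray | hog | gray+hog
    search_scale: float = 2.5     # search window / target size
    learning_rate: float = 0.02   # theta of the template update
    conf_floor: float = 0.25      # occlusion flag below this fraction of mean peak
    n_scales: int = 33            # scale-filter pyramid size (odd)
    scale_step: float = 1.02      # ratio between adjacent scales
    scale_model_size: int = 16    # each scale patch resized to this square
    pca_dims: int = 32            # scale-feature dimension after projection
    scale_window: str = "hann"    # hann | hamming taper over scales
    correction: bool = True       # watershed edge correction of the box
    correction_level: int = 2     # watershed level used for the correction
    correction_min_overlap: float = 0.5

    # --- multi-target -------------------------------------------------------
    max_lost_frames: int = 10     # consecutive lost frames before termination

    # --- synthetic data -----------------------------------------------------
    noise_sigma: float = 3.0      # additive Gaussian noise (intensity)
    noise_poisson: float = 0.05   # Poisson-like signal-dependent noise scaling

    def __post_init__(self) -> None:
        if not (0 < self.gamma_p <= 1):
            raise ValueError("gamma_p must be in (0, 1]")
        if self.c_min < 1 or self.c_init < self.c_min:
            raise ValueError("need c_init >= c_min >= 1")
        if self.expand_factor < 1:
            raise ValueError("expand_factor must be >= 1")
        if self.e0 >= self.e1:
            raise ValueError("need e0 < e1")
        if not (0 < self.beta_img <= 1):
            raise ValueError("beta_img must be in (0, 1]")
        if self.vibe_n < self.vibe_nmin or self.vibe_nmin < 1:
            raise ValueError("need vibe_n >= vibe_nmin >= 1")
        if not (0 <= self.learning_rate <= 1):
            raise ValueError("learning_rate must be in [0, 1]")
        if self.n_scales < 1 or self.n_scales % 2 == 0:
            raise ValueError("n_scales must be odd and >= 1")
        if self.scale_step <= 0:
            raise ValueError("scale_step must be positive")

    # -- flat serialization --------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
             for k, v in d.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("e1") == "inf":
            d["e1"] = math.inf
        return cls(**d)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
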