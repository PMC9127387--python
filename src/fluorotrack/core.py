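"""Core containers shared by every tracker: frames, boxes, trajectories.

Conventions (used everywhere in the package):

* frames are 2-D ``uint8`` arrays, pixel grid 0-based, x to the right,
  y downward;
* a bounding box is ``(x, y, w, h)`` with the half-open pixel footprint
  ``[x, x+w) x [y, y+h)``;
* trajectories carry one record per processed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["BBox", "VideoSequence", "TrajectoryRecord", "Trajectory"]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box ``(x, y, w, h)``, half-open integer convention."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            object.__setattr__(self, name, int(round(getattr(self, name))))
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative box size: {self}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing a frame array."""
        return slice(self.y, self.y2), slice(self.x, self.x2)

    def clip(self, shape: tuple[int, int]) -> "BBox":
        """Clip to an image of ``shape`` (height, width)."""
        h, w = shape[:2]
        x1 = min(max(self.x, 0), w)
        y1 = min(max(self.y, 0), h)
        x2 = min(max(self.x2, 0), w)
        y2 = min(max(self.y2, 0), h)
        return BBox(x1, y1, x2 - x1, y2 - y1)

    def expand(self, factor: float, shape: tuple[int, int] | None = None) -> "BBox":
        """Scale width/height by ``factor`` about the box center.

        Result is rounded to integers and, if ``shape`` is given, clipped
        to the frame.
        """
        if factor < 1:
            raise ValueError("expansion factor must be >= 1")
        cx, cy = self.center
        nw = int(round(self.w * factor))
        nh = int(round(self.h * factor))
        box = BBox(int(round(cx - nw / 2.0)), int(round(cy - nh / 2.0)), nw, nh)
        if shape is not None:
            box = box.clip(shape)
        return box

    def iou(self, other: "BBox") -> float:
        """Intersection-over-union with another box."""
        ix = max(0, min(self.x2, other.x2) - max(self.x, other.x))
        iy = max(0, min(self.y2, other.y2) - max(self.y, other.y))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def contains(self, x: float, y: float) -> bool:
        return self.x <= x < self.x2 and self.y <= y < self.y2

    @staticmethod
    def from_mask(mask: np.ndarray) -> "BBox":
        """Tight bounding box of the nonzero pixels of a 2-D mask."""
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            raise ValueError("empty mask has no bounding box")
        return BBox(int(xs.min()), int(ys.min()),
                    int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))


@dataclass
class VideoSequence:
    """Ordered stack of same-sized 8-bit grayscale frames."""

    frames: list[np.ndarray]
    frame_rate: float = 25.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty sequence")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D grayscale")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass(frozen=True)
class TrajectoryRecord:
    frame_index: int
    box: BBox
    centroid: tuple[float, float]
    score: float = 0.0


@dataclass
class Trajectory:
    """Per-frame (box, centroid, score) record stream for one target."""

    target_id: str = "target"
    records: list[TrajectoryRecord] = field(default_factory=list)

    def append(self, frame_index: int, box: BBox,
               centroid: tuple[float, float] | None = None,
               score: float = 0.0) -> None:
        if self.records and frame_index <= self.records[-1].frame_index:
            raise ValueError("frame_index must be strictly increasing")
        if centroid is None:
            centroid = box.center
        self.records.append(TrajectoryRecord(frame_index, box,
                                             (float(centroid[0]), float(centroid[1])),
                                             float(score)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrajectoryRecord]:
        return iter(self.records)

    def frame_indices(self) -> list[int]:
        return [r.frame_index for r in self.records]

    def by_frame(self) -> dict[int, TrajectoryRecord]:
        return {r.frame_index: r for r in self.records}

    def centroids(self) -> np.ndarray:
        return np.array([r.centroid for r in self.records], dtype=float)


def as_frame(img: np.ndarray) -> np.ndarray:
    """Coerce an array to a uint8 grayscale frame.

    Color inputs are converted to luminance; bit depths above 8 are
    linearly rescaled so the dtype maximum maps to 255.
    """
    a = np.asarray(img)
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[..., :3]
        # ITU-R 601 luma
        a = (a[..., 0] * 0.299 + a[..., 1] * 0.587 + a[..., 2] * 0.114)
        if np.issubdtype(np.asarray(img).dtype, np.integer):
            a = np.round(a)
    if a.dtype == np.uint8:
        return a.astype(np.uint8)
    if np.issubdtype(a.dtype, np.integer):
        info = np.iinfo(a.dtype) if a.dtype != np.int64 else None
        maxval = info.max if info is not None else int(a.max() or 1)
        return np.round(a.astype(float) * 255.0 / maxval).astype(np.uint8)
    # float input: assume 0..1 if within, else 0..255
    a = a.astype(float)
    if a.max() <= 1.0:
        a = a * 255.0
    return np.clip(np.round(a), 0, 255).astype(np.uint8)
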