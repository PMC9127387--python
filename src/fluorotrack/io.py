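"""Image-stack and trajectory I/O.

Sequences are read from a directory of PNG/TIFF frames (natural,
numeric-aware filename order) or from a single AVI file when an imageio
reader is available.  Trajectories round-trip exactly through CSV with
columns ``frame,x,y,w,h,cx,cy,score``.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import imageio.v2 as imageio
import numpy as np

from .core import BBox, Trajectory, TrajectoryRecord, VideoSequence, as_frame

__all__ = [
    "read_sequence", "write_sequence",
    "read_trajectory", "write_trajectory",
    "read_masks", "write_masks", "write_label_map",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def _natural_key(name: str):
    """Numeric-aware sort key: f2.png sorts before f10.png."""
    return [int(t) if t.isdigit() else t.lower()
            for t in re.split(r"(\d+)", name)]


def read_sequence(path: str | Path, pattern: str = "*") -> VideoSequence:
    """Read an ordered image stack (or one AVI) as a grayscale sequence.

    Parameters
    ----------
    path
        Directory of image frames, or a single ``.avi`` file.
    pattern
        Glob applied to filenames inside a directory (default all images).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input: {path}")
    if path.is_file():
        if path.suffix.lower() != ".avi":
            raise ValueError(f"single-file input must be .avi, got {path.name}")
        try:
            reader = imageio.get_reader(path)
            frames = [as_frame(im) for im in reader]
        except Exception as exc:  # no AVI plugin available offline
            raise ValueError(f"cannot decode AVI {path}: {exc}") from exc
        if len(frames) < 2:
            raise ValueError(f"sequence {path} has fewer than 2 frames")
        return VideoSequence(frames, source_id=str(path))

    files = sorted((p for p in path.glob(pattern)
                    if p.suffix.lower() in _IMAGE_EXTS),
                   key=lambda p: _natural_key(p.name))
    if not files:
        raise FileNotFoundError(f"no images matching {pattern!r} in {path}")
    frames = []
    shape = None
    for p in files:
        f = as_frame(imageio.imread(p))
        if shape is None:
            shape = f.shape
        elif f.shape != shape:
            raise ValueError(
                f"inconsistent frame dimensions: {p.name} is {f.shape}, "
                f"expected {shape}")
        frames.append(f)
    return VideoSequence(frames, source_id=str(path))


def write_sequence(seq: VideoSequence, path: str | Path,
                   prefix: str = "f") -> list[Path]:
    """Write frames as zero-padded PNGs ``<prefix>000.png`` ... ."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digits = max(3, len(str(len(seq) - 1)))
    out = []
    for i, frame in enumerate(seq):
        p = path / f"{prefix}{i:0{digits}d}.png"
        imageio.imwrite(p, frame)
        out.append(p)
    return out


def write_trajectory(t: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as CSV; floats keep full repr precision."""
    if not t.records:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "x", "y", "w", "h", "cx", "cy", "score"])
        for r in t.records:
            w.writerow([r.frame_index, r.box.x, r.box.y, r.box.w, r.box.h,
                        repr(r.centroid[0]), repr(r.centroid[1]),
                        repr(r.score)])
    return path


def read_trajectory(path: str | Path, target_id: str | None = None) -> Trajectory:
    path = Path(path)
    t = Trajectory(target_id or path.stem)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            t.records.append(TrajectoryRecord(
                int(row["frame"]),
                BBox(int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"])),
                (float(row["cx"]), float(row["cy"])),
                float(row["score"])))
    return t


def write_masks(masks: list[np.ndarray], path: str | Path,
                prefix: str = "mask") -> list[Path]:
    """Write binary masks as 0/255 PNGs, one per frame."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digits = max(3, len(str(max(len(masks) - 1, 0))))
    out = []
    for i, m in enumerate(masks):
        img = (np.asarray(m) > 0).astype(np.uint8) * 255
        p = path / f"{prefix}{i:0{digits}d}.png"
        imageio.imwrite(p, img)
        out.append(p)
    return out


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label image (e.g. a watershed map) as 16-bit PNG."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("labels must fit in uint16")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    imageio.imwrite(path, labels.astype(np.uint16))
    return path


def read_masks(path: str | Path, pattern: str = "*") -> list[np.ndarray]:
    seq = read_sequence(path, pattern)
    return [(f > 127).astype(np.uint8) for f in seq]
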