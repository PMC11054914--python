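"""Image/annotation I/O, preprocessing and the position-class encoding.

Coordinates are 0-based with ``x`` the column index and ``y`` the row index,
origin at the top-left.  Grayscale images are 2-D float arrays with
intensities in [0, 1]; canonical on-disk storage is 8-bit grayscale PNG plus
a ``labels.csv`` sidecar (columns ``filename, cx, cy, width, height,
profile, seed``).

The low-resolution classifier assigns one class per pixel position,
row-major and 1-based at the user-facing boundary: class 1 is the top-left
pixel, class 2 is row 0 / column 1, and class ``width*height`` is the
bottom-right pixel.  Internally 0-based labels (``class - 1``) are used.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import ConsistencyError, FormatError, RangeError, SizeError

#: BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class PupilAnnotation(NamedTuple):
    """Pupil-center coordinates in integer pixels (x = column, y = row)."""

    cx: int
    cy: int


@dataclass
class LabeledSample:
    """A grayscale eye image with its pupil-center ground truth."""

    image: np.ndarray
    annotation: PupilAnnotation
    source_tag: str = ""


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit 3-channel image, scaled to [0, 1]."""
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected an HxWx3 image, got array of shape {arr.shape}"
        )
    w = np.asarray(LUMA_WEIGHTS)
    return (arr.astype(np.float64) @ w) / 255.0


def resize(img: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    """Bilinear resize to ``out_h`` x ``out_w``; output clipped to [0, 1]."""
    if out_w < 1 or out_h < 1:
        raise SizeError(f"target size {out_w}x{out_h} must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.shape == (out_h, out_w):
        return img.copy()
    out = _sk_resize(img, (out_h, out_w), order=1, anti_aliasing=False,
                     preserve_range=True, mode="edge")
    return np.clip(out, 0.0, 1.0)


def scale_annotation(
    ann: PupilAnnotation, in_size: tuple, out_size: tuple
) -> PupilAnnotation:
    """Rescale an annotation by the per-axis size ratios.

    Coordinates are multiplied by ``out/in``, rounded to the nearest integer
    (ties toward +inf) and clipped into the output bounds.
    """
    in_w, in_h = in_size
    out_w, out_h = out_size
    cx = int(np.clip(_round_half_up(ann.cx * out_w / in_w), 0, out_w - 1))
    cy = int(np.clip(_round_half_up(ann.cy * out_h / in_h), 0, out_h - 1))
    return PupilAnnotation(cx, cy)


def crop_center(img: np.ndarray, out_w: int, out_h: int):
    """Centered crop; returns ``(cropped, (dx, dy))``.

    The offset is what must be subtracted from annotations.  Odd margins are
    split with the smaller half toward the top-left.
    """
    h, w = img.shape
    if out_w > w or out_h > h:
        raise SizeError(
            f"crop {out_w}x{out_h} larger than source {w}x{h}"
        )
    dx = (w - out_w) // 2
    dy = (h - out_h) // 2
    return img[dy:dy + out_h, dx:dx + out_w], (dx, dy)


def coord_to_class(
    ann: PupilAnnotation, width: int, height: Optional[int] = None
) -> int:
    """Row-major 1-based position class: ``cy*width + cx + 1``."""
    if ann.cx < 0 or ann.cx >= width or ann.cy < 0:
        raise RangeError(f"annotation {ann} outside a {width}-column grid")
    if height is not None and ann.cy >= height:
        raise RangeError(f"annotation {ann} outside {width}x{height} grid")
    return ann.cy * width + ann.cx + 1


def class_to_coord(
    class_index: int, width: int, height: Optional[int] = None
) -> PupilAnnotation:
    """Inverse of :func:`coord_to_class`."""
    if class_index < 1:
        raise RangeError(f"class index {class_index} must be >= 1")
    if height is not None and class_index > width * height:
        raise RangeError(
            f"class index {class_index} exceeds {width * height} classes"
        )
    idx = class_index - 1
    return PupilAnnotation(idx % width, idx // width)


# ---------------------------------------------------------------------------
# dataset directory I/O (PNG + labels.csv)
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["filename", "cx", "cy", "width", "height", "profile", "seed"]


def save_dataset(samples, path, seed: Optional[int] = None) -> None:
    """Write samples as 8-bit grayscale PNGs plus ``labels.csv``."""
    os.makedirs(path, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"img_{i:05d}.png"
        arr = np.clip(np.round(np.asarray(s.image) * 255.0), 0, 255)
        Image.fromarray(arr.astype(np.uint8), mode="L").save(
            os.path.join(path, fname)
        )
        h, w = s.image.shape
        rows.append(
            {
                "filename": fname,
                "cx": s.annotation.cx,
                "cy": s.annotation.cy,
                "width": w,
                "height": h,
                "profile": s.source_tag,
                "seed": "" if seed is None else seed,
            }
        )
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(
        os.path.join(path, "labels.csv"), index=False
    )


def load_dataset(path) -> list:
    """Load a PNG + ``labels.csv`` dataset directory.

    Raises :class:`ConsistencyError` naming the offending file when the CSV
    and the PNG files on disk disagree.
    """
    csv_path = os.path.join(path, "labels.csv")
    if not os.path.exists(csv_path):
        raise ConsistencyError(f"missing labels.csv in {path}")
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {csv_path}: {exc}") from exc
    for col in ("filename", "cx", "cy"):
        if col not in df.columns:
            raise FormatError(f"labels.csv missing required column {col!r}")
    listed = set(df["filename"])
    on_disk = {f for f in os.listdir(path) if f.lower().endswith(".png")}
    missing = sorted(listed - on_disk)
    if missing:
        raise ConsistencyError(f"labels.csv references absent file {missing[0]!r}")
    extra = sorted(on_disk - listed)
    if extra:
        raise ConsistencyError(f"image file {extra[0]!r} has no labels.csv row")
    samples = []
    for row in df.itertuples(index=False):
        with Image.open(os.path.join(path, row.filename)) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        ann = PupilAnnotation(int(row.cx), int(row.cy))
        h, w = arr.shape
        if not (0 <= ann.cx < w and 0 <= ann.cy < h):
            raise ConsistencyError(
                f"annotation {ann} out of bounds for {row.filename!r} ({w}x{h})"
            )
        tag = str(getattr(row, "profile", "")) if hasattr(row, "profile") else ""
        samples.append(LabeledSample(arr, ann, tag))
    return samples
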