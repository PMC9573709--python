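"""Image loading and canonical representation.

Every measure in this package consumes a single canonical form: a 2-D
float64 intensity array on [0, 1].  RGB inputs are converted to luminance
with ITU-R BT.601 weights and integer dtypes are rescaled by their native
maximum (``im2double`` semantics).  Focal stacks are ordered sequences of
same-shaped frames, typically a defocus-focus-defocus sweep.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Image",
    "FocalStack",
    "BT601_WEIGHTS",
    "RASTER_EXTENSIONS",
    "as_pixels",
    "prepare_pixels",
    "load_image",
    "load_stack",
]

#: ITU-R BT.601 luminance weights for R, G, B (sum to 1 exactly).
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Raster file extensions accepted when scanning a stack directory.
RASTER_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


@dataclass(frozen=True)
class Image:
    """A canonical grayscale image: finite float64 values on [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(
                f"Image requires a non-empty 2-D array, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("Image pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                "Image pixels must lie in [0, 1]; "
                f"got range [{px.min():g}, {px.max():g}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def as_pixels(image: "Image | np.ndarray") -> np.ndarray:
    """Return the float64 pixel array behind an :class:`Image` or array."""
    if isinstance(image, Image):
        return image.pixels
    return Image(np.asarray(image)).pixels


@dataclass
class FocalStack:
    """An ordered sequence of same-shaped frames swept through focus."""

    frames: list[Image]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = [f if isinstance(f, Image) else Image(f) for f in self.frames]
        if len(self.frames) < 3:
            raise ValueError(
                f"a focal stack needs at least 3 frames, got {len(self.frames)}"
            )
        if not self.labels:
            self.labels = [f"frame_{i:03d}" for i in range(len(self.frames))]
        if len(self.labels) != len(self.frames):
            raise ValueError("labels and frames must have equal length")
        shape0 = self.frames[0].shape
        for lab, frame in zip(self.labels, self.frames):
            if frame.shape != shape0:
                raise ValueError(
                    f"frame {lab!r} has shape {frame.shape}, expected {shape0}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


def prepare_pixels(raw: np.ndarray) -> np.ndarray:
    """Convert a raw decoded array to the canonical grayscale double form.

    3-channel (or 4-channel; alpha dropped) inputs are reduced to luminance
    with BT.601 weights before rescaling.  Integer dtypes divide by their
    native maximum; float inputs are assumed already on [0, 1] and clipped.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("zero-sized image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
        w = np.asarray(BT601_WEIGHTS, dtype=np.float64)
        arr = arr.astype(np.float64) @ w
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")

    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(raw).dtype).max)
        out = arr.astype(np.float64) / scale
    else:
        out = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return out


def load_image(path: "str | os.PathLike[str]") -> Image:
    """Read a PNG/TIFF/JPEG/BMP file into the canonical representation."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures -> IO error
        raise OSError(f"could not read image {path}: {exc}") from exc
    return Image(prepare_pixels(raw))


def _resolve_sources(source) -> list[Path]:
    if isinstance(source, (str, os.PathLike)):
        p = Path(source)
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir()
                if f.suffix.lower() in RASTER_EXTENSIONS and f.is_file()
            )
        elif p.is_file() and p.suffix.lower() not in RASTER_EXTENSIONS:
            # manifest: one file path per line, order preserved
            lines = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
            files = [(p.parent / ln) if not Path(ln).is_absolute() else Path(ln)
                     for ln in lines]
        else:
            raise ValueError(f"stack source {p} is neither a directory nor a manifest")
        return files
    return [Path(f) for f in source]


def load_stack(source: "str | os.PathLike[str] | Iterable[str]") -> FocalStack:
    """Load an ordered focal stack.

    ``source`` may be a directory (frames taken in lexicographic file-name
    order), a plain-text manifest file (one path per line, order preserved),
    or an explicit ordered sequence of paths.
    """
    files = _resolve_sources(source)
    if len(files) < 3:
        raise ValueError(f"a focal stack needs at least 3 frames, got {len(files)}")
    frames: list[Image] = []
    shape0: tuple[int, int] | None = None
    for f in files:
        img = load_image(f)
        if shape0 is None:
            shape0 = img.shape
        elif img.shape != shape0:
            raise ValueError(
                f"frame {f} has shape {img.shape}, expected {shape0}"
            )
        frames.append(img)
    return FocalStack(frames=frames, labels=[f.name for f in files])
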