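"""Synthetic focal stacks emulating sparse cell-like microscope scenes.

Urinary-sediment fields of view contain a handful of roughly circular
cells scattered over a near-uniform background of similar gray level — a
regime in which the background dominates naive contrast measures.  The
phantom reproduces that structure: quasi-circular bright objects with
granular interior texture over a gently shaded background.  A focal
stack is the phantom blurred under a defocus sweep whose blur radius is
zero at the in-focus frame and grows linearly toward both ends
(defocus-focus-defocus).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi

from .io import FocalStack, Image

__all__ = [
    "PhantomSpec",
    "SweepSpec",
    "make_phantom",
    "make_stack",
    "write_stack",
]

#: amplitude of the smooth background shading field
_SHADING_AMPLITUDE = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and photometry of the cell phantom."""

    height: int = 256
    width: int = 256
    n_cells: int = 12
    radius_range: tuple[float, float] = (6.0, 14.0)
    cell_contrast: float = 0.35
    background_level: float = 0.55
    texture_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom must be at least 32x32")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        top = self.background_level + _SHADING_AMPLITUDE + self.cell_contrast \
            + self.texture_amplitude
        if top > 1.0 + 1e-9:
            raise ValueError(
                "background_level + contrast + texture exceeds 1; "
                "reduce the contrast or background"
            )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["radius_range"] = list(self.radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "radius_range" in d:
            d["radius_range"] = tuple(d["radius_range"])
        return cls(**d)


@dataclass(frozen=True)
class SweepSpec:
    """The defocus sweep: frame i gets blur sigma |i - peak_frame| * step."""

    n_frames: int = 21
    peak_frame: int | None = None  # default: center frame
    step: float = 0.6
    psf: str = "gaussian"
    blur_profile: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("a sweep needs at least 3 frames")
        if self.psf not in ("gaussian", "disk"):
            raise ValueError(f"psf must be 'gaussian' or 'disk', got {self.psf!r}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        peak = self.n_frames // 2 if self.peak_frame is None else self.peak_frame
        if not 0 <= peak < self.n_frames:
            raise ValueError(f"peak_frame {peak} outside [0, {self.n_frames})")
        object.__setattr__(self, "peak_frame", peak)

    def sigma(self, i: int) -> float:
        if self.blur_profile is not None:
            return float(self.blur_profile(i))
        return abs(i - self.peak_frame) * self.step

    def to_dict(self) -> dict:
        return {"n_frames": self.n_frames, "peak_frame": self.peak_frame,
                "step": self.step, "psf": self.psf}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _place_cells(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample disjoint cell centres/radii fully inside the frame."""
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r)
    margin = 2.0
    max_attempts = 300 * max(spec.n_cells, 1)
    attempts = 0
    while len(placed) < spec.n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells of radius "
                f"{spec.radius_range} in a {spec.height}x{spec.width} frame; "
                "reduce n_cells or the radii"
            )
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        # 20% boundary perturbation allowance + render bbox + margin
        pad = np.ceil(1.25 * r) + 4.0
        if 2 * pad >= spec.height or 2 * pad >= spec.width:
            continue  # this radius cannot fit; counts toward the attempt budget
        cy = rng.uniform(pad, spec.height - pad)
        cx = rng.uniform(pad, spec.width - pad)
        if all(np.hypot(cy - py, cx - px) > 1.2 * (r + pr) + margin
               for py, px, pr in placed):
            placed.append((cy, cx, r))
    return placed


def _render_cell(canvas: np.ndarray, cy: float, cx: float, r: float,
                 contrast: float, texture_amplitude: float,
                 rng: np.random.Generator) -> None:
    """Draw one quasi-circular cell with granular interior texture."""
    # smooth boundary perturbation: low-order Fourier series, <= 20% of r
    n_harm = 3
    amps = rng.uniform(0.0, 0.2 / n_harm, size=n_harm)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)

    pad = int(np.ceil(1.25 * r)) + 2
    y0, y1 = int(cy) - pad, int(cy) + pad + 1
    x0, x1 = int(cx) - pad, int(cx) + pad + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    radius_t = r * (1.0 + sum(
        a * np.cos((m + 2) * theta + p) for m, (a, p) in enumerate(zip(amps, phases))
    ))
    # soft 1-px edge so the boundary is not aliased
    mask = np.clip(radius_t - rho + 0.5, 0.0, 1.0)

    texture = rng.normal(0.0, 1.0, size=mask.shape)
    texture = ndi.gaussian_filter(texture, 1.0)
    texture *= texture_amplitude / max(np.abs(texture).max(), 1e-12)

    patch = mask * (contrast + texture)
    canvas[y0:y1, x0:x1] += patch


def make_phantom(spec: PhantomSpec | None = None) -> Image:
    """Generate the cell phantom; deterministic given ``spec.seed``."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    # wrap-filtered so the background is periodic-smooth: no spurious
    # border discontinuity injecting fine-scale energy into every frame
    shading = rng.normal(0.0, 1.0, size=(spec.height, spec.width))
    shading = ndi.gaussian_filter(shading, sigma=min(spec.height, spec.width) / 4.0,
                                  mode="wrap")
    shading *= _SHADING_AMPLITUDE / max(np.abs(shading).max(), 1e-12)
    canvas = spec.background_level + shading

    for cy, cx, r in _place_cells(spec, rng):
        _render_cell(canvas, cy, cx, r, spec.cell_contrast,
                     spec.texture_amplitude, rng)
    return Image(np.clip(canvas, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Defocus sweep
# ---------------------------------------------------------------------------

def _disk_kernel(radius: float) -> np.ndarray:
    n = int(np.ceil(radius)) + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    k = (np.clip(radius - np.hypot(yy, xx) + 0.5, 0.0, 1.0)).astype(np.float64)
    s = k.sum()
    if s == 0.0:
        k = np.zeros_like(k)
        k[n, n] = 1.0
        return k
    return k / s


def _blur(px: np.ndarray, sigma: float, psf: str) -> np.ndarray:
    if sigma <= 0.0:
        return px.copy()
    if psf == "gaussian":
        return ndi.gaussian_filter(px, sigma, mode="wrap")
    return ndi.convolve(px, _disk_kernel(sigma * np.sqrt(2.0)), mode="wrap")


def make_stack(phantom: "Image | np.ndarray",
               sweep: SweepSpec | None = None) -> FocalStack:
    """Blur the phantom along the sweep; the peak frame is the phantom itself."""
    sweep = sweep or SweepSpec()
    px = phantom.pixels if isinstance(phantom, Image) else np.asarray(phantom, float)
    frames = []
    for i in range(sweep.n_frames):
        out = np.clip(_blur(px, sweep.sigma(i), sweep.psf), 0.0, 1.0)
        frames.append(Image(out))
    labels = [f"frame_{i:03d}" for i in range(sweep.n_frames)]
    return FocalStack(frames=frames, labels=labels)


def write_stack(stack: FocalStack, out_dir: "str | Path",
                bit_depth: int = 8, fmt: str = "png") -> list[Path]:
    """Write frames as numbered PNG/TIFF files plus a manifest.txt."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    paths = []
    for i, frame in enumerate(stack.frames):
        quant = np.round(frame.pixels * scale).astype(dtype)
        p = out_dir / f"frame_{i:03d}.{fmt}"
        iio.imwrite(p, quant)
        paths.append(p)
    (out_dir / "manifest.txt").write_text(
        "\n".join(p.name for p in paths) + "\n"
    )
    return paths
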