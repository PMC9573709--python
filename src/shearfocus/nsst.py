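"""Non-subsampled shearlet transform (NSST).

The transform has two stages.  A non-subsampled pyramid (NSP) splits the
image into one low-pass residual and one high-pass band per scale; a bank
of shear (directional) windows then splits each high-pass band into
orientation sub-bands.  Nothing is subsampled, so every sub-band has the
input's shape and the whole decomposition is translation invariant — the
property that suppresses pseudo-Gibbs ringing in subsampled designs.

Construction
------------
All filtering is pointwise multiplication in the 2-D DFT domain (circular
boundary handling), which makes three properties exact by design:

* perfect reconstruction: the scale windows telescope to 1, so summing the
  low band and all directional sub-bands recovers the input;
* shift equivariance: circular shifts commute with the transform;
* directional partition of unity: the orientation windows at each scale
  sum to 1, so the directional sub-bands sum back to the pyramid band.

Scale ``k = 1`` is the FINEST (highest-frequency) band.  The "maxflat"
pyramid uses maximally-flat polynomial transitions (the Meyer auxiliary
function) between dyadic square annuli in frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import Image, as_pixels

__all__ = [
    "NSSTConfig",
    "SubbandSet",
    "nsp_decompose",
    "shear_decompose",
    "nsst_decompose",
    "nsst_reconstruct",
]

#: Smallest image side accepted by the transform.
MIN_SIZE = 32

PYRAMID_FILTERS = ("maxflat", "cosine")


@dataclass(frozen=True)
class NSSTConfig:
    """Decomposition geometry: scales, directions per scale, filter family.

    Parameters
    ----------
    n_scales:
        Number of high-frequency scales (the pyramid depth k); the
        decomposition yields this many band-pass scales plus one low-pass
        residual.
    directions_per_scale:
        Orientation count for each scale, finest first.  Each entry must be
        a power of two >= 2.
    shear_filter_size:
        Nominal support of each directional filter in pixels.  The
        frequency-sampled windows used here span the full grid, so this
        field is validated and carried for config round-trips but does not
        alter the construction.
    pyramid_filter_id:
        Transition profile of the radial scale windows: ``"maxflat"``
        (maximally-flat polynomial) or ``"cosine"`` (raised cosine).  Both
        are perfect-reconstruction by construction.
    """

    n_scales: int = 3
    directions_per_scale: tuple[int, ...] = (4, 4, 4)
    shear_filter_size: int = 32
    pyramid_filter_id: str = "maxflat"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "directions_per_scale", tuple(int(d) for d in self.directions_per_scale)
        )
        if self.n_scales < 1:
            raise ValueError(f"n_scales must be >= 1, got {self.n_scales}")
        if len(self.directions_per_scale) != self.n_scales:
            raise ValueError(
                "directions_per_scale must have one entry per scale "
                f"({self.n_scales}), got {len(self.directions_per_scale)}"
            )
        for d in self.directions_per_scale:
            if d < 2 or d & (d - 1):
                raise ValueError(f"directions count must be a power of two >= 2, got {d}")
        if self.shear_filter_size < 1:
            raise ValueError("shear_filter_size must be positive")
        if self.pyramid_filter_id not in PYRAMID_FILTERS:
            raise ValueError(
                f"unknown pyramid_filter_id {self.pyramid_filter_id!r}; "
                f"choose from {PYRAMID_FILTERS}"
            )

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_scales": self.n_scales,
            "directions_per_scale": list(self.directions_per_scale),
            "shear_filter_size": self.shear_filter_size,
            "pyramid_filter_id": self.pyramid_filter_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NSSTConfig":
        return cls(
            n_scales=d.get("n_scales", 3),
            directions_per_scale=tuple(d.get("directions_per_scale", (4, 4, 4))),
            shear_filter_size=d.get("shear_filter_size", 32),
            pyramid_filter_id=d.get("pyramid_filter_id", "maxflat"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NSSTConfig":
        return cls.from_dict(json.loads(s))


@dataclass
class SubbandSet:
    """NSST coefficients: one low band plus directional bands per scale.

    ``high[k][l]`` is the l-th orientation sub-band of scale ``k`` (0-based
    here; scale index 0 is the finest).  Every array has the input shape.
    """

    low: np.ndarray
    high: list[list[np.ndarray]]
    config: NSSTConfig

    def __post_init__(self) -> None:
        if len(self.high) != self.config.n_scales:
            raise ValueError(
                f"expected {self.config.n_scales} high-frequency scales, "
                f"got {len(self.high)}"
            )
        shape = self.low.shape
        for k, bands in enumerate(self.high):
            if len(bands) != self.config.directions_per_scale[k]:
                raise ValueError(
                    f"scale {k + 1} holds {len(bands)} directional bands, "
                    f"config says {self.config.directions_per_scale[k]}"
                )
            for b in bands:
                if b.shape != shape:
                    raise ValueError("all sub-bands must share the input shape")


# ---------------------------------------------------------------------------
# Window construction (cached per shape/config)
# ---------------------------------------------------------------------------

def _nu_maxflat(x: np.ndarray) -> np.ndarray:
    """Maximally-flat monotone ramp on [0,1] with nu(x) + nu(1-x) = 1."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _nu_cosine(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


_NU = {"maxflat": _nu_maxflat, "cosine": _nu_cosine}


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    wy = 2.0 * np.pi * np.fft.fftfreq(shape[0])
    wx = 2.0 * np.pi * np.fft.fftfreq(shape[1])
    return np.meshgrid(wy, wx, indexing="ij")


def _symmetrize(win: np.ndarray) -> np.ndarray:
    """Average a window with its point reflection W(-omega) on the DFT grid.

    Guarantees real-valued sub-bands for real input (the Nyquist row/column
    of an even-sized grid otherwise breaks the symmetry).
    """
    refl = np.roll(win[::-1, ::-1], shift=1, axis=(0, 1))
    return 0.5 * (win + refl)


@lru_cache(maxsize=16)
def _pyramid_windows(shape: tuple[int, int], n_scales: int,
                     filter_id: str) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Radial scale windows: n_scales band-pass + 1 low-pass, summing to 1.

    The low-pass at level j passes the square |omega|_inf <= 2^-j * pi and
    decays to zero by 1.5 * 2^-j * pi; band j is the difference of adjacent
    low-passes, so the family telescopes to unity exactly.
    """
    nu = _NU[filter_id]
    WY, WX = _freq_grids(shape)
    r = np.maximum(np.abs(WY), np.abs(WX)) / np.pi  # [0, 1]

    def lowpass(cut: float) -> np.ndarray:
        t = (r - cut) / (0.5 * cut)  # transition over [cut, 1.5 cut]
        return 1.0 - nu(t)

    lows = [np.ones_like(r)]
    for j in range(1, n_scales + 1):
        lows.append(lowpass(2.0 ** (-j)))
    bands = tuple(lows[j - 1] - lows[j] for j in range(1, n_scales + 1))
    return lows[-1], bands


@lru_cache(maxsize=32)
def _direction_windows(shape: tuple[int, int], n_directions: int,
                       filter_id: str = "maxflat") -> tuple[np.ndarray, ...]:
    """Meyer-type orientation windows on theta in [0, pi), summing to 1.

    Window l is a smooth bump of width 2*pi/n centred on l*pi/n, wrapped
    periodically; adjacent bumps overlap on half their support and the
    transition identity nu(x) + nu(1-x) = 1 makes the sum exactly one.
    Each window is symmetrized under omega -> -omega so real inputs give
    real sub-bands.
    """
    nu = _NU[filter_id]
    WY, WX = _freq_grids(shape)
    theta = np.mod(np.arctan2(WY, WX), np.pi)  # orientation of the line
    t = theta / np.pi * n_directions  # [0, n)

    def bump(u: np.ndarray) -> np.ndarray:
        # smooth tent on (-1, 1): rises on (-1,0], falls on [0,1)
        return np.where(u <= 0.0, nu(1.0 + u), nu(1.0 - u))

    wins = []
    for l in range(n_directions):
        # periodic distance from centre l in units of the window spacing
        u = np.mod(t - l + n_directions / 2.0, n_directions) - n_directions / 2.0
        w = np.where(np.abs(u) < 1.0, bump(np.clip(u, -1.0, 1.0)), 0.0)
        wins.append(_symmetrize(w))
    return tuple(wins)


# ---------------------------------------------------------------------------
# Transform operations
# ---------------------------------------------------------------------------

def _check_size(px: np.ndarray, n_scales: int) -> None:
    need = max(MIN_SIZE, 2 ** (n_scales + 2))
    if min(px.shape) < need:
        raise ValueError(
            f"image of shape {px.shape} too small for {n_scales}-scale "
            f"decomposition (needs min side >= {need})"
        )


def nsp_decompose(image: "Image | np.ndarray", n_scales: int = 3,
                  pyramid_filter_id: str = "maxflat") -> tuple[np.ndarray, list[np.ndarray]]:
    """Non-subsampled pyramid: one low-pass residual + a band per scale.

    Returns ``(low, bands)`` with ``bands[0]`` the finest scale.  All
    outputs share the input shape; summing them reproduces the input.
    """
    px = as_pixels(image) if not isinstance(image, np.ndarray) else np.asarray(image, float)
    if px.ndim != 2:
        raise ValueError("nsp_decompose expects a 2-D image")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    _check_size(px, n_scales)
    low_w, band_ws = _pyramid_windows(px.shape, n_scales, pyramid_filter_id)
    F = np.fft.fft2(px)
    low = np.fft.ifft2(low_w * F).real
    bands = [np.fft.ifft2(w * F).real for w in band_ws]
    return low, bands


def shear_decompose(band: np.ndarray, n_directions: int,
                    shear_filter_size: int = 32) -> list[np.ndarray]:
    """Split a band into orientation sub-bands that sum back to it.

    The shear windows tile orientation space as a partition of unity, so
    ``sum(shear_decompose(b, n)) == b`` to numerical precision.
    """
    if n_directions < 2 or n_directions & (n_directions - 1):
        raise ValueError(
            f"n_directions must be a power of two >= 2, got {n_directions}"
        )
    if shear_filter_size < 1:
        raise ValueError("shear_filter_size must be positive")
    band = np.asarray(band, dtype=np.float64)
    wins = _direction_windows(band.shape, n_directions)
    F = np.fft.fft2(band)
    return [np.fft.ifft2(w * F).real for w in wins]


def nsst_decompose(image: "Image | np.ndarray",
                   config: NSSTConfig | None = None) -> SubbandSet:
    """Full NSST: pyramid decomposition, then directional split per scale."""
    config = config or NSSTConfig()
    px = as_pixels(image) if not isinstance(image, np.ndarray) else np.asarray(image, float)
    low, bands = nsp_decompose(px, config.n_scales, config.pyramid_filter_id)
    high = [
        shear_decompose(band, ndir, config.shear_filter_size)
        for band, ndir in zip(bands, config.directions_per_scale)
    ]
    return SubbandSet(low=low, high=high, config=config)


def nsst_reconstruct(subbands: SubbandSet) -> np.ndarray:
    """Inverse transform (validation only): sum of all sub-bands.

    Exact because the scale windows telescope to unity and each scale's
    directional windows are a partition of unity.
    """
    out = subbands.low.copy()
    for bands in subbands.high:
        for b in bands:
            out += b
    return out
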