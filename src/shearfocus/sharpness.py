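"""Focus measures: the NSST variance-energy ratio and classical baselines.

The NSST measure decomposes the image, takes the population variance of
every sub-band as its energy, and scores sharpness as the ratio of the
weighted high-frequency energy to the low-frequency energy:

    EL   = Var(low band)
    SV'k = sum over directions l of Var(band k, l)
    EkH  = SV'k / 2^k                      (k = 1 is the finest scale)
    EH   = s * E1H + (1 - s) * (sum_{k>=2} EkH) / w
    h    = EH / EL

with defaults s = 0.8 and w = 3.  Defocus drains fine-scale detail, so EH
collapses while EL (the smoothed gist of the image) barely moves; the
ratio therefore peaks sharply at focus and, because noise spreads over
many directional bands while the low band averages it away, degrades
gracefully under noise.

Classical baselines (Tenengrad/Sobel, Roberts, Laplacian, energy of
gradient, DCT high-frequency fraction, Canny edge density, plain
variance) are provided for the comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage as ndi
from skimage.feature import canny as _canny

from .io import Image, as_pixels
from .nsst import NSSTConfig, SubbandSet, nsst_decompose

__all__ = [
    "NSSTSharpnessParams",
    "EnergyBreakdown",
    "subband_variance",
    "nsst_energy_breakdown",
    "nsst_sharpness",
    "baseline_sharpness",
    "BASELINE_METHODS",
    "MEASURES",
]


@dataclass(frozen=True)
class NSSTSharpnessParams:
    """Weights of the energy ratio.

    ``s`` weighs the finest-scale energy (default 0.8); ``w`` divides the
    pooled coarser-scale energies (default 3); ``epsilon`` guards the EL
    denominator so a featureless image scores 0 rather than dividing by
    zero.
    """

    s: float = 0.8
    w: float = 3.0
    nsst: NSSTConfig = field(default_factory=NSSTConfig)
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.w <= 0:
            raise ValueError(f"w must be positive, got {self.w}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class EnergyBreakdown:
    """All intermediate energies behind one NSST sharpness score."""

    EL: float
    SV_per_scale: tuple[float, ...]
    EkH_per_scale: tuple[float, ...]
    EH: float
    h: float

    def to_dict(self) -> dict:
        return {
            "EL": self.EL,
            "SV_per_scale": list(self.SV_per_scale),
            "EkH_per_scale": list(self.EkH_per_scale),
            "EH": self.EH,
            "h": self.h,
        }


def subband_variance(coeffs: np.ndarray) -> float:
    """Population variance of a coefficient array (divide by MN, not MN-1)."""
    a = np.asarray(coeffs, dtype=np.float64)
    if a.size == 0:
        raise ValueError("subband_variance requires a non-empty array")
    return float(np.mean((a - a.mean()) ** 2))


def energy_breakdown_from_subbands(subbands: SubbandSet,
                                   params: NSSTSharpnessParams) -> EnergyBreakdown:
    """Aggregate sub-band variances into the high/low energy ratio."""
    EL = subband_variance(subbands.low)
    SV = tuple(
        float(sum(subband_variance(b) for b in bands)) for bands in subbands.high
    )
    EkH = tuple(sv / 2.0 ** (k + 1) for k, sv in enumerate(SV))  # k+1: finest is k=1
    n = len(EkH)
    coarse = sum(EkH[1:]) if n > 1 else 0.0
    EH = params.s * EkH[0] + (1.0 - params.s) * coarse / params.w
    h = EH / max(EL, params.epsilon)
    return EnergyBreakdown(EL=EL, SV_per_scale=SV, EkH_per_scale=EkH, EH=float(EH), h=float(h))


def nsst_energy_breakdown(image: "Image | np.ndarray",
                          params: NSSTSharpnessParams | None = None) -> EnergyBreakdown:
    """Decompose an image and compute the full energy breakdown."""
    params = params or NSSTSharpnessParams()
    subbands = nsst_decompose(image, params.nsst)
    return energy_breakdown_from_subbands(subbands, params)


def nsst_sharpness(image: "Image | np.ndarray",
                   params: NSSTSharpnessParams | None = None) -> float:
    """The NSST focus score h = EH / EL (larger is sharper)."""
    return nsst_energy_breakdown(image, params).h


# ---------------------------------------------------------------------------
# Baseline focus measures
# ---------------------------------------------------------------------------

_ROBERTS_A = np.array([[1.0, 0.0], [0.0, -1.0]])
_ROBERTS_B = np.array([[0.0, 1.0], [-1.0, 0.0]])
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _tenengrad(px: np.ndarray) -> float:
    gx = ndi.sobel(px, axis=1, mode="reflect")
    gy = ndi.sobel(px, axis=0, mode="reflect")
    return float(np.sum(gx**2 + gy**2))


def _roberts(px: np.ndarray) -> float:
    ra = ndi.convolve(px, _ROBERTS_A, mode="reflect")
    rb = ndi.convolve(px, _ROBERTS_B, mode="reflect")
    return float(np.sum(ra**2 + rb**2))


def _laplacian(px: np.ndarray) -> float:
    lap = ndi.convolve(px, _LAPLACIAN, mode="reflect")
    return float(np.sum(lap**2))


def _eog(px: np.ndarray) -> float:
    dv = np.diff(px, axis=0)
    dh = np.diff(px, axis=1)
    return float(np.sum(dv**2) + np.sum(dh**2))


def _dct(px: np.ndarray, cutoff_frac: float = 0.25) -> float:
    """Fraction of AC energy carried by high-frequency DCT coefficients.

    "High" means coefficients whose index sum exceeds ``cutoff_frac`` of
    the maximum index sum.  Returns 0 for a constant image (no AC energy).
    """
    c = scipy.fft.dctn(px, norm="ortho")
    total_ac = float(np.sum(c**2) - c[0, 0] ** 2)
    if total_ac <= 0.0:
        return 0.0
    m, n = px.shape
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    cutoff = cutoff_frac * (m - 1 + n - 1)
    high = float(np.sum(c[(ii + jj) > cutoff] ** 2))
    return high / total_ac


def _canny_density(px: np.ndarray, sigma: float = 1.0,
                   low: float = 0.1, high: float = 0.2) -> float:
    edges = _canny(px, sigma=sigma, low_threshold=low, high_threshold=high)
    return float(edges.mean())


BASELINE_METHODS = {
    "tenengrad": _tenengrad,
    "roberts": _roberts,
    "laplacian": _laplacian,
    "eog": _eog,
    "dct": _dct,
    "canny": _canny_density,
    "variance": subband_variance,
}


def baseline_sharpness(image: "Image | np.ndarray", method: str) -> float:
    """Score an image with one of the classical focus measures."""
    try:
        fn = BASELINE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown baseline method {method!r}; "
            f"choose from {sorted(BASELINE_METHODS)}"
        ) from None
    return float(fn(as_pixels(image)))


def _nsst_measure(px: np.ndarray, params: NSSTSharpnessParams | None = None) -> float:
    return nsst_sharpness(px, params)


#: Every measure the curve/robustness experiments can dispatch on.
MEASURES = {"nsst": _nsst_measure, **BASELINE_METHODS}
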