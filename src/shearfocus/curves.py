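"""Focus curves and their evaluation statistics.

A focus curve is the per-frame score of a focal stack, min-max normalized
to [0, 1].  Two statistics summarize how useful a curve is for
peak-seeking autofocus: the narrow width (ratio of the level-set widths
at 80% and 40% of the peak — closer to 1 means steeper) and unimodality
diagnostics (local-maximum count and the height of secondary peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import FocalStack
from .sharpness import MEASURES, NSSTSharpnessParams, baseline_sharpness, nsst_sharpness

__all__ = [
    "FocusCurve",
    "NarrowWidthResult",
    "CurveDiagnostics",
    "score_stack",
    "normalize_scores",
    "narrow_width",
    "diagnose_curve",
    "curve_frame",
]


@dataclass(frozen=True)
class FocusCurve:
    """Raw and min-max normalized per-frame scores of one stack."""

    raw: np.ndarray
    normalized: np.ndarray
    frame_labels: tuple[str, ...]
    is_constant: bool

    def __len__(self) -> int:
        return len(self.raw)


@dataclass(frozen=True)
class NarrowWidthResult:
    """Level-set widths of the normalized curve around its peak.

    ``alpha_width`` is the width at level 0.4, ``beta_width`` at 0.8, both
    in fractional frame-index units via linear interpolation.  ``ratio`` is
    beta/alpha: in (0, 1] for a unimodal curve, and larger means a steeper,
    more discriminative curve.  ``truncated`` flags widths clipped at the
    frame range.
    """

    alpha_width: float
    beta_width: float
    ratio: float
    truncated: bool = False


@dataclass(frozen=True)
class CurveDiagnostics:
    """Peak structure of a normalized curve."""

    argmax_frame: int
    n_local_maxima: int
    is_unimodal: bool
    max_secondary_peak: float
    is_constant: bool = False


def normalize_scores(raw: Sequence[float],
                     labels: Sequence[str] | None = None) -> FocusCurve:
    """Min-max rescale raw scores to [0, 1]; a constant curve maps to zeros."""
    raw_arr = np.asarray(raw, dtype=np.float64)
    if raw_arr.ndim != 1 or raw_arr.size == 0:
        raise ValueError("scores must form a non-empty 1-D sequence")
    lo, hi = float(raw_arr.min()), float(raw_arr.max())
    constant = hi == lo
    norm = np.zeros_like(raw_arr) if constant else (raw_arr - lo) / (hi - lo)
    labs = tuple(labels) if labels is not None else tuple(
        f"frame_{i:03d}" for i in range(raw_arr.size)
    )
    if len(labs) != raw_arr.size:
        raise ValueError("labels and scores must have equal length")
    return FocusCurve(raw=raw_arr, normalized=norm, frame_labels=labs,
                      is_constant=constant)


def score_stack(stack: FocalStack, measure: str,
                params: NSSTSharpnessParams | None = None) -> FocusCurve:
    """Score every frame of a stack with one measure, in frame order."""
    if measure == "nsst":
        scorer: Callable = lambda px: nsst_sharpness(px, params)
    elif measure in MEASURES:
        scorer = lambda px: baseline_sharpness(px, measure)
    else:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        )
    raw = [scorer(frame.pixels) for frame in stack.frames]
    return normalize_scores(raw, stack.labels)


# ---------------------------------------------------------------------------
# Narrow width
# ---------------------------------------------------------------------------

def _basin(y: np.ndarray, peak: int) -> tuple[int, int]:
    """Indices of the monotone basin around one peak (nearest local minima)."""
    lo = peak
    while lo > 0 and y[lo - 1] <= y[lo]:
        lo -= 1
    hi = peak
    while hi < len(y) - 1 and y[hi + 1] <= y[hi]:
        hi += 1
    return lo, hi


def _outer_crossing(y: np.ndarray, level: float, peak: int, lo: int, hi: int,
                    side: str) -> tuple[float, bool]:
    """Outermost interpolated crossing of ``level`` on one side of the peak.

    Returns (fractional index, truncated) — truncated when the curve never
    drops below the level before the range boundary.
    """
    if side == "left":
        idx = range(peak - 1, lo - 1, -1)
        boundary = float(lo)
    else:
        idx = range(peak, hi)
        boundary = float(hi)
    crossing = None
    for i in idx:
        a, b = y[i], y[i + 1]
        if (a - level) * (b - level) <= 0.0 and a != b:
            x = i + (level - a) / (b - a)
            crossing = x if crossing is None else (
                min(crossing, x) if side == "left" else max(crossing, x)
            )
    if crossing is None:
        return boundary, True
    return float(crossing), False


def narrow_width(curve: FocusCurve, peak_frame: int | None = None,
                 levels: tuple[float, float] = (0.4, 0.8)) -> NarrowWidthResult:
    """Widths of the normalized curve's level sets at 40% and 80%.

    Crossings are located by linear interpolation between samples; the
    width at each level is the distance between the outermost crossings on
    either side of the global peak (or of ``peak_frame``'s basin when
    given, for curves with several peaks).  When a level is never crossed
    before the frame range ends the width is clipped and a truncation
    warning is issued.
    """
    y = curve.normalized
    if curve.is_constant:
        raise ValueError("narrow width is undefined for a constant curve")
    peak = int(np.argmax(y)) if peak_frame is None else int(peak_frame)
    if not 0 <= peak < len(y):
        raise ValueError(f"peak_frame {peak} outside curve of length {len(y)}")
    if peak_frame is None:
        lo, hi = 0, len(y) - 1
    else:
        lo, hi = _basin(y, peak)

    widths = []
    truncated = False
    peak_val = y[peak]
    for level in levels:
        lvl = level * peak_val if peak_frame is not None else level
        left, tl = _outer_crossing(y, lvl, peak, lo, hi, "left")
        right, tr = _outer_crossing(y, lvl, peak, lo, hi, "right")
        widths.append(right - left)
        truncated |= tl or tr
    if truncated:
        warnings.warn(
            "focus curve does not cross a level on both sides of the peak; "
            "width clipped to the observed frame range",
            stacklevel=2,
        )
    alpha, beta = widths
    ratio = beta / alpha if alpha > 0 else 0.0
    return NarrowWidthResult(alpha_width=float(alpha), beta_width=float(beta),
                             ratio=float(ratio), truncated=truncated)


# ---------------------------------------------------------------------------
# Peak diagnostics
# ---------------------------------------------------------------------------

def diagnose_curve(curve: FocusCurve) -> CurveDiagnostics:
    """Count local maxima of the normalized curve and locate the peak.

    A local maximum is a frame (or plateau of equal frames, collapsed to
    its leftmost index) strictly greater than both neighbors; endpoints
    count when strictly greater than their single neighbor.  A constant
    curve has zero local maxima and is not unimodal.
    """
    y = curve.normalized
    n = len(y)
    if n == 0:
        raise ValueError("empty curve")
    if curve.is_constant or n == 1:
        return CurveDiagnostics(argmax_frame=0, n_local_maxima=0,
                                is_unimodal=False, max_secondary_peak=0.0,
                                is_constant=True)
    maxima: list[tuple[int, float]] = []  # (leftmost index, height)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append((i, float(y[i])))
        i = j + 1
    argmax = int(np.argmax(y))
    global_height = float(y[argmax])
    secondary = [h for idx, h in maxima if h < global_height]
    # plateaus tied with the global max other than the global run also count
    global_runs = [idx for idx, h in maxima if h == global_height]
    if len(global_runs) > 1:
        secondary.extend([global_height] * (len(global_runs) - 1))
    return CurveDiagnostics(
        argmax_frame=argmax,
        n_local_maxima=len(maxima),
        is_unimodal=len(maxima) == 1,
        max_secondary_peak=max(secondary) if secondary else 0.0,
        is_constant=False,
    )


def curve_frame(curves: dict[str, FocusCurve]) -> pd.DataFrame:
    """Tidy table of one or more curves: (frame_label, measure, raw, normalized)."""
    rows = []
    for measure, curve in curves.items():
        for lab, r, nv in zip(curve.frame_labels, curve.raw, curve.normalized):
            rows.append(
                {"frame_label": lab, "measure": measure,
                 "raw": float(r), "normalized": float(nv)}
            )
    return pd.DataFrame(rows, columns=["frame_label", "measure", "raw", "normalized"])
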