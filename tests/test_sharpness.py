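"""The variance energy measure and the classical baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from shearfocus import (
    NSSTConfig,
    NSSTSharpnessParams,
    baseline_sharpness,
    nsst_decompose,
    nsst_energy_breakdown,
    nsst_sharpness,
    subband_variance,
)
from shearfocus.sharpness import BASELINE_METHODS


def brute_force_variance(a):
    """Literal double-sum population variance, the independent oracle."""
    m, n = a.shape
    mean = sum(a[i, j] for i in range(m) for j in range(n)) / (m * n)
    return sum((a[i, j] - mean) ** 2 for i in range(m) for j in range(n)) / (m * n)


class TestSubbandVariance:
    def test_constant_array_is_zero(self):
        assert subband_variance(np.full((5, 7), 3.3)) == pytest.approx(0.0, abs=1e-15)

    def test_two_by_two_example(self):
        assert subband_variance(np.array([[0.0, 0.0], [1.0, 1.0]])) == 0.25

    @given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   min_side=2, max_side=8),
                      elements=st.floats(-10, 10)))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_brute_force_double_sum(self, a):
        expected = brute_force_variance(a)
        got = subband_variance(a)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_shift_invariance(self, rng):
        a = rng.random((16, 16))
        assert subband_variance(a + 0.37) == pytest.approx(
            subband_variance(a), abs=1e-10
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subband_variance(np.zeros((0, 3)))


def literal_energy_composition(subbands, s, w):
    """Independently coded aggregation of the sub-band variances.

    Follows the published recipe step by step: per-band population
    variances, per-scale directional sums, the 1/2^k scale weights with
    k = 1 the finest, the s/(1-s)/w combination, and the final ratio.
    """
    EL = float(np.mean((subbands.low - subbands.low.mean()) ** 2))
    SV = []
    for bands in subbands.high:
        SV.append(sum(float(np.mean((b - b.mean()) ** 2)) for b in bands))
    EkH = [SV[k] / 2 ** (k + 1) for k in range(len(SV))]
    EH = s * EkH[0] + (1 - s) * sum(EkH[1:]) / w
    return EH / max(EL, 1e-12)


class TestEnergyBreakdown:
    def test_constant_image_scores_zero(self):
        bd = nsst_energy_breakdown(np.full((64, 64), 0.5))
        assert bd.EL == 0.0 and bd.EH == 0.0 and bd.h == 0.0

    def test_matches_literal_composition(self, rng):
        params = NSSTSharpnessParams()
        for _ in range(20):
            img = rng.random((64, 64))
            sb = nsst_decompose(img, params.nsst)
            expected = literal_energy_composition(sb, params.s, params.w)
            assert nsst_sharpness(img, params) == pytest.approx(expected, rel=1e-12)

    def test_minimal_configuration_hand_composed(self, rng):
        # one scale, two directions, s = 1: h = (V(d1)+V(d2))/2 / V(low)
        img = rng.random((64, 64))
        cfg = NSSTConfig(n_scales=1, directions_per_scale=(2,))
        params = NSSTSharpnessParams(s=1.0, nsst=cfg)
        sb = nsst_decompose(img, cfg)
        d1, d2 = sb.high[0]
        expected = ((np.var(d1) + np.var(d2)) / 2) / np.var(sb.low)
        assert nsst_sharpness(img, params) == pytest.approx(expected, rel=1e-10)

    def test_sharp_beats_blurred(self, default_phantom):
        from scipy.ndimage import gaussian_filter
        sharp = default_phantom.pixels
        blurred = gaussian_filter(sharp, 3.0, mode="wrap")
        assert nsst_sharpness(sharp) > nsst_sharpness(blurred)

    def test_blur_monotonicity(self, default_phantom):
        from scipy.ndimage import gaussian_filter
        px = default_phantom.pixels
        hs = [nsst_sharpness(px)] + [
            nsst_sharpness(gaussian_filter(px, s, mode="wrap"))
            for s in np.arange(0.5, 5.5, 0.5)
        ]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_translation_invariance_of_h(self, default_phantom):
        px = default_phantom.pixels
        rolled = np.roll(px, (13, -29), axis=(0, 1))
        assert nsst_sharpness(rolled) == pytest.approx(nsst_sharpness(px), rel=1e-8)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NSSTSharpnessParams(s=1.5)
        with pytest.raises(ValueError):
            NSSTSharpnessParams(w=0.0)


class TestBaselines:
    @pytest.mark.parametrize("method", sorted(BASELINE_METHODS))
    def test_constant_image_scores_zero(self, method):
        assert baseline_sharpness(np.full((64, 64), 0.5), method) == 0.0

    def test_tenengrad_step_edge_is_local(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        assert baseline_sharpness(img, "tenengrad") > 0.0
        assert baseline_sharpness(np.zeros((32, 32)), "tenengrad") == 0.0

    def test_eog_of_ramp(self):
        img = np.tile(np.array([0.0, 1.0, 2.0, 3.0]) / 3.0, (5, 1))
        # horizontal term per row: 3 * (1/3)^2; 5 rows; no vertical term
        assert baseline_sharpness(img, "eog") == pytest.approx(5 * 3 * (1 / 3) ** 2)

    @pytest.mark.parametrize("method", sorted(set(BASELINE_METHODS) - {"dct", "canny"}))
    def test_intensity_shift_invariance(self, method, rng):
        a = rng.random((32, 32)) * 0.5
        assert baseline_sharpness(a + 0.25, method) == pytest.approx(
            baseline_sharpness(a, method), abs=1e-10
        )

    def test_blur_reduces_every_baseline(self, default_phantom):
        from scipy.ndimage import gaussian_filter
        sharp = default_phantom.pixels
        blurred = gaussian_filter(sharp, 3.0, mode="wrap")
        for method in BASELINE_METHODS:
            assert baseline_sharpness(sharp, method) > baseline_sharpness(
                blurred, method
            ), method

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_sharpness(np.zeros((32, 32)), "brenner")
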