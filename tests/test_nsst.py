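"""Transform correctness: perfect reconstruction, shift equivariance,
directional partition of unity, linearity, and band selectivity."""

import numpy as np
import pytest

from shearfocus import (
    NSSTConfig,
    nsp_decompose,
    nsst_decompose,
    nsst_reconstruct,
    shear_decompose,
)


def _all_bands(subbands):
    yield subbands.low
    for bands in subbands.high:
        yield from bands


class TestConfig:
    def test_defaults(self):
        cfg = NSSTConfig()
        assert cfg.n_scales == 3 and cfg.directions_per_scale == (4, 4, 4)

    @pytest.mark.parametrize("kwargs", [
        {"n_scales": 0},
        {"n_scales": 2, "directions_per_scale": (4,)},
        {"directions_per_scale": (4, 4, 3)},
        {"directions_per_scale": (4, 4, 1)},
        {"pyramid_filter_id": "unknown"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NSSTConfig(**kwargs)

    def test_json_roundtrip(self):
        cfg = NSSTConfig(n_scales=2, directions_per_scale=(8, 4))
        assert NSSTConfig.from_json(cfg.to_json()) == cfg


class TestPyramid:
    def test_constant_image_has_no_detail(self):
        low, bands = nsp_decompose(np.full((64, 64), 0.37), n_scales=3)
        for b in bands:
            assert np.abs(b).max() < 1e-10
        np.testing.assert_allclose(low, 0.37, atol=1e-10)

    def test_impulse_reconstructs_through_synthesis(self):
        img = np.zeros((64, 64))
        img[20, 31] = 1.0
        low, bands = nsp_decompose(img)
        rec = low + sum(bands)
        assert np.abs(rec - img).max() < 1e-6

    def test_sinusoid_energy_concentrates_in_finest_band(self):
        x = np.arange(64)
        img = 0.5 + 0.4 * np.cos(2 * np.pi * 28 * x / 64)[None, :] * np.ones((64, 1))
        _, bands = nsp_decompose(img, n_scales=3)
        energies = [np.sum(b**2) for b in bands]
        assert energies[0] / sum(energies) > 0.9

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            nsp_decompose(np.zeros((16, 16)), n_scales=3)

    @pytest.mark.parametrize("filter_id", ["maxflat", "cosine"])
    def test_both_filter_families_reconstruct(self, filter_id, random_image):
        low, bands = nsp_decompose(random_image, pyramid_filter_id=filter_id)
        assert np.abs(low + sum(bands) - random_image).max() < 1e-6


class TestShearDecompose:
    def test_partition_of_unity(self, random_image):
        _, bands = nsp_decompose(random_image)
        for band in bands:
            parts = shear_decompose(band, 4)
            assert np.abs(sum(parts) - band).max() < 1e-6

    def test_zero_band_gives_zero_subbands(self):
        for part in shear_decompose(np.zeros((64, 64)), 4):
            assert np.all(part == 0.0)

    def test_oriented_lines_select_different_directions(self):
        horiz = np.zeros((64, 64))
        horiz[32, 10:54] = 1.0  # a 0-degree segment
        vert = horiz.T.copy()
        _, (fine_h, *_) = nsp_decompose(horiz)
        _, (fine_v, *_) = nsp_decompose(vert)
        eh = [np.sum(p**2) for p in shear_decompose(fine_h, 4)]
        ev = [np.sum(p**2) for p in shear_decompose(fine_v, 4)]
        assert int(np.argmax(eh)) != int(np.argmax(ev))

    @pytest.mark.parametrize("n_dir", [0, 1, 3, 6])
    def test_non_power_of_two_rejected(self, n_dir):
        with pytest.raises(ValueError):
            shear_decompose(np.zeros((64, 64)), n_dir)

    def test_subbands_are_real_and_input_shaped(self, random_image):
        parts = shear_decompose(random_image, 8)
        assert len(parts) == 8
        for p in parts:
            assert p.dtype == np.float64 and p.shape == random_image.shape


class TestFullTransform:
    def test_subband_count_forced_by_config(self, random_image):
        img = np.pad(random_image, ((0, 64), (0, 64)), mode="wrap")  # 128x128
        sb = nsst_decompose(img, NSSTConfig(3, (4, 4, 4)))
        assert sb.low.shape == (128, 128)
        assert sum(len(b) for b in sb.high) == 12
        assert all(b.shape == (128, 128) for bands in sb.high for b in bands)

    def test_shift_equivariance(self, random_image):
        shift = (7, -11)
        sb = nsst_decompose(random_image)
        sb_shifted = nsst_decompose(np.roll(random_image, shift, axis=(0, 1)))
        for a, b in zip(_all_bands(sb), _all_bands(sb_shifted)):
            assert np.abs(np.roll(a, shift, axis=(0, 1)) - b).max() < 1e-8

    def test_linearity(self, rng):
        x, y = rng.random((2, 64, 64))
        a, b = 0.6, -1.7
        sb_mix = nsst_decompose(a * x + b * y + 2.0)  # offset only hits low band
        sb_x, sb_y = nsst_decompose(x), nsst_decompose(y)
        for k in range(3):
            for l in range(4):
                lhs = sb_mix.high[k][l]
                rhs = a * sb_x.high[k][l] + b * sb_y.high[k][l]
                assert np.abs(lhs - rhs).max() < 1e-8

    def test_roundtrip_perfect_reconstruction(self, random_image):
        rec = nsst_reconstruct(nsst_decompose(random_image))
        assert np.abs(rec - random_image).max() < 1e-6

    def test_constant_roundtrip_preserves_dc(self):
        img = np.full((64, 64), 0.81)
        rec = nsst_reconstruct(nsst_decompose(img))
        assert np.abs(rec - img).max() < 1e-6

    def test_blur_reduces_high_band_variance(self, default_phantom):
        from scipy.ndimage import gaussian_filter
        sharp = default_phantom.pixels
        blurred = gaussian_filter(sharp, 3.0, mode="wrap")
        def total_high_var(img):
            sb = nsst_decompose(img)
            return sum(np.var(b) for bands in sb.high for b in bands)
        assert total_high_var(sharp) > total_high_var(blurred)

    def test_reconstruct_rejects_inconsistent_subbands(self, random_image):
        sb = nsst_decompose(random_image)
        sb.high[0] = sb.high[0][:-1]
        with pytest.raises(ValueError):
            from shearfocus.nsst import SubbandSet
            SubbandSet(low=sb.low, high=sb.high, config=sb.config)
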