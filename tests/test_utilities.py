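"""Utility layer: I/O scaling, centred transforms, filtering, peak search,
speckle reduction."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

import dhmkit as dk
from dhmkit.core import ValidationError
from dhmkit.utilities import load_complex_field, save_complex_field


class TestReadImage:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0)])
    def test_8bit_full_scale(self, tmp_path, value, expected):
        p = tmp_path / "const.tif"
        tifffile.imwrite(p, np.full((16, 16), value, dtype=np.uint8))
        img = dk.read_image(p)
        assert img.pixels.shape == (16, 16)
        np.testing.assert_allclose(img.pixels, expected)

    def test_16bit_ramp_normalised(self, tmp_path):
        ramp = np.linspace(0, 65535, 256).astype(np.uint16)
        arr = np.tile(ramp, (4, 1))
        p = tmp_path / "ramp.tif"
        tifffile.imwrite(p, arr)
        img = dk.read_image(p)
        assert abs((img.pixels.max() - img.pixels.min()) - 1.0) < 1e-12
        np.testing.assert_allclose(np.diff(img.pixels[0]), np.diff(img.pixels[0])[0])

    def test_rgb_luminance_average(self, tmp_path):
        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[..., 0] = 30
        rgb[..., 1] = 60
        rgb[..., 2] = 90
        p = tmp_path / "rgb.png"
        import imageio.v3 as iio

        iio.imwrite(p, rgb)
        img = dk.read_image(p)
        np.testing.assert_allclose(img.pixels, 60.0 / 255.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises((IOError, FileNotFoundError)):
            dk.read_image(tmp_path / "nope.tif")


class TestCenteredTransforms:
    def test_constant_concentrates_at_dc(self):
        f = dk.ComplexField(np.full((32, 48), 3.0 + 0j))
        S = dk.ft_centered(f)
        dc = S.values[16, 24]
        off_dc = np.abs(S.values).sum() - abs(dc)
        assert off_dc < 1e-10 * abs(dc)

    def test_on_grid_cosine_two_symmetric_peaks(self):
        M = N = 64
        x = np.arange(N)[None, :]
        field = np.cos(2 * np.pi * 5 * x / N) * np.ones((M, 1))
        S = np.abs(dk.ft_centered(dk.RealImage(field)).values)
        peaks = np.argwhere(S > S.max() / 2)
        assert sorted(map(tuple, peaks)) == [(32, 32 - 5), (32, 32 + 5)]

    def test_delta_at_dc_gives_constant(self):
        spec = np.zeros((16, 16), complex)
        spec[8, 8] = 1.0
        out = dk.ift_centered(dk.Spectrum(spec)).values
        np.testing.assert_allclose(out, out[0, 0])

    def test_shifted_delta_gives_fringe(self):
        M = N = 32
        spec = np.zeros((M, N), complex)
        spec[16 + 4, 16] = 1.0
        out = dk.ift_centered(dk.Spectrum(spec)).values
        rows = np.arange(M) - 16
        expected = np.exp(2j * np.pi * 4 * rows / M)[:, None] * out[16, 16]
        np.testing.assert_allclose(out, np.tile(expected, (1, N)), atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([8, 17, 64]))
    def test_round_trip_and_parseval(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        f = dk.ComplexField(a)
        S = dk.ft_centered(f)
        back = dk.ift_centered(S).values
        assert np.max(np.abs(back - a)) / np.max(np.abs(a)) < 1e-10
        assert abs((np.abs(a) ** 2).sum() - (np.abs(S.values) ** 2).sum()) < 1e-8 * (
            np.abs(a) ** 2
        ).sum()

    def test_non_finite_rejected(self):
        a = np.ones((4, 4))
        a[0, 0] = np.nan
        with pytest.raises(ValidationError):
            dk.ft_centered(a)


class TestDisplayMaps:
    def test_pythagorean_triple(self):
        f = dk.ComplexField(np.full((4, 4), 3 + 4j))
        np.testing.assert_allclose(dk.amplitude(f).pixels, 5.0)
        np.testing.assert_allclose(dk.intensity(f).pixels, 25.0)
        np.testing.assert_allclose(dk.phase(f).pixels, np.arctan2(4, 3))

    def test_negative_real_phase_is_pi(self):
        f = dk.ComplexField(np.full((4, 4), -1.0 + 0j))
        np.testing.assert_allclose(dk.phase(f).pixels, np.pi)

    def test_zero_field_conventions(self):
        f = dk.ComplexField(np.zeros((4, 4), complex))
        np.testing.assert_allclose(dk.phase(f).pixels, 0.0)
        np.testing.assert_allclose(dk.amplitude(f).pixels, 0.0)

    def test_log_display(self):
        f = dk.ComplexField(np.full((4, 4), 9 + 0j))
        np.testing.assert_allclose(dk.amplitude(f, log=True).pixels, 1.0)


class TestSpatialFilter:
    def test_full_mask_is_identity(self, offaxis_hologram):
        M, N = offaxis_hologram.shape
        full = dk.RectangularFilter(0, 0, N - 1, M - 1)
        out = dk.spatial_filter(offaxis_hologram, full)
        assert (
            np.max(np.abs(out.values - offaxis_hologram.pixels))
            < 1e-10 * offaxis_hologram.pixels.max()
        )

    def test_keep_centered_demodulates_carrier(self, blob_phantom, offaxis_cfg):
        holo = dk.simulate_hologram(blob_phantom, offaxis_cfg)
        S = dk.ft_centered(holo)
        peak = dk.find_order_peak(S, upper=True)
        out = dk.spatial_filter(
            holo, dk.CircularFilter(20, peak), keep_centered=True
        )
        S2 = np.abs(dk.ft_centered(out).values)
        r, c = np.unravel_index(np.argmax(S2), S2.shape)
        assert (r, c) == (128, 128)  # residual carrier < one bin

    def test_dark_corner_mask_passes_no_energy(self, offaxis_hologram):
        out = dk.spatial_filter(offaxis_hologram, dk.CircularFilter(3, (2, 2)))
        e_in = (offaxis_hologram.pixels**2).sum()
        assert (np.abs(out.values) ** 2).sum() < 1e-6 * e_in

    def test_idempotent(self, offaxis_hologram):
        spec = dk.CircularFilter(15, (80, 90))
        once = dk.spatial_filter(offaxis_hologram, spec)
        twice = dk.spatial_filter(dk.RealImage(once.values.real, dx=None), spec)
        # filtering the (real part of an) already-filtered field with the
        # same mask keeps exactly the masked content
        S1 = dk.ft_centered(once).values
        mask = spec.mask(once.shape)
        np.testing.assert_allclose(S1 * ~mask, 0.0, atol=1e-12 * np.abs(S1).max())

    def test_out_of_bounds_rejected(self, offaxis_hologram):
        with pytest.raises(ValidationError):
            dk.spatial_filter(offaxis_hologram, dk.CircularFilter(5, (500, 10)))
        with pytest.raises(ValidationError):
            dk.spatial_filter(
                offaxis_hologram, dk.RectangularFilter(10, 10, 5, 40)
            )


class TestFindOrderPeak:
    def test_half_plane_selection(self):
        spec = np.zeros((64, 64), complex)
        spec[32 - 20, 32] = 1.0
        spec[32 + 20, 32] = 1.0
        S = dk.Spectrum(spec)
        assert dk.find_order_peak(S, upper=True) == (12, 32)
        assert dk.find_order_peak(S, upper=False) == (52, 32)

    def test_simulated_carrier_located(self, blob_phantom):
        cfg = dk.AcquisitionConfig.from_carrier_bins(30, -25)
        holo = dk.simulate_hologram(blob_phantom, cfg)
        S = dk.ft_centered(holo)
        # the real-image lobe sits at minus the carrier offset
        assert dk.find_order_peak(S, upper=True) == (128 - 30, 128 + 25)

    def test_peak_inside_exclusion_disc_raises(self):
        spec = np.zeros((64, 64), complex)
        spec[32 - 2, 32] = 1.0
        with pytest.raises(ValidationError, match="no diffraction order"):
            dk.find_order_peak(dk.Spectrum(spec), upper=True, dc_exclusion_radius=5)


class TestHybridMedianMean:
    def test_constant_unchanged(self):
        img = dk.RealImage(np.full((32, 32), 0.7))
        np.testing.assert_allclose(dk.hybrid_median_mean(img, 5).pixels, 0.7)

    def test_kernel3_equals_plain_median(self, rng):
        from scipy import ndimage

        a = rng.random((32, 32))
        out = dk.hybrid_median_mean(dk.RealImage(a), 3).pixels
        np.testing.assert_allclose(
            out, ndimage.median_filter(a, size=3, mode="nearest")
        )

    def test_denoises_salt_and_pepper(self, rng):
        clean = dk.make_phantom("blobs", (64, 64), peak_phase=1.0, seed=0).phase
        noisy = clean.copy()
        idx = rng.random(clean.shape) < 0.10
        noisy[idx] = rng.choice([0.0, 1.0], size=int(idx.sum()))
        out = dk.hybrid_median_mean(dk.RealImage(noisy), 5).pixels
        assert np.abs(out - clean).mean() < np.abs(noisy - clean).mean()

    def test_never_expands_range(self, rng):
        a = rng.random((40, 40))
        out = dk.hybrid_median_mean(dk.RealImage(a), 7).pixels
        assert out.min() >= a.min() - 1e-12 and out.max() <= a.max() + 1e-12

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            dk.hybrid_median_mean(dk.RealImage(np.ones((8, 8))), 4)


class TestComplexPersistence:
    def test_round_trip_with_calibration(self, tmp_path, rng):
        a = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        f = dk.ComplexField(a.astype(np.complex64), wavelength=0.532, dx=2.4, dy=3.1)
        p = tmp_path / "field.tif"
        save_complex_field(p, f)
        back = load_complex_field(p)
        np.testing.assert_allclose(back.values, f.values, atol=1e-6)
        assert back.wavelength == pytest.approx(0.532)
        assert back.dx == pytest.approx(2.4)
        assert back.dy == pytest.approx(3.1)
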