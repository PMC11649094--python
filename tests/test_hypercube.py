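"""Cube container, TIFF round-trip, reflectance calibration and 3-D denoising."""

import numpy as np
import pytest

from hypercut import (
    CalibrationError,
    CalibrationSet,
    ContractError,
    FormatError,
    Hypercube,
    REFERENCE_WAVELENGTHS_NM,
    calibrate_reflectance,
    gaussian_denoise,
    pseudo_rgb,
    read_cube,
    write_cube,
)


def _const_cube(value, shape=(4, 4, 3), wavelengths=(400, 405, 410)):
    return Hypercube(data=np.full(shape, float(value)), wavelengths_nm=wavelengths)


class TestContainer:
    def test_reference_grid_has_121_bands(self):
        assert len(REFERENCE_WAVELENGTHS_NM) == 121
        assert REFERENCE_WAVELENGTHS_NM[0] == 400 and REFERENCE_WAVELENGTHS_NM[-1] == 1000

    def test_wavelength_band_mismatch_rejected(self):
        with pytest.raises(ContractError):
            Hypercube(data=np.zeros((2, 2, 3)), wavelengths_nm=[400, 500])

    def test_non_increasing_wavelengths_rejected(self):
        with pytest.raises(ContractError):
            Hypercube(data=np.zeros((2, 2, 2)), wavelengths_nm=[500, 400])


class TestTiffIO:
    def test_constant_pages_round_trip(self, tmp_path):
        data = np.stack([np.full((4, 4), v) for v in (1.0, 2.0, 3.0)], axis=2)
        cube = Hypercube(data=data, wavelengths_nm=[400, 405, 410])
        path = write_cube(tmp_path / "c.tif", cube)
        back = read_cube(path)
        assert np.all(back.data[:, :, 1] == 2.0)
        assert np.array_equal(back.wavelengths_nm, [400, 405, 410])

    def test_round_trip_bit_exact_float32(self, tmp_path, rng):
        data = rng.random((6, 5, 4)).astype(np.float32)
        cube = Hypercube(data=data, wavelengths_nm=[400, 500, 600, 700])
        back = read_cube(write_cube(tmp_path / "c.tif", cube))
        assert back.data.dtype == np.float32
        assert np.array_equal(back.data, data)

    def test_121_page_stack(self, tmp_path, rng):
        data = rng.random((8, 8, 121)).astype(np.float32)
        cube = Hypercube(data=data, wavelengths_nm=REFERENCE_WAVELENGTHS_NM)
        back = read_cube(write_cube(tmp_path / "c.tif", cube))
        assert back.n_bands == 121

    def test_wavelength_count_mismatch_is_format_error(self, tmp_path, rng):
        data = rng.random((4, 4, 3)).astype(np.float32)
        cube = Hypercube(data=data, wavelengths_nm=[400, 405, 410])
        path = write_cube(tmp_path / "c.tif", cube)
        with pytest.raises(FormatError):
            read_cube(path, wavelengths_nm=[400, 405])

    def test_envi_bsq_round_trip(self, tmp_path, rng):
        from hypercut.hypercube import read_envi

        data = rng.random((3, 4, 2)).astype(np.float32)
        np.moveaxis(data, 2, 0).tofile(tmp_path / "cube.raw")
        (tmp_path / "cube.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 3\nbands = 2\ndata type = 4\n"
            "interleave = bsq\nwavelength = { 500.0, 800.0 }\n"
        )
        cube = read_envi(tmp_path / "cube.hdr")
        assert np.array_equal(cube.data, data)
        assert list(cube.wavelengths_nm) == [500.0, 800.0]

    def test_envi_non_bsq_rejected(self, tmp_path):
        (tmp_path / "cube.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\ndata type = 4\ninterleave = bil\n"
        )
        from hypercut.hypercube import read_envi

        with pytest.raises(FormatError):
            read_envi(tmp_path / "cube.hdr")

    def test_missing_sidecar_is_format_error(self, tmp_path, rng):
        data = rng.random((4, 4, 3)).astype(np.float32)
        cube = Hypercube(data=data, wavelengths_nm=[400, 405, 410])
        path = write_cube(tmp_path / "c.tif", cube)
        path.with_suffix(".wavelengths.json").unlink()
        with pytest.raises(FormatError):
            read_cube(path)


class TestCalibration:
    def test_white_maps_to_one_and_dark_to_zero(self, rng):
        dark = _const_cube(10.0)
        white = _const_cube(110.0)
        cal = CalibrationSet(white=white, dark=dark)
        assert np.allclose(calibrate_reflectance(white, cal).data, 1.0)
        assert np.allclose(calibrate_reflectance(dark, cal).data, 0.0)

    def test_midpoint_is_half(self):
        cal = CalibrationSet(white=_const_cube(110.0), dark=_const_cube(10.0))
        out = calibrate_reflectance(_const_cube(60.0), cal)
        assert np.allclose(out.data, 0.5)

    def test_affine_equivariance_under_common_scaling(self, rng):
        raw = Hypercube(data=rng.uniform(20, 90, (5, 5, 3)), wavelengths_nm=[400, 500, 600])
        dark = _const_cube(5.0, (5, 5, 3), (400, 500, 600))
        white = _const_cube(100.0, (5, 5, 3), (400, 500, 600))
        ref1 = calibrate_reflectance(raw, CalibrationSet(white=white, dark=dark)).data
        scale = 3.7
        raw2 = Hypercube(data=raw.data * scale, wavelengths_nm=raw.wavelengths_nm)
        cal2 = CalibrationSet(
            white=Hypercube(data=white.data * scale, wavelengths_nm=white.wavelengths_nm),
            dark=Hypercube(data=dark.data * scale, wavelengths_nm=dark.wavelengths_nm),
        )
        ref2 = calibrate_reflectance(raw2, cal2).data
        assert np.allclose(ref1, ref2)

    def test_guard_zeroes_degenerate_voxels_and_counts_them(self):
        white = _const_cube(100.0)
        dark_data = np.full((4, 4, 3), 5.0)
        dark_data[0, 0, 0] = 100.0  # denominator zero at one voxel
        dark = Hypercube(data=dark_data, wavelengths_nm=[400, 405, 410])
        out = calibrate_reflectance(_const_cube(60.0), CalibrationSet(white=white, dark=dark))
        assert out.data[0, 0, 0] == 0.0
        assert out.meta["guarded_voxels"] == 1

    def test_all_zero_denominator_plane_names_the_band(self):
        white = _const_cube(100.0)
        dark_data = np.full((4, 4, 3), 5.0)
        dark_data[:, :, 1] = 100.0
        dark = Hypercube(data=dark_data, wavelengths_nm=[400, 405, 410])
        with pytest.raises(CalibrationError, match="band 1"):
            calibrate_reflectance(_const_cube(60.0), CalibrationSet(white=white, dark=dark))

    def test_shape_mismatch_rejected(self):
        cal = CalibrationSet(white=_const_cube(100.0), dark=_const_cube(5.0))
        other = Hypercube(data=np.zeros((3, 3, 3)), wavelengths_nm=[400, 405, 410])
        with pytest.raises(ContractError):
            calibrate_reflectance(other, cal)


def _gaussian_kernel_1d(sigma, truncate=4.0):
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _brute_force_denoise(data, sigma, truncate=4.0):
    """Independent oracle: symmetric-pad once, full 3-D kernel sum per voxel."""
    k1 = _gaussian_kernel_1d(sigma, truncate)
    radius = (len(k1) - 1) // 2
    k3 = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    padded = np.pad(data, radius, mode="symmetric")
    out = np.empty_like(data, dtype=float)
    n = 2 * radius + 1
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                out[i, j, k] = np.sum(padded[i:i + n, j:j + n, k:k + n] * k3)
    return out


class TestDenoise:
    def test_constant_cube_unchanged(self):
        cube = _const_cube(0.4, (6, 6, 6), wavelengths=np.arange(400, 430, 5))
        out = gaussian_denoise(cube, sigma=2.0)
        assert np.allclose(out.data, 0.4, atol=1e-10)

    def test_impulse_total_mass_preserved(self):
        data = np.zeros((31, 31, 31))
        data[15, 15, 15] = 1.0
        cube = Hypercube(data=data, wavelengths_nm=np.arange(400, 1020, 20))
        out = gaussian_denoise(cube, sigma=2.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-6)

    def test_matches_triple_loop_convolution_oracle(self, rng):
        data = rng.random((9, 9, 9))
        cube = Hypercube(data=data, wavelengths_nm=np.arange(400, 1000, 70)[:9])
        out = gaussian_denoise(cube, sigma=2.0)
        expected = _brute_force_denoise(data, sigma=2.0)
        assert np.allclose(out.data, expected, rtol=1e-6, atol=1e-9)

    def test_commutes_with_axis_transposition(self, rng):
        data = rng.random((8, 8, 8))
        w = np.arange(400, 1000, 80)[:8]
        a = gaussian_denoise(Hypercube(data=data, wavelengths_nm=w), sigma=1.5).data
        b = gaussian_denoise(Hypercube(data=data.transpose(2, 0, 1), wavelengths_nm=w), sigma=1.5).data
        assert np.allclose(a, b.transpose(1, 2, 0), atol=1e-12)

    def test_nonpositive_sigma_rejected(self, small_cube):
        with pytest.raises(ContractError):
            gaussian_denoise(small_cube, sigma=0.0)


class TestPseudoRGB:
    def test_constant_bands_give_constant_channels(self):
        data = np.stack([np.full((4, 4), v) for v in (0.1, 0.5, 0.9)], axis=2)
        cube = Hypercube(data=data, wavelengths_nm=[470, 540, 610])
        img = pseudo_rgb(cube, bands_nm=(610, 540, 470))
        assert img.shape == (4, 4, 3)
        for ch in range(3):
            assert len(np.unique(img[:, :, ch])) == 1

    def test_on_grid_wavelengths_pick_exact_planes(self, rng):
        data = rng.random((5, 5, 3))
        cube = Hypercube(data=data, wavelengths_nm=[470, 540, 610])
        img = pseudo_rgb(cube, bands_nm=(610, 540, 470))
        # red channel scales the 610 nm plane: rank order preserved
        plane = data[:, :, 2]
        assert np.array_equal(np.argsort(img[:, :, 0], axis=None, kind="stable"),
                              np.argsort(np.floor((plane - plane.min()) / np.ptp(plane) * 255 + 0.5),
                                         axis=None, kind="stable"))

    def test_windowed_average_matches_direct_mean(self, rng):
        data = rng.random((4, 4, 5))
        cube = Hypercube(data=data, wavelengths_nm=[600, 605, 610, 615, 620])
        img = pseudo_rgb(cube, bands_nm=(610, 610, 610), window_nm=10.0)
        sel = (cube.wavelengths_nm >= 600) & (cube.wavelengths_nm <= 620)  # inclusive window
        mean_plane = data[:, :, sel].mean(axis=2)
        mn, mx = mean_plane.min(), mean_plane.max()
        expected = np.floor((mean_plane - mn) / (mx - mn) * 255 + 0.5).astype(np.uint8)
        assert np.array_equal(img[:, :, 0], expected)

    def test_out_of_range_wavelength_rejected(self, small_cube):
        with pytest.raises(ContractError):
            pseudo_rgb(small_cube, bands_nm=(1200, 540, 470))
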