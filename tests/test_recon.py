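"""Image formation: delays, DAS, SLSC, k-space reconstruction, display."""

import numpy as np
import pytest

from pabreast.acoustics import (
    ChannelData, InitialPressureMap, TransducerArray, simulate_channels,
)
from pabreast.phantom import GridSpec
from pabreast.recon import (
    BeamformedImage, ImageGrid, SLSCConfig,
    das, delay_channels, envelope, fft_recon, kernel_samples_for_length,
    log_compress, normalize, normalize_display, postprocess, slsc,
    spatial_coherence,
)

MM = 1e-3


def ramp_data(ne=8, nt=400, fs=40e6, c=1540.0, pitch=0.3):
    """Channel data whose sample value equals its sample index, so a
    delayed read-back reveals the delay itself."""
    rf = np.tile(np.arange(nt, dtype=float), (ne, 1))
    return ChannelData(rf=rf, sampling_frequency_hz=fs, t0=0.0,
                       speed_of_sound=c,
                       element_positions_mm=(np.arange(ne) - (ne - 1) / 2) * pitch)


def random_data(rng, ne=8, nt=300):
    return ChannelData(rf=rng.standard_normal((ne, nt)),
                       sampling_frequency_hz=40e6, t0=0.0,
                       speed_of_sound=1540.0,
                       element_positions_mm=(np.arange(ne) - (ne - 1) / 2) * 0.3)


def point_source_data(depth_mm=6.0, lateral_mm=0.0, voxel=0.1):
    grid = GridSpec(shape=(80, 60), voxel_size=voxel,
                    origin=(voxel / 2, -59 / 2 * voxel))
    iz = int(round((depth_mm - voxel / 2) / voxel))
    ix = int(np.argmin(np.abs(grid.axis_coords(1) - lateral_mm)))
    p0 = np.zeros(grid.shape)
    p0[iz, ix] = 1.0
    data = simulate_channels(InitialPressureMap(p0=p0, grid=grid))
    true_pos = (grid.axis_coords(0)[iz], grid.axis_coords(1)[ix])
    return data, ImageGrid.from_grid_spec(grid), true_pos


def peak_position(image):
    iz, ix = np.unravel_index(np.argmax(image.values), image.values.shape)
    return image.grid.z_coords[iz], image.grid.x_coords[ix]


class TestDelays:
    def test_kernel_length_conversion(self):
        # 0.270 mm at 1540 m/s and 40 MHz is the study's 7-sample kernel
        assert kernel_samples_for_length(0.270, 1540.0, 40e6) == 7

    def test_delay_matches_geometry(self, rng):
        data = ramp_data()
        for _ in range(10):
            pz = rng.uniform(2, 10)
            px = rng.uniform(-1, 1)
            win, ok = delay_channels(data, (pz, px), 1540.0)
            d = np.hypot(pz, px - data.element_positions_mm)
            expected = d * MM / 1540.0 * data.sampling_frequency_hz
            assert np.allclose(win[:, 0], expected, atol=1e-9)
            assert ok.all()

    def test_doubling_sound_speed_halves_delay(self):
        data = ramp_data()
        w1, _ = delay_channels(data, (5.0, 0.0), 1540.0)
        w2, _ = delay_channels(data, (5.0, 0.0), 3080.0)
        assert np.allclose(w2[:, 0], w1[:, 0] / 2)

    def test_out_of_span_flagged_and_zeroed(self):
        data = ramp_data(nt=20)
        win, ok = delay_channels(data, (100.0, 0.0), 1540.0)
        assert not ok.any()
        assert np.all(win == 0)


class TestDAS:
    def test_zero_rf_gives_zero_image(self):
        data = ramp_data()
        data.rf[:] = 0.0
        grid = ImageGrid(z0=1.0, dz=0.2, nz=8, x0=-0.5, dx=0.2, nx=6)
        assert np.all(das(data, grid).values == 0)

    def test_matches_brute_force_double_loop(self, rng):
        data = random_data(rng)
        grid = ImageGrid(z0=2.0, dz=0.3, nz=4, x0=-0.6, dx=0.3, nx=4)
        img = das(data, grid, 1540.0)
        fs = data.sampling_frequency_hz
        for iz, z in enumerate(grid.z_coords):
            for ix, x in enumerate(grid.x_coords):
                acc = 0.0
                for e, ex in enumerate(data.element_positions_mm):
                    idx = np.hypot(z, x - ex) * MM / 1540.0 * fs
                    i0 = int(idx)
                    if 0 <= i0 < data.rf.shape[1] - 1:
                        f = idx - i0
                        acc += data.rf[e, i0] * (1 - f) + data.rf[e, i0 + 1] * f
                assert img.values[iz, ix] == pytest.approx(acc, abs=1e-9)

    def test_point_source_localized(self):
        data, grid, true_pos = point_source_data()
        img = postprocess(das(data, grid))
        pz, px = peak_position(img)
        assert abs(pz - true_pos[0]) <= grid.dz + 1e-9
        assert abs(px - true_pos[1]) <= grid.dx + 1e-9

    def test_additivity(self, rng):
        a = random_data(rng)
        b = random_data(rng)
        ab = ChannelData(rf=a.rf + b.rf, sampling_frequency_hz=40e6, t0=0.0,
                         speed_of_sound=1540.0,
                         element_positions_mm=a.element_positions_mm)
        grid = ImageGrid(z0=2.0, dz=0.2, nz=5, x0=-0.4, dx=0.2, nx=5)
        assert np.allclose(das(ab, grid).values,
                           das(a, grid).values + das(b, grid).values,
                           atol=1e-12)


class TestSpatialCoherence:
    def test_identical_windows_are_fully_coherent(self):
        win = np.tile(np.array([1.0, 2.0, -1.0, 0.5]), (6, 1))
        for m in range(1, 6):
            assert spatial_coherence(win, m) == pytest.approx(1.0)

    def test_alternating_sign_gives_minus_one_at_lag_one(self):
        base = np.array([0.3, -1.2, 0.8])
        win = np.array([base * (-1) ** i for i in range(6)])
        assert spatial_coherence(win, 1) == pytest.approx(-1.0)

    def test_noise_windows_average_to_zero(self, rng):
        vals = [spatial_coherence(rng.standard_normal((16, 7)), 1)
                for _ in range(300)]
        assert abs(np.mean(vals)) < 0.03

    def test_zero_energy_pairs_raise(self):
        with pytest.raises(ValueError, match="zero energy"):
            spatial_coherence(np.zeros((4, 3)), 1)

    def test_invalid_lag_rejected(self):
        with pytest.raises(ValueError):
            spatial_coherence(np.ones((4, 3)), 4)


class TestSLSC:
    def test_constant_channels_sum_to_m(self):
        # identical windows on every element: each R(m) is 1, the image is M
        data = ramp_data(ne=8, nt=500)
        data.rf[:] = 1.0
        grid = ImageGrid(z0=4.0, dz=0.5, nz=2, x0=-0.3, dx=0.3, nx=2)
        for M in (1, 4, 7):
            img = slsc(data, grid, config=SLSCConfig(M=M, kernel_samples=5))
            assert np.allclose(img.values, M)

    def test_matches_brute_force_all_pairs(self, rng):
        data = random_data(rng)
        grid = ImageGrid(z0=2.0, dz=0.25, nz=4, x0=-0.4, dx=0.2, nx=4)
        fs = data.sampling_frequency_hz
        for M in (1, 3, 5):
            for kernel in (1, 3, 7):
                img = slsc(data, grid, 1540.0,
                           SLSCConfig(M=M, kernel_samples=kernel))
                half = kernel // 2
                for iz, z in enumerate(grid.z_coords):
                    for ix, x in enumerate(grid.x_coords):
                        # independent re-implementation: explicit loops over
                        # elements, lags, and window samples
                        ne = data.rf.shape[0]
                        win = np.zeros((ne, kernel))
                        for e, ex in enumerate(data.element_positions_mm):
                            idx = np.hypot(z, x - ex) * MM / 1540.0 * fs
                            for j in range(kernel):
                                p = idx + j - half
                                i0 = int(np.floor(p))
                                if 0 <= i0 < data.rf.shape[1] - 1 and p >= 0:
                                    f = p - i0
                                    win[e, j] = (data.rf[e, i0] * (1 - f)
                                                 + data.rf[e, i0 + 1] * f)
                        val = 0.0
                        for m in range(1, M + 1):
                            acc, cnt = 0.0, 0
                            for i in range(ne - m):
                                ei = np.sum(win[i] ** 2)
                                ej = np.sum(win[i + m] ** 2)
                                if ei > 0 and ej > 0:
                                    acc += win[i] @ win[i + m] / np.sqrt(ei * ej)
                                    cnt += 1
                            if cnt:
                                val += acc / cnt
                        assert img.values[iz, ix] == pytest.approx(val, abs=1e-9)

    def test_noise_channels_stay_far_below_m(self, rng):
        data = random_data(rng, ne=32, nt=800)
        grid = ImageGrid(z0=3.0, dz=0.3, nz=5, x0=-0.6, dx=0.3, nx=5)
        img = slsc(data, grid, config=SLSCConfig(M=10, kernel_samples=7))
        assert img.values.mean() < 1.0

    def test_value_range_and_postprocess_range(self, rng):
        data = random_data(rng, ne=16, nt=600)
        grid = ImageGrid(z0=3.0, dz=0.3, nz=6, x0=-0.6, dx=0.3, nx=6)
        img = slsc(data, grid, config=SLSCConfig(M=5, kernel_samples=3))
        assert np.all(img.values >= -5) and np.all(img.values <= 5)
        post = postprocess(img)
        assert np.all(post.values >= 0) and post.values.max() == 1.0

    def test_point_source_localized(self):
        data, grid, true_pos = point_source_data()
        img = postprocess(slsc(data, grid))
        pz, px = peak_position(img)
        assert abs(pz - true_pos[0]) <= grid.dz + 1e-9
        assert abs(px - true_pos[1]) <= grid.dx + 1e-9

    def test_m_exceeding_aperture_rejected(self, rng):
        data = random_data(rng, ne=8)
        grid = ImageGrid(z0=2.0, dz=0.3, nz=2, x0=0.0, dx=0.3, nx=2)
        with pytest.raises(ValueError):
            slsc(data, grid, config=SLSCConfig(M=8, kernel_samples=3))


class TestFFTRecon:
    def test_zero_rf_gives_zero_image(self):
        data = ramp_data(ne=16, nt=128)
        data.rf[:] = 0.0
        grid = ImageGrid(z0=1.0, dz=0.2, nz=10, x0=-1.0, dx=0.2, nx=10)
        assert np.allclose(fft_recon(data, grid).values, 0.0)

    def test_point_source_depth_and_das_agreement(self):
        data, grid, true_pos = point_source_data()
        img_fft = postprocess(fft_recon(data, grid))
        pz, px = peak_position(img_fft)
        assert abs(pz - true_pos[0]) <= grid.dz + 1e-9
        assert abs(px - true_pos[1]) <= grid.dx + 1e-9
        img_das = postprocess(das(data, grid))
        dz, dx = peak_position(img_das)
        assert abs(pz - dz) <= grid.dz and abs(px - dx) <= grid.dx

    def test_additivity(self, rng):
        a = random_data(rng, ne=16, nt=256)
        b = random_data(rng, ne=16, nt=256)
        ab = ChannelData(rf=a.rf + b.rf, sampling_frequency_hz=40e6, t0=0.0,
                         speed_of_sound=1540.0,
                         element_positions_mm=a.element_positions_mm)
        grid = ImageGrid(z0=1.0, dz=0.2, nz=8, x0=-1.0, dx=0.25, nx=8)
        assert np.allclose(fft_recon(ab, grid).values,
                           fft_recon(a, grid).values + fft_recon(b, grid).values,
                           atol=1e-9)


class TestEnvelopeAndDisplay:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(256)
        sig = 1.7 * np.cos(2 * np.pi * 0.125 * t)  # bin-aligned tone
        env = envelope(sig[:, None])[:, 0]
        assert np.allclose(env[30:-30], 1.7, rtol=0.01)
        assert np.all(env >= 0)

    def test_gaussian_modulated_tone_recovers_envelope(self):
        t = np.arange(512.0)
        gauss = np.exp(-(t - 256) ** 2 / (2 * 40.0 ** 2))
        sig = gauss * np.cos(2 * np.pi * 0.15 * t)
        env = envelope(sig[:, None])[:, 0]
        interior = slice(100, 412)
        assert np.allclose(env[interior], gauss[interior], atol=0.02)

    def test_short_axial_dimension_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.ones((4, 10)))

    def test_normalization_and_log_compression(self, rng):
        grid = ImageGrid(z0=1.0, dz=0.1, nz=10, x0=0.0, dx=0.1, nx=10)
        img = BeamformedImage(values=rng.random((10, 10)) * 7.0, grid=grid,
                              method="DAS", stage="envelope")
        norm = normalize(img)
        assert norm.values.max() == 1.0 and norm.stage == "normalized"
        comp = log_compress(norm)
        assert comp.values.max() == pytest.approx(0.0)
        assert comp.stage == "compressed"

    def test_slsc_display_stays_linear(self, rng):
        grid = ImageGrid(z0=1.0, dz=0.1, nz=10, x0=0.0, dx=0.1, nx=10)
        img = BeamformedImage(values=rng.random((10, 10)), grid=grid,
                              method="SLSC", stage="raw")
        disp = normalize_display(img)
        assert disp.stage == "normalized"
        assert disp.values.min() >= 0 and disp.values.max() == 1.0
        with pytest.raises(ValueError, match="linear"):
            log_compress(normalize(img))

    def test_all_zero_image_cannot_normalize(self):
        grid = ImageGrid(z0=1.0, dz=0.1, nz=5, x0=0.0, dx=0.1, nx=5)
        img = BeamformedImage(values=np.zeros((5, 5)), grid=grid,
                              method="DAS", stage="envelope")
        with pytest.raises(ValueError):
            normalize(img)
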