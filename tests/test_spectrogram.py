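"""STFT, windowing, wavelet denoising, masking and rendering."""

import numpy as np
import pytest

from glucospec.signals import ClassLabel, simulate_glucose_trace
from glucospec.spectrogram import (
    TimeFrequencyMatrix,
    WindowFunction,
    gaussian_window,
    lowpass_mask,
    render_spectrogram_image,
    segment_trace,
    stft,
    trace_to_images,
    wavelet_denoise,
)


def brute_force_stft(samples, window, hop, nfft):
    """O(n^2) direct-DFT oracle for the windowed hopped transform."""
    w = window.coefficients
    wlen = len(w)
    n_frames = 1 + (len(samples) - wlen) // hop
    n_bins = nfft // 2 + 1
    out = np.zeros((n_bins, n_frames), dtype=complex)
    for t in range(n_frames):
        seg = np.zeros(nfft)
        seg[:wlen] = samples[t * hop : t * hop + wlen] * w
        for k in range(n_bins):
            out[k, t] = sum(
                seg[n] * np.exp(-2j * np.pi * k * n / nfft) for n in range(nfft)
            )
    return out


class TestGaussianWindow:
    def test_peak_and_symmetry(self):
        w = gaussian_window(65, 10.0)
        c = w.coefficients
        assert c[32] == 1.0
        assert np.allclose(c, c[::-1], atol=1e-12)

    def test_value_at_one_sigma(self):
        w = gaussian_window(33, 8.0)
        # center is index 16; one sigma away is index 24
        assert w.coefficients[24] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_wider_sigma_raises_offset_values(self):
        narrow = gaussian_window(33, 4.0).coefficients[20]
        wide = gaussian_window(33, 12.0).coefficients[20]
        assert wide > narrow

    def test_invalid_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_window(10, 0.0)


class TestWaveletDenoise:
    def test_keep_all_is_identity(self, rng):
        x = rng.standard_normal(256)
        back = wavelet_denoise(x, levels=3, keep_detail_from=1)
        assert np.max(np.abs(back - x)) < 1e-8

    def test_low_frequency_content_preserved(self):
        t = np.arange(512) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)  # 1 Hz << fs / 2^3
        y = wavelet_denoise(x, levels=3, keep_detail_from=3)
        assert np.linalg.norm(y - x) / np.linalg.norm(x) < 0.05

    def test_white_noise_variance_shrinks(self, rng):
        x = rng.standard_normal(512)
        y = wavelet_denoise(x, levels=3, keep_detail_from=3)
        assert y.var() < x.var()

    def test_excessive_levels_error(self):
        with pytest.raises(ValueError):
            wavelet_denoise(np.ones(16), levels=5)


class TestStft:
    def test_matches_brute_force_dft(self, rng):
        window = gaussian_window(16, 4.0)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(64, 128))
            tfm = stft(x, window, hop=8, nfft=32, fs_hz=1.0)
            oracle = brute_force_stft(x, window, 8, 32)
            scale = np.abs(oracle).max()
            assert np.max(np.abs(tfm.values - oracle)) / scale <= 1e-9

    def test_sinusoid_argmax_bin(self):
        t = np.arange(500) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        tfm = stft(x, gaussian_window(100, 12.0), hop=50, nfft=256, fs_hz=100.0)
        assert np.all(np.abs(tfm.values).argmax(axis=0) == round(10 * 256 / 100))

    def test_constant_signal_is_pure_dc(self):
        # boxcar window spanning the whole DFT: no leakage at all
        window = WindowFunction(coefficients=np.ones(64), sigma=np.inf, kind="boxcar")
        tfm = stft(np.ones(200), window, hop=32, nfft=64, fs_hz=1.0)
        mags = np.abs(tfm.values)
        total = mags.sum(axis=0)
        assert np.all(mags[1:, :].sum(axis=0) / total <= 1e-10)

    def test_per_frame_parseval(self, rng):
        window = gaussian_window(32, 6.0)
        x = rng.standard_normal(256)
        nfft = 32
        tfm = stft(x, window, hop=16, nfft=nfft, fs_hz=1.0)
        for t in range(tfm.n_frames):
            seg = x[t * 16 : t * 16 + 32] * window.coefficients
            spec = tfm.values[:, t]
            # two-sided energy from the one-sided half (real input)
            twosided = np.abs(spec[0]) ** 2 + np.abs(spec[-1]) ** 2
            twosided += 2 * np.sum(np.abs(spec[1:-1]) ** 2)
            assert twosided == pytest.approx(nfft * np.sum(seg**2), rel=1e-6)

    def test_short_signal_errors(self):
        with pytest.raises(ValueError):
            stft(np.ones(8), gaussian_window(16, 4.0), hop=4, nfft=16)


class TestLowpassMask:
    def _tfm(self, rng):
        x = rng.standard_normal(128)
        return stft(x, gaussian_window(16, 4.0), hop=8, nfft=32, fs_hz=100.0)

    def test_nyquist_cutoff_identity(self, rng):
        tfm = self._tfm(rng)
        out = lowpass_mask(tfm, 50.0)
        assert np.array_equal(out.values, tfm.values)

    def test_half_bin_cutoff_keeps_only_dc(self, rng):
        tfm = self._tfm(rng)
        out = lowpass_mask(tfm, tfm.bin_hz / 2)
        assert np.all(out.values[1:, :] == 0)
        assert np.array_equal(out.values[0], tfm.values[0])

    def test_energy_bookkeeping(self, rng):
        tfm = self._tfm(rng)
        out = lowpass_mask(tfm, 20.0)
        e_in = np.sum(np.abs(tfm.values) ** 2)
        e_out = np.sum(np.abs(out.values) ** 2)
        assert e_out <= e_in
        masked = tfm.values[tfm.bin_freqs > 20.0, :]
        assert (e_out == e_in) == (np.sum(np.abs(masked) ** 2) == 0)

    def test_idempotence(self, rng):
        tfm = self._tfm(rng)
        once = lowpass_mask(tfm, 20.0)
        twice = lowpass_mask(once, 20.0)
        assert np.array_equal(once.values, twice.values)

    def test_invalid_cutoff(self, rng):
        tfm = self._tfm(rng)
        for bad in (0.0, -1.0, 50.1):
            with pytest.raises(ValueError):
                lowpass_mask(tfm, bad)


class TestRender:
    def test_constant_magnitudes_give_constant_image(self):
        tfm = TimeFrequencyMatrix(np.full((17, 9), 3.0 + 0j), fs_hz=100, hop=50, nfft=32)
        img = render_spectrogram_image(tfm, size=32)
        assert len(np.unique(img.pixels.reshape(-1, 3), axis=0)) == 1

    def test_output_dimensions(self, rng):
        for frames in (3, 9, 40):
            tfm = TimeFrequencyMatrix(
                rng.standard_normal((17, frames)) + 0j, fs_hz=100, hop=50, nfft=32
            )
            img = render_spectrogram_image(tfm, size=48)
            assert img.pixels.shape == (48, 48, 3)

    def test_rendering_is_deterministic(self, rng):
        tfm = TimeFrequencyMatrix(rng.standard_normal((17, 9)) + 0j, fs_hz=100, hop=50, nfft=32)
        a = render_spectrogram_image(tfm, size=32)
        b = render_spectrogram_image(tfm, size=32)
        assert np.array_equal(a.pixels, b.pixels)

    def test_all_zero_matrix_is_uniform_not_error(self):
        tfm = TimeFrequencyMatrix(np.zeros((17, 9), dtype=complex), fs_hz=100, hop=50, nfft=32)
        img = render_spectrogram_image(tfm, size=32)
        assert len(np.unique(img.pixels.reshape(-1, 3), axis=0)) == 1

    def test_png_round_trip(self, tmp_path):
        from glucospec.spectrogram import SpectrogramImage

        tfm = TimeFrequencyMatrix(np.ones((17, 9)) + 0j, fs_hz=100, hop=50, nfft=32)
        img = render_spectrogram_image(tfm, size=32, label=ClassLabel.HIGH)
        img.save_png(tmp_path / "x.png")
        back = SpectrogramImage.load_png(tmp_path / "x.png")
        assert np.array_equal(back.pixels, img.pixels)
        assert back.label is ClassLabel.HIGH


class TestSegmentTrace:
    def test_counts(self):
        t60 = simulate_glucose_trace("normal", 60, 100, 0)
        assert len(segment_trace(t60, 5)) == 12
        t7 = simulate_glucose_trace("normal", 7, 100, 0)
        assert len(segment_trace(t7, 5)) == 1

    def test_concatenation_partitions_signal(self):
        t = simulate_glucose_trace("normal", 60, 100, 1)
        segs = segment_trace(t, 5)
        assert np.array_equal(np.concatenate(segs), t.samples[: 12 * 500])

    def test_segment_longer_than_trace(self):
        t = simulate_glucose_trace("normal", 6, 100, 0)
        with pytest.raises(ValueError):
            segment_trace(t, 10)


def test_class_signal_survives_pipeline():
    """Mean intensity of the rendered low-frequency band orders the three
    regimes identically across seeds: the class signal survives denoising,
    STFT and rendering."""
    orders = []
    for seed in range(10):
        means = {}
        for label in ClassLabel:
            trace = simulate_glucose_trace(label, 20, 100, 500 + seed)
            imgs = trace_to_images(trace, size=64)
            means[label] = np.mean([im.pixels[-16:, :, :].mean() for im in imgs])
        orders.append(tuple(sorted(means, key=means.get)))
    assert len(set(orders)) == 1
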