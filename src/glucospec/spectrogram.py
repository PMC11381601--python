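"""Trace -> spectrogram-image conversion.

The chain is: multilevel wavelet denoising (discard the finest detail
bands), Gaussian-windowed short-time Fourier transform, ideal low-pass
masking in the time-frequency plane, then rendering to a fixed-size RGB
raster (dB magnitude, per-image min-max normalization, colormap).

Conventions: one-sided spectrum, bin 0 = DC; in rendered images frequency
increases upward and time rightward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pywt
from matplotlib import colormaps
from PIL import Image

from glucospec.signals import ClassLabel, GlucoseTrace

__all__ = [
    "WindowFunction",
    "TimeFrequencyMatrix",
    "SpectrogramImage",
    "gaussian_window",
    "wavelet_denoise",
    "stft",
    "lowpass_mask",
    "render_spectrogram_image",
    "segment_trace",
    "trace_to_images",
]


@dataclass
class WindowFunction:
    """A symmetric analysis window with unit peak at its center."""

    coefficients: np.ndarray
    sigma: float
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass
class TimeFrequencyMatrix:
    """One-sided complex STFT output, bins on rows, frames on columns."""

    values: np.ndarray  # complex [n_bins, n_frames]
    fs_hz: float
    hop: int
    nfft: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def bin_hz(self) -> float:
        """Frequency width of one DFT bin."""
        return self.fs_hz / self.nfft

    @property
    def bin_freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz


@dataclass
class SpectrogramImage:
    """A rendered fixed-size raster; the classifier's input unit."""

    pixels: np.ndarray  # uint8 [H, W, 3]
    label: ClassLabel
    colormap: str
    db_floor: float
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def save_png(self, path) -> None:
        Image.fromarray(self.pixels).save(path, format="PNG")
        sidecar = {
            "label": self.label.value,
            "numeric_tag": self.label.numeric_tag,
            "colormap": self.colormap,
            "db_floor": self.db_floor,
            "source": self.source,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load_png(cls, path) -> "SpectrogramImage":
        pixels = np.asarray(Image.open(path).convert("RGB"))
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"label": "normal", "colormap": "unknown", "db_floor": -80.0, "source": ""}
        return cls(
            pixels=pixels,
            label=ClassLabel(meta["label"]),
            colormap=meta["colormap"],
            db_floor=meta["db_floor"],
            source=meta.get("source", ""),
        )


def gaussian_window(n: int, sigma: float) -> WindowFunction:
    """Gaussian analysis window w[i] = exp(-x^2 / (2 sigma^2)).

    ``x`` is measured in samples from the window center (n-1)/2, so the
    window is symmetric with peak value exactly 1 (at the center sample for
    odd ``n``).  ``sigma`` is in samples; a larger sigma widens the main
    lobe, emphasizing lower frequencies.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sigma is None or sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.arange(n) - (n - 1) / 2.0
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return WindowFunction(coefficients=w, sigma=float(sigma), kind="gaussian")


def wavelet_denoise(
    samples: np.ndarray,
    levels: int = 3,
    keep_detail_from: int = 3,
    wavelet: str = "db4",
) -> np.ndarray:
    """Multilevel DWT denoising by discarding the finest detail bands.

    Detail levels are indexed 1 (finest) .. ``levels`` (coarsest).  All
    detail coefficients at levels strictly finer than ``keep_detail_from``
    are zeroed; approximation coefficients are always kept, so the
    reconstruction is dominated by low-frequency content.  With
    ``keep_detail_from = 1`` no coefficient is dropped and the round-trip is
    the identity (up to float error).
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = len(samples)
    if n < 2**levels:
        raise ValueError(f"signal length {n} is shorter than 2^levels = {2**levels}")
    if levels > int(np.log2(n)):
        raise ValueError(f"levels={levels} exceeds log2(len) for length {n}")
    coeffs = pywt.wavedec(samples, wavelet, level=levels)
    # coeffs = [cA_L, cD_L, cD_{L-1}, ..., cD_1]; position -j holds detail level j
    for j in range(1, levels + 1):
        if j < keep_detail_from:
            coeffs[-j] = np.zeros_like(coeffs[-j])
    rec = pywt.waverec(coeffs, wavelet)
    return rec[:n]


def stft(
    samples: np.ndarray,
    window: WindowFunction,
    hop: int,
    nfft: int,
    fs_hz: float = 1.0,
) -> TimeFrequencyMatrix:
    """Short-time Fourier transform: hopped, windowed one-sided DFTs.

    Frame ``t``, bin ``k`` is the DFT of ``samples[t*hop : t*hop+len(window)]
    * window`` zero-padded to ``nfft``; ``1 + (N - win) // hop`` frames are
    produced.
    """
    samples = np.asarray(samples, dtype=np.float64)
    win = np.asarray(window.coefficients, dtype=np.float64)
    wlen = len(win)
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    if nfft < wlen:
        raise ValueError(f"nfft={nfft} must be >= window length {wlen}")
    n = len(samples)
    if n < wlen:
        raise ValueError(f"signal length {n} shorter than one window ({wlen})")
    n_frames = 1 + (n - wlen) // hop
    starts = np.arange(n_frames) * hop
    frames = samples[starts[:, None] + np.arange(wlen)] * win
    spec = np.fft.rfft(frames, n=nfft, axis=1).T  # [n_bins, n_frames]
    return TimeFrequencyMatrix(values=spec, fs_hz=float(fs_hz), hop=int(hop), nfft=int(nfft))


def lowpass_mask(tfm: TimeFrequencyMatrix, cutoff_hz: float) -> TimeFrequencyMatrix:
    """Ideal brick-wall low-pass in the time-frequency plane.

    Bins whose center frequency exceeds ``cutoff_hz`` are zeroed; bins at or
    below the cutoff are copied bit-identically.
    """
    nyquist = tfm.fs_hz / 2.0
    if cutoff_hz is None or not (0.0 < cutoff_hz <= nyquist):
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={nyquist}], got {cutoff_hz}"
        )
    keep = tfm.bin_freqs <= cutoff_hz
    out = tfm.values.copy()
    out[~keep, :] = 0.0
    return TimeFrequencyMatrix(values=out, fs_hz=tfm.fs_hz, hop=tfm.hop, nfft=tfm.nfft)


def render_spectrogram_image(
    tfm: TimeFrequencyMatrix,
    size: int = 224,
    colormap: str = "viridis",
    db_floor: float = -80.0,
    label: ClassLabel = ClassLabel.NORMAL,
    source: str = "",
) -> SpectrogramImage:
    """Render a time-frequency matrix to a size x size RGB raster.

    Magnitudes go to dB relative to the matrix maximum, floored at
    ``db_floor``, min-max normalized per image, mapped through the colormap
    and resized.  Frequency increases upward, time rightward.  An all-zero
    matrix renders as a uniform image at the floor value.
    """
    if tfm.values.size == 0:
        raise ValueError("time-frequency matrix is empty")
    mag = np.abs(tfm.values)
    peak = mag.max()
    if peak == 0.0:
        db = np.full(mag.shape, db_floor)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / peak)
        db = np.maximum(db, db_floor)
    lo, hi = db.min(), db.max()
    norm = np.zeros_like(db) if hi == lo else (db - lo) / (hi - lo)
    rgba = colormaps[colormap](norm)
    rgb = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    rgb = rgb[::-1, :, :]  # row 0 is the highest frequency: frequency grows upward
    img = Image.fromarray(rgb).resize((size, size), resample=Image.BILINEAR)
    return SpectrogramImage(
        pixels=np.asarray(img),
        label=label,
        colormap=colormap,
        db_floor=float(db_floor),
        source=source,
    )


def segment_trace(trace: GlucoseTrace, segment_s: float = 5.0) -> list[np.ndarray]:
    """Cut a trace into non-overlapping consecutive segments.

    The trailing remainder shorter than ``segment_s`` is dropped; each
    segment implicitly carries the trace's label.
    """
    if segment_s is None or segment_s <= 0:
        raise ValueError(f"segment_s must be positive, got {segment_s}")
    seg_len = round(segment_s * trace.fs_hz)
    if seg_len > len(trace.samples):
        raise ValueError(
            f"segment of {segment_s} s ({seg_len} samples) longer than trace "
            f"({len(trace.samples)} samples)"
        )
    n_seg = len(trace.samples) // seg_len
    return [trace.samples[i * seg_len : (i + 1) * seg_len].copy() for i in range(n_seg)]


def trace_to_images(
    trace: GlucoseTrace,
    segment_s: float = 5.0,
    window_s: float = 1.0,
    hop_s: float = 0.5,
    sigma_fraction: float = 0.125,
    denoise_levels: int = 3,
    keep_detail_from: int = 3,
    cutoff_hz: float | None = None,
    size: int = 224,
    colormap: str = "viridis",
    db_floor: float = -80.0,
) -> list[SpectrogramImage]:
    """Full trace -> list-of-images pipeline (denoise, segment, STFT, render).

    Defaults: 5 s segments, 1 s Gaussian window (sigma = ``sigma_fraction``
    of the trace's samples-per-window), 50% overlap, nfft = next power of
    two >= window, low-pass cutoff at Nyquist (no-op) unless given.
    """
    clean = wavelet_denoise(trace.samples, levels=denoise_levels, keep_detail_from=keep_detail_from)
    clean = np.maximum(clean, 1e-3)
    denoised = GlucoseTrace(
        samples=clean,
        fs_hz=trace.fs_hz,
        label=trace.label,
        seed=trace.seed,
        duration_s=trace.duration_s,
        trace_id=trace.trace_id,
    )
    wlen = round(window_s * trace.fs_hz)
    hop = max(1, round(hop_s * trace.fs_hz))
    nfft = 1 << int(np.ceil(np.log2(wlen)))
    window = gaussian_window(wlen, sigma=max(1.0, sigma_fraction * wlen))
    images = []
    for i, seg in enumerate(segment_trace(denoised, segment_s)):
        tfm = stft(seg, window, hop=hop, nfft=nfft, fs_hz=trace.fs_hz)
        if cutoff_hz is not None:
            tfm = lowpass_mask(tfm, cutoff_hz)
        images.append(
            render_spectrogram_image(
                tfm,
                size=size,
                colormap=colormap,
                db_floor=db_floor,
                label=trace.label,
                source=f"{trace.trace_id}#{i}",
            )
        )
    return images
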