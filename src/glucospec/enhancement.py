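"""Otsu-gated adaptive weighted bilateral enhancement of spectrogram images.

The enhancement kernel (AWBK) is an edge-preserving bilateral smoother: each
pixel becomes a weighted aggregate of its k x k neighborhood, with a spatial
Gaussian weight in pixel distance and a range Gaussian weight in intensity
difference.  Two adaptive ingredients set it apart from a plain bilateral
filter:

* the *range* bandwidth is gated per pixel by which side of the global Otsu
  threshold the center pixel lies on — the darker side (mostly spectrogram
  background/noise floor) receives a larger smoothing bandwidth, the bright
  side (signal ridges) a smaller one, preserving edges where they matter;
* the range bandwidth is additionally scaled by the neighborhood's
  contra-harmonic mean relative to the global mean intensity, so busier,
  brighter neighborhoods smooth less aggressively.

Enhancement operates on the luminance channel of RGB spectrograms; color is
reattached afterwards by rescaling the chroma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "OtsuResult",
    "image_histogram",
    "otsu_threshold",
    "contra_harmonic_mean",
    "awbk_enhance",
    "awbk_enhance_rgb",
    "AWBKEnhancer",
]


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but degenerate for the op."""


@dataclass
class OtsuResult:
    """Optimal histogram split: threshold, criterion value, class weights."""

    threshold: int
    between_class_variance: float
    weights: tuple[float, float]  # (omega_p, omega_q), sums to 1


def image_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a uint8 grayscale image."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("image is empty")
    return np.bincount(img.astype(np.uint8).ravel(), minlength=256)


def otsu_threshold(hist: np.ndarray) -> OtsuResult:
    """Otsu's threshold: maximize the between-class variance of a histogram.

    A cut at threshold ``t`` assigns levels ``<= t`` to the dark class and
    ``> t`` to the bright class; the criterion is
    ``V(t) = w_p * w_q * (mu_p - mu_q)^2`` (equivalent to the weighted
    within/between variance decomposition).  Ties are broken toward the
    smallest ``t``.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if len(hist) != 256:
        raise ValueError(f"histogram must have 256 bins, got {len(hist)}")
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("histogram has fewer than two populated levels")
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)  # w_p(t) for cut after level t
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    w_p = omega[:-1]
    w_q = 1.0 - w_p
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_p = mu[:-1] / w_p
        mu_q = (mu_total - mu[:-1]) / w_q
        v = w_p * w_q * (mu_p - mu_q) ** 2
    v = np.where((w_p > 0) & (w_q > 0), v, -np.inf)
    t = int(np.argmax(v))  # argmax takes the first (smallest) maximizer
    return OtsuResult(
        threshold=t,
        between_class_variance=float(v[t]),
        weights=(float(w_p[t]), float(w_q[t])),
    )


def contra_harmonic_mean(values) -> float:
    """Contra-harmonic mean sum(x^2)/sum(x) of strictly positive values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if np.any(values <= 0):
        raise ValueError("values must all be positive")
    return float(np.sum(values**2) / np.sum(values))


def awbk_enhance(
    img: np.ndarray,
    kernel: int = 5,
    sigma_spatial: float = 2.0,
    sigma_range: float = 30.0,
    otsu_ratio: float = 2.0,
) -> np.ndarray:
    """Apply the Otsu-gated adaptive weighted bilateral kernel to a gray image.

    Each output pixel is ``sum_b w(a,b) i_b / sum_b w(a,b)`` over the k x k
    neighborhood, with ``w = exp(-||a-b||^2 / 2 s_s^2) *
    exp(-(i_a-i_b)^2 / 2 s_r(a)^2)``.  The per-pixel range bandwidth is

        s_r(a) = sigma_range * gate(a) * clip(m_s(a) / mean(img+1), 1/4, 4)

    where ``gate`` is ``otsu_ratio`` on the dark side of the Otsu threshold
    and 1 on the bright side, and ``m_s`` is the contra-harmonic mean of the
    (1-shifted, hence positive) neighborhood intensities.  Borders use
    reflective padding; output is clipped to [0, 255] uint8.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel}")
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigma_spatial and sigma_range must be positive")
    x = img.astype(np.float64)
    r = kernel // 2
    pad = np.pad(x, r, mode="reflect")
    h, w = x.shape

    # Stack the k^2 shifted neighborhoods: shape [k*k, H, W]
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    neigh = np.stack([pad[r + dy : r + dy + h, r + dx : r + dx + w] for dy, dx in offsets])
    spatial = np.array(
        [np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_spatial**2)) for dy, dx in offsets]
    )

    shifted = neigh + 1.0  # strictly positive for the contra-harmonic mean
    m_s = (shifted**2).sum(axis=0) / shifted.sum(axis=0)
    scale = np.clip(m_s / (x.mean() + 1.0), 0.25, 4.0)

    hist = image_histogram(img)
    if np.count_nonzero(hist) < 2:
        gate = np.ones_like(x)  # flat image: nothing to gate
    else:
        t = otsu_threshold(hist).threshold
        gate = np.where(x <= t, float(otsu_ratio), 1.0)
    s_r = sigma_range * gate * scale

    diff = neigh - x[None, :, :]
    weights = spatial[:, None, None] * np.exp(-(diff**2) / (2.0 * s_r[None, :, :] ** 2))
    out = (weights * neigh).sum(axis=0) / weights.sum(axis=0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def contrast_stretch(img: np.ndarray) -> np.ndarray:
    """Linear stretch of a grayscale image to the full [0, 255] range.

    A constant image is returned unchanged (the stretch is undefined).
    """
    x = np.asarray(img, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.asarray(img).astype(np.uint8)
    return np.clip(np.rint((x - lo) * 255.0 / (hi - lo)), 0, 255).astype(np.uint8)


def awbk_enhance_rgb(
    img: np.ndarray,
    kernel: int = 5,
    sigma_spatial: float = 2.0,
    sigma_range: float = 30.0,
    otsu_ratio: float = 2.0,
    stretch: bool = False,
) -> np.ndarray:
    """Enhance the luminance of an RGB image, preserving chroma ratios.

    With ``stretch=True`` the denoised luminance is additionally
    contrast-stretched to the full intensity range, spreading the histogram
    of the enhanced spectrogram instead of leaving it piled up in a narrow
    band.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        out = awbk_enhance(img, kernel, sigma_spatial, sigma_range, otsu_ratio)
        return contrast_stretch(out) if stretch else out
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB, got shape {img.shape}")
    rgb = img.astype(np.float64)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    enhanced = awbk_enhance(
        np.clip(np.rint(luma), 0, 255).astype(np.uint8),
        kernel,
        sigma_spatial,
        sigma_range,
        otsu_ratio,
    )
    if stretch:
        enhanced = contrast_stretch(enhanced)
    ratio = enhanced.astype(np.float64) / np.maximum(luma, 1e-9)
    out = rgb * ratio[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


class AWBKEnhancer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer applying AWBK to image batches.

    Accepts arrays of shape [N, H, W] (grayscale) or [N, H, W, 3] (RGB,
    enhanced on the luminance channel).
    """

    def __init__(
        self,
        kernel: int = 5,
        sigma_spatial: float = 2.0,
        sigma_range: float = 30.0,
        otsu_ratio: float = 2.0,
        stretch: bool = True,
    ):
        self.kernel = kernel
        self.sigma_spatial = sigma_spatial
        self.sigma_range = sigma_range
        self.otsu_ratio = otsu_ratio
        self.stretch = stretch

    def fit(self, X, y=None):
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def transform(self, X):
        X = np.asarray(X)
        return np.stack(
            [
                awbk_enhance_rgb(
                    im, self.kernel, self.sigma_spatial, self.sigma_range,
                    self.otsu_ratio, stretch=self.stretch,
                )
                for im in X
            ]
        )
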