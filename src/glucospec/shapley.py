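"""Shapley-value explanations over superpixel features.

A spectrogram image is partitioned into a small grid of rectangular patches;
each patch is one player in the Shapley game.  A coalition is evaluated by
substituting the pixels of absent patches with a background reference image
and calling the model.  Exact mode enumerates all 2^M coalitions (M <= 16);
sampled mode averages marginal contributions over random permutations and
reports a Monte-Carlo standard error per feature.

Exact Shapley values satisfy local accuracy (baseline + sum(phi) equals the
prediction on the instance), symmetry and the dummy axiom.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "Explanation",
    "superpixel_partition",
    "exact_shapley",
    "sampled_shapley",
    "shap_overlay",
]


@dataclass
class Explanation:
    """Per-feature Shapley attributions plus the background baseline."""

    phi: np.ndarray
    baseline: float
    prediction: float
    feature_partition: np.ndarray  # int map [H, W], patch index per pixel
    standard_error: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "baseline": self.baseline,
            "prediction": self.prediction,
            "phi": [float(v) for v in self.phi],
            "standard_error": None
            if self.standard_error is None
            else [float(v) for v in self.standard_error],
            **self.meta,
        }
        return json.dumps(obj, indent=2)


def superpixel_partition(image: np.ndarray, grid: int) -> np.ndarray:
    """Tile an image into a grid x grid map of rectangular patch indices.

    Returns an int array [H, W] assigning each pixel to one of grid^2
    contiguous patches.  When the grid does not divide the image evenly the
    remainder pixels are absorbed by the edge patches.
    """
    image = np.asarray(image)
    if grid < 1:
        raise ValueError(f"grid must be >= 1, got {grid}")
    h, w = image.shape[:2]
    if grid > h or grid > w:
        raise ValueError(f"grid {grid} exceeds image size {h}x{w}")
    rows = np.minimum(np.arange(h) * grid // h, grid - 1)
    cols = np.minimum(np.arange(w) * grid // w, grid - 1)
    return (rows[:, None] * grid + cols[None, :]).astype(int)


def _masked_images(instance, background, partition, coalitions):
    """Build one image per coalition: patches outside the coalition are
    replaced by the background pixels."""
    out = np.empty((len(coalitions),) + instance.shape, dtype=instance.dtype)
    for i, coalition in enumerate(coalitions):
        keep = np.isin(partition, list(coalition)) if coalition else np.zeros(partition.shape, bool)
        img = background.copy()
        img[keep] = instance[keep]
        out[i] = img
    return out


def exact_shapley(predict_fn, instance, background, partition) -> Explanation:
    """Exact Shapley values by full coalition enumeration.

    ``phi_i = sum_{S not containing i} |S|! (M-|S|-1)! / M! *
    [f(S u {i}) - f(S)]`` with coalition evaluation by background
    substitution.  ``predict_fn`` maps a batch of images to a vector of
    scalar outputs.  Refuses more than 16 features.
    """
    instance = np.asarray(instance)
    background = np.asarray(background)
    if background.shape != instance.shape:
        raise ValueError("background must match the instance shape")
    features = np.unique(partition)
    m = len(features)
    if m > 16:
        raise ValueError(
            f"{m} features is too many for exact enumeration (max 16); "
            "use sampled_shapley"
        )
    subsets = []
    for size in range(m + 1):
        subsets.extend(combinations(features, size))
    values = np.asarray(
        predict_fn(_masked_images(instance, background, partition, subsets)), dtype=np.float64
    )
    v = {frozenset(s): values[i] for i, s in enumerate(subsets)}

    fact = [math.factorial(i) for i in range(m + 1)]
    phi = np.zeros(m)
    for i, feat in enumerate(features):
        for s in subsets:
            if feat in s:
                continue
            weight = fact[len(s)] * fact[m - len(s) - 1] / fact[m]
            phi[i] += weight * (v[frozenset(s) | {feat}] - v[frozenset(s)])
    return Explanation(
        phi=phi,
        baseline=float(v[frozenset()]),
        prediction=float(v[frozenset(features)]),
        feature_partition=np.asarray(partition),
        meta={"mode": "exact", "n_features": m},
    )


def sampled_shapley(
    predict_fn, instance, background, partition, n_samples: int, seed: int = 0
) -> Explanation:
    """Permutation-sampling Shapley estimate with per-feature standard error.

    ``n_samples`` counts marginal-contribution draws in total (>= 10 per
    feature); they are organized into ``ceil(n_samples / M)`` random
    permutations, each contributing one marginal per feature.  Deterministic
    given ``seed``.  With a single feature the estimate is exact.
    """
    instance = np.asarray(instance)
    background = np.asarray(background)
    features = np.unique(partition)
    m = len(features)
    if n_samples < 10 * m:
        raise ValueError(f"n_samples must be >= 10 * n_features = {10 * m}, got {n_samples}")
    rng = np.random.default_rng(seed)
    n_perms = math.ceil(n_samples / m)
    contributions = np.zeros((n_perms, m))
    baseline = float(np.asarray(predict_fn(_masked_images(instance, background, partition, [()])))[0])
    full = float(
        np.asarray(predict_fn(_masked_images(instance, background, partition, [tuple(features)])))[0]
    )
    for p in range(n_perms):
        order = rng.permutation(m)
        coalitions = [tuple(features[order[:k]]) for k in range(m + 1)]
        vals = np.asarray(
            predict_fn(_masked_images(instance, background, partition, coalitions)),
            dtype=np.float64,
        )
        for k, j in enumerate(order):
            contributions[p, j] = vals[k + 1] - vals[k]
    phi = contributions.mean(axis=0)
    se = contributions.std(axis=0, ddof=1) / math.sqrt(n_perms) if n_perms > 1 else np.zeros(m)
    return Explanation(
        phi=phi,
        baseline=baseline,
        prediction=full,
        feature_partition=np.asarray(partition),
        standard_error=se,
        meta={"mode": "sampled", "n_features": m, "n_permutations": n_perms, "seed": seed},
    )


#: Pink (positive) and blue (negative) overlay colors, RGB.
_PINK = np.array([255.0, 105.0, 180.0])
_BLUE = np.array([65.0, 105.0, 225.0])


def shap_overlay(image: np.ndarray, explanation: Explanation) -> np.ndarray:
    """Blend an attribution overlay onto the image.

    Patches with positive phi are tinted with a pink ramp, negative with
    blue; the blend alpha is proportional to |phi| / max|phi|.  An all-zero
    attribution returns the image unchanged.
    """
    image = np.asarray(image)
    partition = explanation.feature_partition
    if partition.shape != image.shape[:2]:
        raise ValueError("explanation partition does not match image dimensions")
    phi = np.asarray(explanation.phi, dtype=np.float64)
    peak = np.abs(phi).max()
    if peak == 0:
        return image.copy()
    out = image.astype(np.float64)
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    features = np.unique(partition)
    for i, feat in enumerate(features):
        alpha = 0.6 * abs(phi[i]) / peak
        if alpha == 0:
            continue
        color = _PINK if phi[i] > 0 else _BLUE
        mask = partition == feat
        out[mask] = (1 - alpha) * out[mask] + alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
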