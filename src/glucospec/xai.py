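"""Transparent feature weighting, fitness scoring and feature selection.

The scheme makes the classifier head interpretable: each penultimate
feature receives an importance weight initialized from the absolute
products of its paths through the head (input-hidden times hidden-output
weights), and a fitness score mixing masked-accuracy impact with the
feature's information gain.  Fitness values are refined over iterations by
a bounded step whose size follows a decaying schedule
``eta(m) = 2 exp(-(4 m / m_t)^2)`` modulated by a chaotic logistic-map
coefficient; low-fitness features are then pruned by quantile.

The scheme runs as a post-training wrapper over frozen penultimate
features; it never touches the convolutional backbone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "FeatureWeights",
    "FitnessScore",
    "init_feature_weights",
    "eta_coefficient",
    "chaotic_theta",
    "update_fitness",
    "gradient_step",
    "feature_fitness",
    "information_gain",
    "select_features",
    "weighted_training_loss",
    "FeatureWeightSelector",
]


@dataclass
class FeatureWeights:
    """Nonnegative per-feature weights plus their fitness trajectory."""

    omega: np.ndarray
    fitness: np.ndarray
    iteration: int = 0
    total_iterations: int = 0

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        self.fitness = np.asarray(self.fitness, dtype=np.float64)
        if len(self.omega) != len(self.fitness):
            raise ValueError("omega and fitness must have equal length")
        if np.any(~np.isfinite(self.omega)) or np.any(self.omega < 0):
            raise ValueError("omega must be finite and nonnegative")


@dataclass
class FitnessScore:
    """Feature fitness: a convex mix of accuracy and feature parsimony."""

    value: float
    components: dict = field(default_factory=dict)


def init_feature_weights(input_hidden: np.ndarray, hidden_output: np.ndarray) -> np.ndarray:
    """Per-input-feature importance: sum of |w_xy * w_yo| over all paths.

    ``input_hidden`` is [n_features, n_hidden]; ``hidden_output`` is
    [n_hidden, n_outputs].  The weight of feature ``x`` sums the absolute
    products along every hidden-to-output path starting at ``x``.
    """
    wxy = np.atleast_2d(np.asarray(input_hidden, dtype=np.float64))
    wyo = np.atleast_2d(np.asarray(hidden_output, dtype=np.float64))
    if wxy.shape[1] != wyo.shape[0]:
        raise ValueError(
            f"inner dimensions disagree: input_hidden {wxy.shape} vs hidden_output {wyo.shape}"
        )
    return np.abs(wxy) @ np.abs(wyo).sum(axis=1)


def eta_coefficient(m: int, m_t: int) -> float:
    """Decaying step-size schedule eta = 2 exp(-(4 m / m_t)^2), in (0, 2]."""
    if m_t is None or m_t <= 0:
        raise ValueError(f"m_t must be positive, got {m_t}")
    if not (0 <= m <= m_t):
        raise ValueError(f"m must lie in [0, m_t={m_t}], got {m}")
    return 2.0 * math.exp(-((4.0 * m / m_t) ** 2))


def chaotic_theta(state: float) -> tuple[float, float]:
    """Logistic-map coefficient: returns (theta = state, next state).

    The next state is ``4 s (1 - s)``.  ``s = 0.5`` maps to 1.0, which is a
    degenerate absorbing value; it is flagged by reseeding the orbit at
    0.123 (and the current theta is still returned).
    """
    if not (0.0 < state < 1.0):
        raise ValueError(f"state must lie in (0, 1), got {state}")
    nxt = 4.0 * state * (1.0 - state)
    if nxt <= 0.0 or nxt >= 1.0:  # degenerate orbit (state 0.5 or numeric edge)
        nxt = 0.123
    return float(state), float(nxt)


def update_fitness(
    f_x, eta: float, theta: float, gamma: float, t_l: float = 0.0, t_u: float = 1.0
):
    """Bounded fitness step: f' = f_x +/- eta * ((t_u - t_l) theta + t_l).

    Additive when the gradient sign ``gamma`` is >= 0, subtractive when
    negative.  ``gamma`` may be a scalar or a per-feature vector.
    """
    if t_u < t_l:
        raise ValueError(f"t_u ({t_u}) must be >= t_l ({t_l})")
    step = eta * ((t_u - t_l) * theta + t_l)
    sign = np.where(np.asarray(gamma) >= 0, 1.0, -1.0)
    out = np.asarray(f_x, dtype=np.float64) + sign * step
    return float(out) if np.isscalar(f_x) else out


def gradient_step(g: float, alpha: float, grad: float) -> float:
    """One gradient-descent step g' = g - alpha * dL/dg."""
    if not all(np.isfinite([g, alpha, grad])):
        raise ValueError("gradient_step requires finite inputs")
    return g - alpha * grad


def feature_fitness(acc: float, i_gain: float, tot_f: int, omega: float = 0.5) -> FitnessScore:
    """Fitness f = omega * acc + (1 - omega) * (1 - I_gain / tot_f)."""
    if tot_f is None or tot_f < 1:
        raise ValueError(f"tot_f must be >= 1, got {tot_f}")
    if not (0.0 <= acc <= 1.0):
        raise ValueError(f"acc must lie in [0, 1], got {acc}")
    value = omega * acc + (1.0 - omega) * (1.0 - i_gain / tot_f)
    return FitnessScore(
        value=float(value),
        components={"acc": acc, "i_gain": i_gain, "tot_f": tot_f, "omega": omega},
    )


def information_gain(feature: np.ndarray, labels: np.ndarray, bins: int = 8) -> float:
    """Information gain H(labels) - H(labels | binned feature), in bits."""
    feature = np.asarray(feature, dtype=np.float64)
    labels = np.asarray(labels)
    if len(feature) != len(labels) or len(labels) < 2:
        raise ValueError("feature and labels must have equal length >= 2")
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        return 0.0
    lo, hi = feature.min(), feature.max()
    if hi == lo:
        binned = np.zeros(len(feature), dtype=int)
    else:
        edges = np.linspace(lo, hi, bins + 1)
        binned = np.clip(np.digitize(feature, edges[1:-1]), 0, bins - 1)
    joint = np.zeros((bins, len(classes)))
    np.add.at(joint, (binned, y), 1.0)
    joint /= joint.sum()
    p_bin = joint.sum(axis=1)
    p_cls = joint.sum(axis=0)

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_y = _ent(p_cls)
    h_cond = sum(_ent(joint[b] / p_bin[b]) * p_bin[b] for b in range(bins) if p_bin[b] > 0)
    return max(0.0, h_y - h_cond)


def select_features(omega: np.ndarray, fitness: np.ndarray, q: float = 0.75) -> np.ndarray:
    """Keep the top ``ceil(q * n)`` features by fitness (ties kept).

    Features whose fitness reaches the (1-q)-quantile boundary value are all
    kept, so a uniform fitness vector keeps everything; at least one feature
    is always kept.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must lie in (0, 1], got {q}")
    fitness = np.asarray(fitness, dtype=np.float64)
    n = len(fitness)
    k = max(1, math.ceil(q * n))
    boundary = np.sort(fitness)[::-1][k - 1]
    return fitness >= boundary


def weighted_training_loss(per_sample_loss, features, omega) -> float:
    """Feature-weight-aware training loss.

    Each sample's loss is scaled by its relevance — the omega-weighted mean
    of its absolute penultimate activations, normalized to unit mean over
    the batch — so samples expressing highly weighted features count more.
    With all weights equal the result is exactly the plain mean loss.
    """
    loss = np.asarray(per_sample_loss, dtype=np.float64)
    feats = np.abs(np.asarray(features, dtype=np.float64))
    w = np.asarray(omega, dtype=np.float64)
    denom = feats.sum(axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    relevance = (feats * w).sum(axis=1) / denom
    mean_rel = relevance.mean()
    if mean_rel > 0:
        relevance = relevance / mean_rel
    else:
        relevance = np.ones_like(relevance)
    return float(np.mean(relevance * loss))


class FeatureWeightSelector(BaseEstimator):
    """Post-training feature weighting and pruning over a frozen classifier.

    Parameters
    ----------
    iterations : number of fitness-refinement iterations (m_t).
    mix : the accuracy/parsimony mixing coefficient of the fitness score.
    quantile : fraction of features kept by :func:`select_features`.
    t_l, t_u : lower/upper step thresholds of the fitness update.
    theta0 : initial state of the chaotic logistic orbit.

    After ``fit(classifier, X, y)`` the fitted attributes hold per-feature
    weights ``omega_``, refined ``fitness_``, the kept-feature ``mask_`` and
    the masked-accuracy deltas the gradient signs were derived from.
    """

    def __init__(self, iterations=20, mix=0.5, quantile=0.75, t_l=0.0, t_u=1.0, theta0=0.123, bins=8):
        self.iterations = iterations
        self.mix = mix
        self.quantile = quantile
        self.t_l = t_l
        self.t_u = t_u
        self.theta0 = theta0
        self.bins = bins

    def fit(self, classifier, X, y):
        feats = classifier.transform(X)
        y = np.asarray(y)
        n_features = feats.shape[1]
        net = classifier.network_
        self.omega_ = init_feature_weights(net.fc1.params["W"], net.fc2.params["W"])

        base_acc = float(np.mean(classifier.predict(X) == y))
        gains = np.array([information_gain(feats[:, j], y, self.bins) for j in range(n_features)])
        fitness = np.array(
            [feature_fitness(base_acc, gains[j], n_features, self.mix).value for j in range(n_features)]
        )

        # Masked-accuracy delta per feature: fitness gradient estimate.
        # Dropping a useful feature lowers accuracy -> positive delta ->
        # positive gamma -> its fitness grows over the iterations.
        deltas = np.empty(n_features)
        weights = np.ones(n_features)
        for j in range(n_features):
            weights[j] = 0.0
            probs = classifier.predict_proba_weighted(X, weights)
            acc_wo = float(np.mean(classifier.classes_[probs.argmax(axis=1)] == y))
            deltas[j] = base_acc - acc_wo
            weights[j] = 1.0
        gamma = np.where(deltas == 0.0, np.sign(gains - np.median(gains)), np.sign(deltas))

        state = self.theta0
        for m in range(self.iterations):
            eta = eta_coefficient(m, self.iterations)
            theta, state = chaotic_theta(state)
            fitness = update_fitness(fitness, eta, theta, gamma, self.t_l, self.t_u)

        self.fitness_ = fitness
        self.deltas_ = deltas
        self.gains_ = gains
        self.mask_ = select_features(self.omega_, fitness, self.quantile)
        self.base_accuracy_ = base_acc
        return self

    def transform_weights(self) -> np.ndarray:
        """Pruned weight vector: omega masked to the selected features."""
        return self.omega_ * self.mask_

    def report(self) -> dict:
        return {
            "base_accuracy": self.base_accuracy_,
            "features": [
                {
                    "index": int(j),
                    "omega": float(self.omega_[j]),
                    "fitness": float(self.fitness_[j]),
                    "information_gain_bits": float(self.gains_[j]),
                    "masked_accuracy_delta": float(self.deltas_[j]),
                    "kept": bool(self.mask_[j]),
                }
                for j in range(len(self.omega_))
            ],
        }

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)
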