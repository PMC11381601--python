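"""Shapley attributions: axioms, oracles, sampling convergence, overlays."""

from itertools import combinations

import numpy as np
import pytest

from glucospec.shapley import (
    exact_shapley,
    sampled_shapley,
    shap_overlay,
    superpixel_partition,
)


def patch_mean_model(weights, partition, background):
    """f(image) = sum_j w_j * mean(patch_j): linear in patch means."""
    features = np.unique(partition)

    def predict(images):
        out = np.zeros(len(images))
        for i, img in enumerate(images):
            for j, feat in enumerate(features):
                out[i] += weights[j] * img[partition == feat].mean()
        return out

    return predict


class TestPartition:
    def test_single_feature(self):
        p = superpixel_partition(np.zeros((8, 8)), 1)
        assert np.all(p == 0)

    def test_quad_partition_covers_exactly(self):
        p = superpixel_partition(np.zeros((8, 8)), 2)
        assert sorted(np.unique(p)) == [0, 1, 2, 3]
        assert all((p == k).sum() == 16 for k in range(4))

    def test_remainder_absorbed_by_edges(self):
        p = superpixel_partition(np.zeros((5, 5)), 2)
        assert np.bincount(p.ravel()).sum() == 25
        assert len(np.unique(p)) == 4

    def test_areas_sum_to_image(self):
        p = superpixel_partition(np.zeros((13, 7)), 3)
        assert np.bincount(p.ravel(), minlength=9).sum() == 13 * 7

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            superpixel_partition(np.zeros((2, 2)), 5)


class TestExactShapley:
    def test_dummy_axiom(self, rng):
        img = rng.integers(0, 255, size=(6, 6)).astype(float)
        bg = np.zeros((6, 6))
        part = superpixel_partition(img, 2)

        def ignores_patch_zero(images):
            return np.array([im[part != 0].sum() for im in images])

        expl = exact_shapley(ignores_patch_zero, img, bg, part)
        assert expl.phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_model_closed_form(self, rng):
        img = rng.uniform(0, 255, size=(6, 6))
        bg = rng.uniform(0, 255, size=(6, 6))
        part = superpixel_partition(img, 2)
        w = rng.standard_normal(4)
        expl = exact_shapley(patch_mean_model(w, part, bg), img, bg, part)
        for j in range(4):
            expected = w[j] * (img[part == j].mean() - bg[part == j].mean())
            assert expl.phi[j] == pytest.approx(expected, abs=1e-9)

    def test_two_feature_enumeration_oracle(self, rng):
        img = rng.uniform(0, 1, size=(4, 4))
        bg = np.zeros((4, 4))
        part = np.zeros((4, 4), dtype=int)
        part[:, 2:] = 1

        def f(images):  # nonlinear interaction
            a = np.array([im[part == 0].sum() for im in images])
            b = np.array([im[part == 1].sum() for im in images])
            return a + b + 0.5 * a * b

        def val(coal):
            im = bg.copy()
            for j in coal:
                im[part == j] = img[part == j]
            return f(im[None])[0]

        v00, v0, v1, v01 = val(()), val((0,)), val((1,)), val((0, 1))
        phi0 = 0.5 * (v0 - v00) + 0.5 * (v01 - v1)
        phi1 = 0.5 * (v1 - v00) + 0.5 * (v01 - v0)
        expl = exact_shapley(f, img, bg, part)
        assert expl.phi == pytest.approx([phi0, phi1], abs=1e-12)

    def test_local_accuracy_on_random_models(self, rng):
        for trial in range(50):
            g = int(rng.integers(1, 4))  # up to 9 features
            img = rng.uniform(0, 1, size=(6, 6))
            bg = rng.uniform(0, 1, size=(6, 6))
            part = superpixel_partition(img, g)
            w1 = rng.standard_normal(g * g)
            w2 = rng.standard_normal(g * g)

            def f(images):
                means = np.array(
                    [[im[part == k].mean() for k in range(g * g)] for im in images]
                )
                return np.tanh(means @ w1) + (means @ w2) ** 2

            expl = exact_shapley(f, img, bg, part)
            assert abs(expl.baseline + expl.phi.sum() - expl.prediction) <= 1e-9

    def test_symmetry(self, rng):
        img = np.zeros((4, 4))
        img[:2, :2] = 7.0
        img[:2, 2:] = 7.0  # two identical patches
        bg = np.zeros((4, 4))
        part = superpixel_partition(img, 2)

        def symmetric(images):
            return np.array([im[part == 0].sum() + im[part == 1].sum() for im in images])

        expl = exact_shapley(symmetric, img, bg, part)
        assert abs(expl.phi[0] - expl.phi[1]) <= 1e-9

    def test_background_equals_instance_gives_zero(self, rng):
        img = rng.uniform(0, 1, size=(6, 6))
        part = superpixel_partition(img, 2)
        f = patch_mean_model(np.ones(4), part, img)
        expl = exact_shapley(f, img, img, part)
        assert np.max(np.abs(expl.phi)) <= 1e-12

    def test_too_many_features_refused(self):
        img = np.zeros((25, 25))
        part = superpixel_partition(img, 5)
        with pytest.raises(ValueError, match="sampled"):
            exact_shapley(lambda ims: np.zeros(len(ims)), img, img, part)


class TestSampledShapley:
    def test_single_feature_is_exact(self, rng):
        img = rng.uniform(0, 1, size=(4, 4))
        bg = np.zeros((4, 4))
        part = superpixel_partition(img, 1)
        f = patch_mean_model(np.array([2.0]), part, bg)
        expl = sampled_shapley(f, img, bg, part, n_samples=10, seed=0)
        assert expl.phi[0] == pytest.approx(2.0 * img.mean(), abs=1e-12)

    def test_seed_reproducibility(self, rng):
        img = rng.uniform(0, 1, size=(6, 6))
        bg = np.zeros((6, 6))
        part = superpixel_partition(img, 2)
        f = patch_mean_model(rng.standard_normal(4), part, bg)
        a = sampled_shapley(f, img, bg, part, n_samples=60, seed=3)
        b = sampled_shapley(f, img, bg, part, n_samples=60, seed=3)
        assert np.array_equal(a.phi, b.phi)

    def test_converges_to_exact_within_three_se(self, rng):
        img = rng.uniform(0, 1, size=(9, 9))
        bg = rng.uniform(0, 1, size=(9, 9))
        part = superpixel_partition(img, 3)

        def f(images):
            means = np.array([[im[part == k].mean() for k in range(9)] for im in images])
            return means.sum(axis=1) + 0.3 * means[:, 0] * means[:, 1]

        exact = exact_shapley(f, img, bg, part)
        sampled = sampled_shapley(f, img, bg, part, n_samples=1800, seed=1)
        se = np.maximum(sampled.standard_error, 1e-12)
        assert np.all(np.abs(sampled.phi - exact.phi) <= 3 * se + 1e-9)

    def test_sample_budget_enforced(self, rng):
        img = np.zeros((4, 4))
        part = superpixel_partition(img, 2)
        with pytest.raises(ValueError, match="n_samples"):
            sampled_shapley(lambda ims: np.zeros(len(ims)), img, img, part, n_samples=5)


class TestOverlay:
    def _explanation(self, phi, part):
        from glucospec.shapley import Explanation

        return Explanation(
            phi=np.asarray(phi, float), baseline=0.0, prediction=float(np.sum(phi)),
            feature_partition=part,
        )

    def test_zero_attribution_returns_original(self, rng):
        img = rng.integers(0, 255, size=(8, 8, 3)).astype(np.uint8)
        part = superpixel_partition(img, 2)
        out = shap_overlay(img, self._explanation([0, 0, 0, 0], part))
        assert np.array_equal(out, img)

    def test_sign_flip_swaps_palettes(self):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        part = superpixel_partition(img, 2)
        phi = [1.0, -1.0, 0.5, -0.5]
        pos = shap_overlay(img, self._explanation(phi, part))
        neg = shap_overlay(img, self._explanation([-v for v in phi], part))
        # on a constant base image, flipping all signs swaps the patch colors
        assert np.array_equal(pos[part == 0][0], neg[part == 1][0])
        assert np.array_equal(pos[part == 1][0], neg[part == 0][0])
        # pink (red-dominant) for positive phi, blue-dominant for negative
        assert pos[part == 0][:, 0].mean() > pos[part == 1][:, 0].mean()
        assert neg[part == 0][:, 2].mean() > neg[part == 1][:, 2].mean()

    def test_dimensions_preserved(self, rng):
        img = rng.integers(0, 255, size=(10, 12, 3)).astype(np.uint8)
        part = superpixel_partition(img, 2)
        out = shap_overlay(img, self._explanation([1, 2, 3, 4], part))
        assert out.shape == img.shape
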