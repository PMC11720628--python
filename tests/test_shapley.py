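"""Shapley engine: axioms, exact-vs-Monte-Carlo agreement, grouping, consensus."""

import numpy as np
import pytest

from claimscope.profiles import FeatureGroupMap
from claimscope.shapley import (
    BackgroundSet,
    GroupedAttribution,
    consensus_attribution,
    exact_shapley,
    group_attributions,
    monte_carlo_shapley,
)


def linear_fn(w):
    w = np.asarray(w, dtype=float)
    return lambda X: X @ w


class TestExactShapley:
    def test_linear_model_with_zero_background(self):
        f = linear_fn([2.0, 3.0])
        bg = BackgroundSet(np.zeros((1, 2)))
        attr = exact_shapley(f, np.array([1.0, 1.0]), bg)
        np.testing.assert_allclose(attr.phi, [2.0, 3.0], atol=1e-12)
        assert attr.base_value == 0.0

    def test_null_player_gets_zero(self):
        f = lambda X: X[:, 0] * 5.0  # independent of feature 1
        bg = BackgroundSet(np.random.default_rng(0).normal(size=(20, 2)))
        attr = exact_shapley(f, np.array([2.0, 7.0]), bg)
        assert attr.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_axiom(self):
        f = lambda X: X[:, 0] + X[:, 1]
        bg = BackgroundSet(np.array([[0.5, 0.5], [-0.5, -0.5]]))
        attr = exact_shapley(f, np.array([3.0, 3.0]), bg)
        assert attr.phi[0] == pytest.approx(attr.phi[1], abs=1e-12)

    def test_linearity_axiom(self):
        rng = np.random.default_rng(1)
        bg = BackgroundSet(rng.normal(size=(10, 3)))
        x = rng.normal(size=3)
        f = lambda X: np.sin(X[:, 0]) + X[:, 1] ** 2
        g = lambda X: X[:, 2] * X[:, 0]
        a, b = 2.0, -0.7
        combo = lambda X: a * f(X) + b * g(X)
        phi_f = exact_shapley(f, x, bg).phi
        phi_g = exact_shapley(g, x, bg).phi
        phi_c = exact_shapley(combo, x, bg).phi
        np.testing.assert_allclose(phi_c, a * phi_f + b * phi_g, atol=1e-9)

    def test_efficiency_identity(self):
        rng = np.random.default_rng(2)
        bg = BackgroundSet(rng.normal(size=(15, 5)))
        x = rng.normal(size=5)
        f = lambda X: np.exp(-np.abs(X).sum(axis=1) / 5) + X[:, 2]
        attr = exact_shapley(f, x, bg)
        assert attr.phi.sum() + attr.base_value == pytest.approx(
            float(f(x[None])[0]), abs=1e-9
        )

    def test_group_level_equals_column_level_then_summed(self):
        rng = np.random.default_rng(3)
        bg = BackgroundSet(rng.normal(size=(8, 4)))
        x = rng.normal(size=4)
        f = linear_fn([1.0, -2.0, 0.5, 3.0])
        by_col = exact_shapley(f, x, bg)
        gmap = FeatureGroupMap(
            (("a", (0, 1)), ("b", (2, 3))), ("c0", "c1", "c2", "c3")
        )
        summed = group_attributions(by_col, gmap)
        by_group = exact_shapley(f, x, bg, groups=[[0, 1], [2, 3]], unit_names=("a", "b"))
        assert summed.importance["a"] == pytest.approx(by_group.phi[0], abs=1e-9)
        assert summed.importance["b"] == pytest.approx(by_group.phi[1], abs=1e-9)

    def test_too_many_groups_refused(self):
        bg = BackgroundSet(np.zeros((1, 13)))
        with pytest.raises(ValueError, match="monte_carlo"):
            exact_shapley(lambda X: X.sum(axis=1), np.ones(13), bg)


class TestMonteCarloShapley:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        bg = BackgroundSet(rng.normal(size=(10, 3)))
        x = rng.normal(size=3)
        f = lambda X: (X ** 2).sum(axis=1)
        a1 = monte_carlo_shapley(f, x, bg, n_permutations=50, seed=9)
        a2 = monte_carlo_shapley(f, x, bg, n_permutations=50, seed=9)
        np.testing.assert_array_equal(a1.phi, a2.phi)

    def test_linear_model_within_three_se_of_exact(self):
        rng = np.random.default_rng(5)
        bg = BackgroundSet(rng.normal(size=(25, 4)))
        x = rng.normal(size=4) + 1.0
        f = linear_fn([1.5, -0.5, 2.0, 0.1])
        exact = exact_shapley(f, x, bg)
        mc = monte_carlo_shapley(f, x, bg, n_permutations=800, seed=1)
        np.testing.assert_array_less(
            np.abs(mc.phi - exact.phi), 3 * mc.standard_errors + 1e-12
        )

    def test_six_group_nonlinear_within_three_se(self):
        rng = np.random.default_rng(6)
        d, groups = 12, [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9], [10, 11]]
        bg = BackgroundSet(rng.normal(size=(20, d)))
        x = rng.normal(size=d)
        f = lambda X: np.tanh(X[:, :6].sum(axis=1)) + (X[:, 6:] ** 2).sum(axis=1)
        exact = exact_shapley(f, x, bg, groups=groups)
        mc = monte_carlo_shapley(f, x, bg, n_permutations=2000, seed=2, groups=groups)
        np.testing.assert_array_less(np.abs(mc.phi - exact.phi), 3 * mc.standard_errors)

    def test_variance_shrinks_with_permutations(self):
        rng = np.random.default_rng(7)
        bg = BackgroundSet(rng.normal(size=(10, 3)))
        x = rng.normal(size=3)
        f = lambda X: (X ** 3).sum(axis=1)
        se_small = monte_carlo_shapley(f, x, bg, n_permutations=100, seed=3).standard_errors
        se_large = monte_carlo_shapley(f, x, bg, n_permutations=1600, seed=3).standard_errors
        # 16x permutations -> ~4x smaller SE
        assert np.all(se_large < se_small)
        assert se_large.mean() < 0.5 * se_small.mean()


class TestGroupedAttribution:
    def test_embedding_group_sums(self):
        from claimscope.shapley import AttributionVector

        gmap = FeatureGroupMap((("code", (0, 1, 2)),), ("e0", "e1", "e2"))
        attr = AttributionVector("e", "d", np.array([0.2, -0.1, 0.4]), 0.0,
                                 ("e0", "e1", "e2"))
        grouped = group_attributions(attr, gmap)
        assert grouped.importance["code"] == pytest.approx(0.5)

    def test_partition_preserves_total(self):
        from claimscope.shapley import AttributionVector

        rng = np.random.default_rng(8)
        phi = rng.normal(size=6)
        gmap = FeatureGroupMap(
            (("a", (0, 1)), ("b", (2, 3, 4)), ("c", (5,))),
            tuple(f"x{i}" for i in range(6)),
        )
        grouped = group_attributions(
            AttributionVector("e", "d", phi, 0.0, tuple(f"x{i}" for i in range(6))),
            gmap,
        )
        assert sum(grouped.importance.values()) == pytest.approx(phi.sum(), abs=1e-12)

    def test_length_mismatch_is_error(self):
        from claimscope.shapley import AttributionVector

        gmap = FeatureGroupMap((("a", (0, 1)),), ("x0", "x1"))
        attr = AttributionVector("e", "d", np.zeros(5), 0.0, tuple("abcde"))
        with pytest.raises(ValueError):
            group_attributions(attr, gmap)


class TestConsensusAttribution:
    def test_l1_rescale_then_mean(self):
        a = GroupedAttribution("e", "m1", {"f1": 2.0, "f2": 2.0})
        b = GroupedAttribution("e", "m2", {"f1": 1.0, "f2": 3.0})
        cons = consensus_attribution([a, b])
        assert cons.importance["f1"] == pytest.approx(0.375)
        assert cons.importance["f2"] == pytest.approx(0.625)

    def test_single_model_is_its_own_l1_normalization(self):
        a = GroupedAttribution("e", "m", {"f1": -1.0, "f2": 3.0})
        cons = consensus_attribution([a])
        assert cons.importance["f1"] == pytest.approx(-0.25)
        assert cons.importance["f2"] == pytest.approx(0.75)

    def test_all_zero_model_contributes_zeros(self):
        a = GroupedAttribution("e", "m1", {"f1": 1.0, "f2": 1.0})
        z = GroupedAttribution("e", "m2", {"f1": 0.0, "f2": 0.0})
        cons = consensus_attribution([a, z])
        assert cons.importance["f1"] == pytest.approx(0.25)
        assert cons.importance["f2"] == pytest.approx(0.25)

    def test_mismatched_features_rejected(self):
        a = GroupedAttribution("e", "m1", {"f1": 1.0})
        b = GroupedAttribution("e", "m2", {"f2": 1.0})
        with pytest.raises(ValueError):
            consensus_attribution([a, b])
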