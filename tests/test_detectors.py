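"""Native detectors against brute-force oracles; ensemble contract; AUROC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from claimscope.detectors import (
    DetectorSpec,
    ECDFTailDetector,
    HistogramDetector,
    KNNDetector,
    evaluate_auroc,
    run_ensemble,
)
from claimscope.profiles import FeatureGroupMap, ProfileMatrix


def profile_from_array(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > 1 and X.shape[1] == 1 or X.ndim == 1:
        X = X.reshape(-1, X.shape[-1] if X.ndim == 2 else 1)
    d = X.shape[1]
    gmap = FeatureGroupMap(
        tuple((f"f{j}", (j,)) for j in range(d)), tuple(f"f{j}" for j in range(d))
    )
    return ProfileMatrix([f"e{i}" for i in range(X.shape[0])], X, gmap)


def brute_force_knn(X, k):
    """O(n^2) oracle: mean distance to the k nearest other rows."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    out = np.empty(n)
    for i in range(n):
        others = np.delete(D[i], i)
        out[i] = np.sort(others)[:k].mean()
    return out


class TestKNN:
    def test_three_points_k1(self):
        prof = profile_from_array([[0.0], [1.0], [10.0]])
        scores = KNNDetector(k=1).fit(prof.values).score_training()
        np.testing.assert_allclose(scores, [1, 1, 9])
        assert np.argmax(scores) == 2

    def test_three_points_k2(self):
        prof = profile_from_array([[0.0], [1.0], [10.0]])
        scores = KNNDetector(k=2).fit(prof.values).score_training()
        np.testing.assert_allclose(scores, [5.5, 5, 9.5])

    def test_duplicate_rows_zero_contribution(self):
        prof = profile_from_array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        scores = KNNDetector(k=1).fit(prof.values).score_training()
        np.testing.assert_allclose(scores[:2], [0, 0], atol=1e-12)

    @pytest.mark.parametrize("n,d,k", [(50, 3, 5), (200, 8, 20), (120, 2, 1)])
    def test_matches_brute_force_oracle(self, n, d, k):
        rng = np.random.default_rng(n + k)
        X = rng.normal(size=(n, d))
        scores = KNNDetector(k=k).fit(X).score_training()
        np.testing.assert_allclose(scores, brute_force_knn(X, k), atol=1e-9)

    def test_k_too_large_is_an_error(self):
        with pytest.raises(ValueError):
            KNNDetector(k=3).fit(np.zeros((3, 2)))


class TestHistogram:
    def test_two_bin_example(self):
        # 10 points, bins (9, 1): lone point in the sparse bin ranks first
        x = np.array([[v] for v in [0.1, 0.2, 0.3, 0.15, 0.25, 0.35, 0.12, 0.22, 0.32, 0.9]])
        det = HistogramDetector(n_bins=2).fit(x)
        scores = det.score_training()
        eps = 1e-12
        np.testing.assert_allclose(scores[0], -np.log(0.9 + eps), atol=1e-9)
        np.testing.assert_allclose(scores[-1], -np.log(0.1 + eps), atol=1e-9)
        assert np.argmax(scores) == 9

    def test_all_points_in_one_bin_score_equally(self):
        x = np.full((8, 1), 3.0) + np.linspace(0, 1e-9, 8)[:, None]
        scores = HistogramDetector(n_bins=4).fit(x).score_training()
        assert np.allclose(scores, scores[0])

    def test_constant_column_changes_no_ranking(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        s1 = HistogramDetector(n_bins=5).fit(X).score_training()
        X_aug = np.hstack([X, np.full((30, 1), 2.0)])
        s2 = HistogramDetector(n_bins=5).fit(X_aug).score_training()
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestECDFTail:
    def test_hand_enumerated_tails(self):
        prof = profile_from_array([[1.0], [2.0], [100.0]])
        scores = ECDFTailDetector().fit(prof.values).score_training()
        np.testing.assert_allclose(
            scores, [-np.log(1 / 3), -np.log(2 / 3), -np.log(1 / 3)], atol=1e-9
        )
        np.testing.assert_allclose(scores, [1.0986, 0.4055, 1.0986], atol=1e-4)

    def test_degenerate_dimension_contributes_zero(self):
        X = np.hstack([np.full((5, 1), 2.0), np.arange(5.0)[:, None]])
        with_const = ECDFTailDetector().fit(X).score_training()
        without = ECDFTailDetector().fit(X[:, 1:]).score_training()
        np.testing.assert_allclose(with_const, without, atol=1e-12)

    def test_monotone_data_extremes_tie(self):
        n = 7
        X = np.arange(float(n))[:, None]
        scores = ECDFTailDetector().fit(X).score_training()
        assert scores[0] == pytest.approx(scores[-1], abs=1e-12)
        assert scores[0] == pytest.approx(-np.log(1 / n), abs=1e-12)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        perm = rng.permutation(40)
        s = ECDFTailDetector().fit(X).score_training()
        sp = ECDFTailDetector().fit(X[perm]).score_training()
        np.testing.assert_allclose(s[perm], sp, atol=1e-12)


class TestEnsemble:
    def test_shape_and_column_order(self, small_benchmark):
        from claimscope.workflow import ClaimsAnomalyModel, RunConfig

        cfg = RunConfig(schema=small_benchmark.table.schema, min_actions=0)
        res = ClaimsAnomalyModel(small_benchmark.table, cfg).fit()
        assert res.scores.detector_names == ["knn", "hist", "ecdf"]
        assert res.scores.scores.shape == (len(res.profiles.entity_ids), 3)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        prof = profile_from_array(rng.normal(size=(50, 4)))
        specs = [DetectorSpec("knn", hyperparameters={"k": 5}),
                 DetectorSpec("ecdf"), DetectorSpec("iforest", seed=3)]
        s1, _ = run_ensemble(prof, specs)
        s2, _ = run_ensemble(prof, specs)
        np.testing.assert_array_equal(s1.scores, s2.scores)

    def test_failing_adapter_is_dropped_not_fatal(self):
        prof = profile_from_array(np.random.default_rng(0).normal(size=(30, 2)))
        specs = [DetectorSpec("knn", hyperparameters={"k": 500}),  # k >= n fails
                 DetectorSpec("ecdf")]
        scores, _ = run_ensemble(prof, specs)
        assert scores.detector_names == ["ecdf"]

    def test_sklearn_adapters_run(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(40, 3)), rng.normal(6.0, 1.0, size=(2, 3))])
        prof = profile_from_array(X)
        specs = [DetectorSpec("lof"), DetectorSpec("iforest", seed=0),
                 DetectorSpec("ocsvm")]
        scores, _ = run_ensemble(prof, specs)
        # the two shifted rows should outrank the bulk under every adapter
        for name in scores.detector_names:
            col = scores.column(name)
            assert set(np.argsort(col)[-2:]) == {40, 41}


def brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([3, 2, 1], [1, 0, 0], 1.0),
            ([1, 2, 3], [1, 0, 0], 0.0),
            ([1, 1, 1, 1], [1, 0, 1, 0], 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert evaluate_auroc(np.array(scores), np.array(labels)) == expected

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_auroc(np.array([1.0, 2.0]), np.array([1, 1]))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=50),
        st.randoms(use_true_random=False),
    )
    def test_matches_exhaustive_pairwise_oracle(self, score_vals, rnd):
        scores = np.array(score_vals, dtype=float)
        labels = np.array([rnd.randint(0, 1) for _ in score_vals])
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        expected = brute_force_auroc(scores, labels)
        assert evaluate_auroc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.3).astype(int)
        assert evaluate_auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )
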