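import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scgnn import (
    ExpressionMatrix,
    adjusted_rand_index,
    baseline_imputations,
    cosine_sim,
    masked_metrics,
    median_l1,
    rmse,
    silhouette_mean,
    synthetic_dropout,
)
from .conftest import two_blob_embedding


def _expr(values):
    n, m = values.shape
    return ExpressionMatrix(values, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(m)],
                            "preprocessed")


class TestSyntheticDropout:
    def test_count_and_locality(self, small_matrix):
        corrupted, mask = synthetic_dropout(small_matrix, 0.2, seed=0)
        nnz = np.count_nonzero(small_matrix.values)
        assert mask.n_masked == round(0.2 * nnz)
        assert np.all(mask.original_values > 0)
        diff = corrupted.values != small_matrix.values
        assert diff.sum() == mask.n_masked
        assert np.all(corrupted.values[mask.entries[:, 0], mask.entries[:, 1]] == 0)

    def test_invalid_rate(self, small_matrix):
        for rate in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                synthetic_dropout(small_matrix, rate)

    def test_rate_rounding_to_zero_rejected(self):
        x = _expr(np.array([[1.0, 0.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="zero masked"):
            synthetic_dropout(x, 0.01)

    def test_seeded_reproducibility(self, small_matrix):
        c1, m1 = synthetic_dropout(small_matrix, 0.2, seed=9)
        c2, m2 = synthetic_dropout(small_matrix, 0.2, seed=9)
        np.testing.assert_array_equal(c1.values, c2.values)
        np.testing.assert_array_equal(m1.entries, m2.entries)


class TestScalarMetrics:
    def test_median_l1_examples(self):
        assert median_l1([1, 2, 3], [1, 2, 3]) == 0.0
        assert median_l1([1, 2, 3], [2, 4, 6]) == 2.0  # deviations {1,2,3}

    def test_median_l1_matches_sort_and_pick(self, rng):
        x, y = rng.random(101), rng.random(101)
        assert median_l1(x, y) == pytest.approx(np.sort(np.abs(x - y))[50], abs=1e-15)

    def test_cosine_examples(self, rng):
        x = rng.random(10) + 0.1
        assert cosine_sim(x, 2 * x) == pytest.approx(1.0)
        assert cosine_sim([1, 0], [0, 1]) == 0.0
        assert cosine_sim([0, 0], [1, 1]) == 0.0  # zero-norm convention
        y = rng.random(10)
        assert cosine_sim(x, y) == pytest.approx(
            float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y))), abs=1e-12
        )

    def test_rmse_examples(self, rng):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([3, 0], [0, 4]) == pytest.approx(np.sqrt(25 / 2), abs=1e-12)
        x, y = rng.random(20), rng.random(20)
        assert rmse(x, y) == pytest.approx(np.sqrt(np.mean((x - y) ** 2)), abs=1e-12)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_pair_translation_invariance(self, xs, c):
        x = np.array(xs)
        y = x[::-1].copy()
        assert median_l1(x + c, y + c) == pytest.approx(median_l1(x, y), abs=1e-8)
        assert rmse(x + c, y + c) == pytest.approx(rmse(x, y), abs=1e-8)


def _pair_counting_ari(a, b):
    """Brute-force ARI via exhaustive pair enumeration (RI, E[RI], max RI)."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    same_a = np.array([a[i] == a[j] for i, j in pairs])
    same_b = np.array([b[i] == b[j] for i, j in pairs])
    s11 = int((same_a & same_b).sum())      # together in both
    total = len(pairs)
    # RI = (a + b)/C(n,2) with the permutation-model expectation; algebra
    # reduces (RI - E[RI])/(max RI - E[RI]) to the form below
    pa, pb = same_a.sum() / total, same_b.sum() / total
    denom = 0.5 * (pa + pb) - pa * pb
    if denom == 0:
        return 1.0  # both partitions trivial (all-singleton or single-block)
    return (s11 / total - pa * pb) / denom


class TestAri:
    def test_identity_and_relabeling(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0

    def test_crossed_example_matches_pair_counting(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        assert adjusted_rand_index(a, b) == pytest.approx(_pair_counting_ari(a, b), abs=1e-12)

    def test_single_cluster_limit(self):
        assert adjusted_rand_index([0, 0, 0], [1, 1, 1]) == 1.0

    def test_exhaustive_small_partitions(self):
        """Closed form equals pair counting for every partition pair, n=4."""
        def partitions(n):
            if n == 0:
                yield []
                return
            for rest in partitions(n - 1):
                m = max(rest, default=-1)
                for lab in range(m + 2):
                    yield rest + [lab]

        parts = list(partitions(4))
        for a in parts:
            for b in parts:
                assert adjusted_rand_index(a, b) == pytest.approx(
                    _pair_counting_ari(a, b), abs=1e-10
                )


class TestSilhouette:
    def test_tight_blobs_high_score(self):
        pts, labels = two_blob_embedding(15, dim=2, gap=40.0, seed=0)
        assert silhouette_mean(pts, labels) > 0.9

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        scores = []
        for s in range(5):
            pts = np.random.default_rng(s).normal(size=(60, 3))
            labels = np.random.default_rng(100 + s).integers(0, 2, 60)
            scores.append(silhouette_mean(pts, labels))
        assert abs(np.mean(scores)) < 0.1

    def test_matches_direct_formula_small_case(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        got = silhouette_mean(pts, labels)
        # per point: a = dist to own clustermate, b = mean dist to other cluster
        expected = np.mean([
            (np.mean([10, 11]) - 1) / np.mean([10, 11]),
            (np.mean([9, 10]) - 1) / np.mean([9, 10]),
            (np.mean([10, 9]) - 1) / np.mean([10, 9]),
            (np.mean([11, 10]) - 1) / np.mean([11, 10]),
        ])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_range_and_errors(self, rng):
        pts = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, 30)
        if len(np.unique(labels)) >= 2:
            assert -1.0 <= silhouette_mean(pts, labels) <= 1.0
        with pytest.raises(ValueError):
            silhouette_mean(pts, np.zeros(30, dtype=int))


class TestMaskedMetrics:
    def test_identity_triple(self, small_matrix):
        corrupted, mask = synthetic_dropout(small_matrix, 0.3, seed=2)
        for mode in ("rowwise", "pooled"):
            m = masked_metrics(small_matrix, small_matrix, mask, mode=mode)
            assert m["median_l1"] == 0.0
            assert m["cosine"] == pytest.approx(1.0)
            assert m["rmse"] == 0.0

    def test_pooled_matches_scalar_ops(self, small_matrix, rng):
        corrupted, mask = synthetic_dropout(small_matrix, 0.3, seed=3)
        imputed = small_matrix.with_values(
            np.abs(small_matrix.values + rng.normal(0, 0.1, small_matrix.values.shape))
        )
        m = masked_metrics(small_matrix, imputed, mask, mode="pooled")
        imp_vals = imputed.values[mask.entries[:, 0], mask.entries[:, 1]]
        assert m["median_l1"] == median_l1(mask.original_values, imp_vals)
        assert m["cosine"] == cosine_sim(mask.original_values, imp_vals)
        assert m["rmse"] == rmse(mask.original_values, imp_vals)

    def test_baselines(self, small_matrix):
        corrupted, mask = synthetic_dropout(small_matrix, 0.3, seed=4)
        bases = baseline_imputations(corrupted)
        np.testing.assert_array_equal(bases["zeros"].values, corrupted.values)
        gm = bases["gene_mean"].values
        assert np.all(gm[corrupted.values == 0] >= 0)
        zero_pos = corrupted.values == 0
        col_means = corrupted.values.mean(axis=0)
        expect = np.broadcast_to(col_means, gm.shape)[zero_pos]
        np.testing.assert_allclose(gm[zero_pos], expect, atol=1e-12)
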