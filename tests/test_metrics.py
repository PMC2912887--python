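"""Metric unit tests, with independent brute-force oracles for the external
clustering measures and the cophenetic coefficient."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmfkit import (
    DomainError,
    NMFModel,
    connectivity,
    cophenetic_coefficient,
    entropy,
    evar,
    model_sparseness,
    objective,
    purity,
    quality_report,
    reports_table,
    rss,
    sparseness,
)
from nmfkit import fit, make_synthetic


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------


def oracle_purity(clusters, labels):
    total = 0
    for k in set(clusters):
        members = [l for c, l in zip(clusters, labels) if c == k]
        counts = {l: members.count(l) for l in set(members)}
        total += max(counts.values())
    return total / len(clusters)


def oracle_entropy(clusters, labels):
    import math

    p = len(clusters)
    q = len(set(labels))
    acc = 0.0
    for k in set(clusters):
        members = [l for c, l in zip(clusters, labels) if c == k]
        nk = len(members)
        for l in set(members):
            nkl = members.count(l)
            acc += nkl * math.log2(nkl / nk)
    return -acc / (p * math.log2(q))


def oracle_cophenetic(D):
    """Average-linkage agglomeration by explicit cluster merging, then the
    Pearson correlation of the induced cophenetic distances with D."""
    p = D.shape[0]
    clusters = {i: [i] for i in range(p)}
    coph = np.zeros((p, p))
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ka, kb = keys[a], keys[b]
                d = np.mean([D[i, j] for i in clusters[ka] for j in clusters[kb]])
                if best is None or d < best[0]:
                    best = (d, ka, kb)
        d, ka, kb = best
        for i in clusters[ka]:
            for j in clusters[kb]:
                coph[i, j] = coph[j, i] = d
        clusters[ka] = clusters[ka] + clusters[kb]
        del clusters[kb]
    iu = np.triu_indices(p, 1)
    return float(np.corrcoef(D[iu], coph[iu])[0, 1])


# ---------------------------------------------------------------------------
# Reconstruction measures
# ---------------------------------------------------------------------------


class TestRSSEvar:
    def test_hand_example(self):
        X = np.array([[2.0], [0.0]])
        m = NMFModel(np.array([[1.0], [1.0]]), np.array([[1.0]]))
        assert rss(X, m) == pytest.approx(2.0)
        assert evar(X, m) == pytest.approx(0.5)

    def test_rss_is_twice_the_halved_objective(self, rng):
        X = rng.random((6, 4))
        m = NMFModel(rng.random((6, 2)), rng.random((2, 4)))
        assert rss(X, m) == pytest.approx(2 * objective(m, X, "euclidean"))

    def test_perfect_and_zero_models(self, rng):
        W, H = rng.random((5, 2)) + 0.1, rng.random((2, 4)) + 0.1
        X = W @ H
        assert evar(X, NMFModel(W, H)) == pytest.approx(1.0)
        zero = NMFModel(np.zeros((5, 2)), np.zeros((2, 4)))
        assert evar(X, zero) == pytest.approx(0.0)

    def test_evar_rss_identity(self, rng):
        X = rng.random((5, 5)) + 0.01
        m = NMFModel(rng.random((5, 2)), rng.random((2, 5)))
        assert evar(X, m) + rss(X, m) / np.sum(X**2) == pytest.approx(1.0)

    def test_all_zero_target_rejected(self):
        m = NMFModel(np.zeros((2, 1)), np.zeros((1, 2)))
        with pytest.raises(DomainError):
            evar(np.zeros((2, 2)), m)


class TestSparseness:
    def test_extremes_and_hand_example(self):
        assert sparseness([0.0, 3.0, 0.0]) == pytest.approx(1.0)
        assert sparseness([2.0, 2.0, 2.0]) == pytest.approx(0.0)
        assert sparseness([1.0, 1.0, 0.0, 0.0]) == pytest.approx(2 - np.sqrt(2))

    def test_errors(self):
        with pytest.raises(DomainError):
            sparseness([0.0, 0.0])
        with pytest.raises(DomainError):
            sparseness([1.0])

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=20))
    def test_bounded_in_unit_interval(self, xs):
        assert -1e-12 <= sparseness(xs) <= 1 + 1e-12

    def test_model_sparseness_aggregates(self):
        W = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        m = NMFModel(W, np.ones((2, 3)))
        sw, sh = model_sparseness(m)
        assert sw == pytest.approx(np.mean([2 - np.sqrt(2), 1.0]))
        assert sh == pytest.approx(0.0)


class TestPurityEntropy:
    def test_hand_examples(self):
        clusters = [1, 1, 1, 2, 2]
        labels = ["x", "x", "y", "y", "y"]
        assert purity(clusters, labels) == pytest.approx(0.8)
        expected = -(2 * np.log2(2 / 3) + np.log2(1 / 3)) / 5
        assert entropy(clusters, labels) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.551, abs=5e-4)

    def test_perfect_clustering(self):
        assert purity([1, 2, 3], ["a", "b", "c"]) == 1.0
        assert entropy([1, 1, 2, 2], ["a", "a", "b", "b"]) == 0.0

    def test_maximal_mixing(self):
        assert entropy([1, 1, 2, 2], ["a", "b", "a", "b"]) == pytest.approx(1.0)

    def test_single_cluster_majority_share(self):
        assert purity([1] * 5, ["a", "a", "a", "b", "b"]) == pytest.approx(0.6)

    def test_single_class_entropy_undefined(self):
        with pytest.raises(DomainError):
            entropy([1, 2], ["a", "a"])

    @given(st.integers(0, 10_000))
    def test_agree_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 30))
        clusters = rng.integers(1, 5, p).tolist()
        labels = rng.choice(["a", "b", "c"], p).tolist()
        assert purity(clusters, labels) == pytest.approx(oracle_purity(clusters, labels))
        if len(set(labels)) >= 2:
            assert entropy(clusters, labels) == pytest.approx(
                oracle_entropy(clusters, labels)
            )


class TestConnectivityConsensus:
    def test_basic_patterns(self):
        np.testing.assert_array_equal(
            connectivity([1, 1, 2]), [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )
        np.testing.assert_array_equal(connectivity([1, 1, 1]), np.ones((3, 3)))
        np.testing.assert_array_equal(connectivity([1, 2, 3]), np.eye(3))

    def test_cophenetic_of_block_consensus_is_one(self):
        C = connectivity([1, 1, 1, 2, 2])
        assert cophenetic_coefficient(C) == pytest.approx(1.0)
        C3 = connectivity([1, 1, 2, 2, 3, 3])
        assert cophenetic_coefficient(C3) == pytest.approx(1.0)

    def test_example_matches_bruteforce_oracle(self):
        C = np.array([[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]])
        expected = oracle_cophenetic(1 - C)
        assert cophenetic_coefficient(C) == pytest.approx(expected)

    @given(st.integers(0, 10_000))
    def test_agrees_with_bruteforce_on_random_consensus(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 10))
        # random consensus from a few random partitions; tiny symmetric
        # jitter removes distance ties, whose merge order is tool-specific
        mats = [connectivity(rng.integers(1, 4, p)) for _ in range(5)]
        C = np.mean(mats, axis=0)
        jitter = rng.random((p, p)) * 1e-9
        C = C - (jitter + jitter.T) / 2
        D = 1 - C
        np.fill_diagonal(D, 0)
        iu = np.triu_indices(p, 1)
        if np.allclose(D[iu], D[iu][0]):
            with pytest.raises(DomainError):
                cophenetic_coefficient(C)
        else:
            assert cophenetic_coefficient(C) == pytest.approx(
                oracle_cophenetic(D), abs=1e-9
            )

    def test_constant_offdiagonal_raises(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        with pytest.raises(DomainError, match="not available"):
            cophenetic_coefficient(C)


class TestQualityReport:
    def test_table_columns_and_ranges(self, small_data):
        res = fit(small_data.X, 3, method="brunet", rng_seed=0)
        rep = quality_report(small_data.X, res, cpu_time_s=0.1)
        assert 0 <= rep.evar <= 1
        assert 0 <= rep.sparseness_W <= 1 and 0 <= rep.sparseness_H <= 1
        assert 0 < rep.purity <= 1 and 0 <= rep.entropy <= 1
        table = reports_table([rep])
        assert list(table.columns)[:4] == ["method", "seed", "metric", "rank"]

    def test_purity_entropy_absent_without_labels(self, small_data):
        X = make_synthetic(n=30, p=10, r=2, group_sizes=[5, 5], rng_seed=0).X
        X.class_labels = None
        res = fit(X, 2, method="lee", rng_seed=0)
        table = reports_table([quality_report(X, res)])
        assert "purity" not in table.columns and "entropy" not in table.columns
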