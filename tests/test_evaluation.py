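"""Clustering metrics against brute-force oracles; Louvain scan; AUC."""

import itertools
import math

import numpy as np
import pytest

from scpoe.evaluation import (
    DEFAULT_RESOLUTIONS,
    adjusted_mutual_information,
    adjusted_rand_index,
    clustering_purity,
    louvain_scan,
    population_auc,
    silhouette,
)


# ---------------------------------------------------------------------------
# independent brute-force implementations (contingency-table definitions)


def brute_mi(u, v):
    n = len(u)
    mi = 0.0
    for a in set(u):
        for b in set(v):
            nij = sum(1 for x, y in zip(u, v) if x == a and y == b)
            if nij == 0:
                continue
            ni = sum(1 for x in u if x == a)
            nj = sum(1 for y in v if y == b)
            mi += (nij / n) * math.log(n * nij / (ni * nj))
    return mi


def brute_entropy(u):
    n = len(u)
    return -sum((c / n) * math.log(c / n)
                for c in (sum(1 for x in u if x == a) for a in set(u)) if c > 0)


def brute_emi(u, v):
    """Expected MI under the permutation (hypergeometric) model."""
    n = len(u)
    a = [sum(1 for x in u if x == i) for i in sorted(set(u))]
    b = [sum(1 for y in v if y == j) for j in sorted(set(v))]
    emi = 0.0
    lg = math.lgamma
    for ai in a:
        for bj in b:
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for nij in range(lo, hi + 1):
                term1 = (nij / n) * math.log(n * nij / (ai * bj))
                term2 = math.exp(
                    lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                    - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                    - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1))
                emi += term1 * term2
    return emi


def brute_ami(u, v):
    mi = brute_mi(u, v)
    emi = brute_emi(u, v)
    h = (brute_entropy(u) + brute_entropy(v)) / 2
    denom = h - emi
    if abs(denom) < 1e-15:
        return 1.0
    return (mi - emi) / denom


def brute_ari(u, v):
    n = len(u)
    pairs = list(itertools.combinations(range(n), 2))
    a = sum(1 for i, j in pairs if u[i] == u[j] and v[i] == v[j])
    b = sum(1 for i, j in pairs if u[i] != u[j] and v[i] != v[j])
    c = sum(1 for i, j in pairs if u[i] == u[j] and v[i] != v[j])
    d = sum(1 for i, j in pairs if u[i] != u[j] and v[i] == v[j])
    ri = (a + b) / len(pairs)
    sum_ai = sum(math.comb(sum(1 for x in u if x == k), 2) for k in set(u))
    sum_bj = sum(math.comb(sum(1 for y in v if y == k), 2) for k in set(v))
    expected = sum_ai * sum_bj / len(pairs)
    maximum = (sum_ai + sum_bj) / 2
    if maximum == expected:
        return 1.0
    return (a - expected) / (maximum - expected)


def brute_purity(ref, clu):
    total = 0
    for c in set(clu):
        members = [r for r, k in zip(ref, clu) if k == c]
        total += max(members.count(x) for x in set(members))
    return total / len(ref)


# ---------------------------------------------------------------------------


class TestAgainstBruteForce:
    def test_random_label_pairs_match_to_1e10(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 50)
            u = rng.integers(0, rng.integers(2, 5), n).tolist()
            v = rng.integers(0, rng.integers(2, 5), n).tolist()
            assert abs(adjusted_mutual_information(u, v) - brute_ami(u, v)) < 1e-10
            assert abs(adjusted_rand_index(u, v) - brute_ari(u, v)) < 1e-10
            assert abs(clustering_purity(u, v) - brute_purity(u, v)) < 1e-10

    def test_perfect_iff_identical_up_to_renaming(self):
        """Over all partitions of 5 elements: ARI=AMI=1 exactly when the two
        partitions coincide up to label renaming."""

        def partitions(n):
            out = []
            labels = [0] * n
            def rec(i, m):
                if i == n:
                    out.append(tuple(labels))
                    return
                for lab in range(m + 1):
                    labels[i] = lab
                    rec(i + 1, max(m, lab + 1))
            rec(0, 0)
            return out

        parts = partitions(5)
        for u in parts:
            for v in parts:
                same = u == v  # canonical form makes renaming-equality literal
                ari = adjusted_rand_index(list(u), list(v))
                if same:
                    assert ari == pytest.approx(1.0)
                elif len(set(u)) > 1 or len(set(v)) > 1:
                    assert ari < 1.0 - 1e-12


class TestWorkedExamples:
    def test_identical_labellings_score_one(self):
        u = [0, 0, 1, 1, 2]
        assert adjusted_mutual_information(u, u) == pytest.approx(1.0)
        assert adjusted_rand_index(u, [1, 1, 0, 0, 2]) == pytest.approx(1.0)

    def test_single_cluster_prediction_scores_zero(self):
        u = [0, 0, 1, 1]
        assert adjusted_mutual_information(u, [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_crossed_partition(self):
        u, v = [0, 0, 1, 1], [0, 1, 0, 1]
        assert adjusted_rand_index(u, v) == pytest.approx(-0.5)
        assert adjusted_mutual_information(u, v) <= 1e-9

    def test_purity_worked_cases(self):
        ref = ["A", "A", "B", "B", "B"]
        clusters = [0, 0, 0, 1, 1]  # {A,A,B} and {B,B}
        assert clustering_purity(ref, clusters) == pytest.approx(0.8)
        ref2 = ["A"] * 6 + ["B"] * 4
        assert clustering_purity(ref2, [0] * 10) == pytest.approx(0.6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestLouvainScan:
    def test_recovers_two_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, (40, 2)), rng.normal(5, 0.2, (40, 2))])
        ref = np.repeat([0, 1], 40)
        res = louvain_scan(X, ref, seed=0)
        assert res.n_clusters == 2
        assert res.metrics["ami"] == pytest.approx(1.0)

    def test_default_grid_has_twenty_resolutions(self):
        assert len(DEFAULT_RESOLUTIONS) == 20
        assert DEFAULT_RESOLUTIONS[0] == pytest.approx(0.1)
        assert DEFAULT_RESOLUTIONS[-1] == pytest.approx(2.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 3))
        ref = rng.integers(0, 3, 60)
        r1 = louvain_scan(X, ref, seed=4)
        r2 = louvain_scan(X, ref, seed=4)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.resolution == r2.resolution

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError):
            louvain_scan(np.zeros((5, 2)), [0, 1])


class TestSilhouette:
    def test_hand_computed_1d_case(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = [0, 0, 1, 1]
        mean, scores = silhouette(X, labels)
        # cell 0: a=1, b=(10+11)/2=10.5 -> (10.5-1)/10.5
        assert scores[0] == pytest.approx((10.5 - 1) / 10.5)
        assert np.all(scores >= 0.88)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_duplicating_points_preserves_mean(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.5, (20, 3)), rng.normal(4, 0.5, (20, 3))])
        labels = np.repeat([0, 1], 20)
        m1, _ = silhouette(X, labels)
        m2, _ = silhouette(np.vstack([X, X]), np.concatenate([labels, labels]))
        assert m1 == pytest.approx(m2, abs=0.02)

    def test_stratified_scores_within_groups(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(8, 1, (40, 2))])
        batch = np.tile([0, 1], 40)
        stratum = np.repeat([0, 1], 40)
        grand, per = silhouette(X, batch, within=stratum)
        assert set(per) == {"0", "1"}
        assert grand == pytest.approx(np.mean(list(per.values())))

    def test_degenerate_stratum_skipped_with_warning(self):
        X = np.arange(12.0).reshape(6, 2)
        labels = [0, 0, 1, 1, 0, 0]
        stratum = [0, 0, 0, 0, 1, 1]  # stratum 1 has a single label level
        with pytest.warns(UserWarning, match="skipped"):
            _, per = silhouette(X, labels, within=stratum)
        assert "1" not in per
        assert "0" in per


class TestPopulationAUC:
    def test_separable_blobs_score_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(6, 0.3, (30, 2))])
        y = np.repeat(["a", "b"], 30)
        per_class, mean_auc = population_auc(X, y, folds=5)
        assert mean_auc == pytest.approx(1.0)
        assert per_class["a"] == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        aucs = []
        for rep in range(10):
            X = rng.normal(0, 1, (120, 4))
            y = rng.integers(0, 2, 120)
            _, m = population_auc(X, y, folds=5, seed=rep)
            aucs.append(m)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < max(3 * se, 0.05)

    def test_small_class_rejected_by_name(self):
        X = np.random.default_rng(0).normal(0, 1, (12, 2))
        y = ["big"] * 10 + ["tiny"] * 2
        with pytest.raises(ValueError, match="tiny"):
            population_auc(X, y, folds=5)
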