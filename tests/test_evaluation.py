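"""Similarity profiles, alignment error, clustering metrics, AUPR, t-test."""

import numpy as np
import pytest
import scipy.sparse as sp

from unpairreg.evaluation import (
    alignment_error,
    aupr_distance_bins,
    clustering_agreement,
    graph_connectivity,
    paired_difference_test,
    profile_similarity,
    silhouette_index,
)
from unpairreg.preprocessing import Embedding
from unpairreg.types import CisRegCoefficients, DistancePairs


class TestProfileSimilarity:
    def test_identity_profiles(self, rng):
        X = rng.random((4, 6))
        assert profile_similarity(X, X, "cell", "pcc").mean == pytest.approx(1.0)
        assert profile_similarity(X, X, "cell", "cosine").mean == pytest.approx(1.0)
        assert profile_similarity(X, X, "gene", "rmse").mean == pytest.approx(0.0)
        assert profile_similarity(X, X, "cell", "spearman").mean == pytest.approx(1.0)

    def test_negated_profiles_give_minus_one(self, rng):
        X = rng.random((3, 5))
        assert profile_similarity(X, -X, "cell", "pcc").mean == pytest.approx(-1.0)

    def test_hand_computed_three_by_three(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 0.0, 1.0], [2.0, 2.0, 2.0]])
        Y = np.array([[3.0, 2.0, 1.0], [0.0, 1.0, 0.0], [1.0, 2.0, 3.0]])
        rep = profile_similarity(X, Y, "cell", "pcc")
        # row 0: perfectly anti-ordered -> -1; row 1: anti-pattern -> -1;
        # row 2 constant in X -> undefined
        assert rep.values[0] == pytest.approx(-1.0)
        assert rep.values[1] == pytest.approx(-1.0)
        assert np.isnan(rep.values[2])
        assert rep.mean == pytest.approx(-1.0)

    def test_gene_axis_transposes(self, rng):
        X, Y = rng.random((4, 3)), rng.random((4, 3))
        by_gene = profile_similarity(X, Y, "gene", "pcc").values
        by_cell_of_T = profile_similarity(X.T, Y.T, "cell", "pcc").values
        np.testing.assert_allclose(by_gene, by_cell_of_T)

    def test_rmse_matches_formula(self):
        X = np.array([[0.0, 0.0]])
        Y = np.array([[3.0, 4.0]])
        assert profile_similarity(X, Y, "cell", "rmse").values[0] == pytest.approx(
            np.sqrt(12.5)
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            profile_similarity(rng.random((2, 3)), rng.random((3, 2)))


class TestAlignmentError:
    def test_perfect_match_gives_zero(self, rng):
        X = rng.random((6, 4))
        np.testing.assert_array_equal(alignment_error(X, X), np.zeros(6, int))

    def test_matches_brute_force_enumeration(self, rng):
        for n in (3, 7, 12, 20):
            X = rng.random((n, 5))
            Y = rng.random((n, 5))
            got = alignment_error(X, Y)
            expected = np.zeros(n, int)
            for k in range(n):
                dkk = np.linalg.norm(X[k] - Y[k])
                expected[k] = sum(
                    np.linalg.norm(X[k] - Y[i]) < dkk for i in range(n)
                ) + sum(np.linalg.norm(X[i] - Y[k]) < dkk for i in range(n))
            np.testing.assert_array_equal(got, expected)

    def test_maximally_misplaced_cell_attains_bound(self):
        n = 5
        Y = np.zeros((n, 2))
        Y[:, 0] = np.arange(n)
        X = Y.copy()
        X[0] = [100.0, 100.0]  # far from everything, farthest from its match? no:
        # place its true match farther than every other cell
        Y[0] = [-100.0, -100.0]
        assert alignment_error(X, Y)[0] == 2 * (n - 1)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            alignment_error(np.ones((1, 2)), np.ones((1, 2)))


class TestSilhouette:
    def test_tight_separated_clusters_near_one(self, rng):
        a = np.tile([10.0, 0.0, 0.0], (5, 1)) + rng.normal(0, 1e-3, (5, 3))
        b = np.tile([0.0, 10.0, 0.0], (5, 1)) + rng.normal(0, 1e-3, (5, 3))
        emb = Embedding(coords=np.vstack([a, b]), dims=(2, 4))
        si = silhouette_index(emb, np.array([0] * 5 + [1] * 5))
        assert si.min() > 0.9

    def test_six_point_formula_oracle(self):
        coords = np.array(
            [[1.0, 0.0], [0.9, 0.1], [1.0, 0.1], [0.0, 1.0], [0.1, 1.0], [0.1, 0.9]]
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        emb = Embedding(coords=coords, dims=(2, 3))
        si = silhouette_index(emb, labels)

        def cos_d(u, v):
            return 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        for i in range(6):
            own = [cos_d(coords[i], coords[j]) for j in range(6)
                   if labels[j] == labels[i] and j != i]
            other = [cos_d(coords[i], coords[j]) for j in range(6)
                     if labels[j] != labels[i]]
            a_i, b_i = np.mean(own), np.mean(other)
            assert si[i] == pytest.approx((b_i - a_i) / max(a_i, b_i), abs=1e-10)

    def test_single_cluster_rejected(self, rng):
        emb = Embedding(coords=rng.random((4, 2)), dims=(2, 3))
        with pytest.raises(ValueError):
            silhouette_index(emb, np.zeros(4))


class TestClusteringAgreement:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2])
        out = clustering_agreement(labels, labels)
        assert out["nmi"] == pytest.approx(1.0) and out["ari"] == pytest.approx(1.0)

    def test_single_cluster_vs_many_gives_zero_nmi(self):
        a = np.zeros(8, int)
        b = np.arange(8) % 3
        assert clustering_agreement(a, b)["nmi"] == pytest.approx(0.0)

    def test_ari_matches_combinatorial_oracle(self):
        from math import comb

        a = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        # contingency-table ARI by the standard adjusted-index formula
        cont = np.zeros((2, 3), int)
        for x, y in zip(a, b):
            cont[x, y] += 1
        sum_comb = sum(comb(int(n), 2) for n in cont.ravel())
        sum_a = sum(comb(int(n), 2) for n in cont.sum(1))
        sum_b = sum(comb(int(n), 2) for n in cont.sum(0))
        total = comb(10, 2)
        expected_idx = sum_a * sum_b / total
        max_idx = (sum_a + sum_b) / 2
        oracle = (sum_comb - expected_idx) / (max_idx - expected_idx)
        assert clustering_agreement(a, b)["ari"] == pytest.approx(oracle, rel=1e-12)


class TestGraphConnectivity:
    def test_fully_connected_labels_give_one(self, rng):
        a = rng.normal(0, 0.1, (8, 2))
        b = rng.normal(10, 0.1, (6, 2))
        coords = np.vstack([a, b])
        labels = np.array([0] * 8 + [1] * 6)
        assert graph_connectivity(coords, labels, k=7) == pytest.approx(1.0)

    def test_split_label_contributes_component_fraction(self):
        # label A: tight trio plus one stray whose nearest neighbor is a B
        # cell, so A's induced subgraph splits 3 + 1 -> contribution 3/4;
        # the two B cells remain mutually connected -> contribution 1
        coords = np.array(
            [[0.0], [0.1], [0.2], [50.0], [49.9], [49.8]]
        )
        labels = np.array(["A", "A", "A", "A", "B", "B"])
        gc = graph_connectivity(coords, labels, k=1)
        assert gc == pytest.approx((3 / 4 + 1.0) / 2)

    def test_matches_exhaustive_component_search(self, rng):
        coords = rng.random((12, 3))
        labels = rng.integers(0, 3, 12)
        k = 3
        got = graph_connectivity(coords, labels, k=k)
        # oracle: explicit kNN graph + BFS components
        from scipy.spatial.distance import cdist

        D = cdist(coords, coords)
        np.fill_diagonal(D, np.inf)
        adj = np.zeros((12, 12), bool)
        for i in range(12):
            for j in np.argsort(D[i], kind="stable")[:k]:
                adj[i, j] = adj[j, i] = True
        fracs = []
        for c in np.unique(labels):
            mem = np.flatnonzero(labels == c)
            seen = set()
            best = 0
            for start in mem:
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(
                        v for v in mem if adj[u, v] and v not in comp
                    )
                seen |= comp
                best = max(best, len(comp))
            fracs.append(best / len(mem))
        assert got == pytest.approx(float(np.mean(fracs)), rel=1e-12)

    def test_invariant_to_cell_permutation(self, rng):
        coords = rng.random((15, 2))
        labels = rng.integers(0, 2, 15)
        perm = rng.permutation(15)
        assert graph_connectivity(coords, labels, k=4) == pytest.approx(
            graph_connectivity(coords[perm], labels[perm], k=4)
        )


def _beta_pairs(scores, dists):
    n = len(scores)
    pairs = DistancePairs(np.arange(n), np.zeros(n, int), dists,
                          cutoff=200_000, n_res=n, n_genes=1)
    mat = sp.csc_matrix((scores, (np.arange(n), np.zeros(n, int))), shape=(n, 1))
    beta = CisRegCoefficients(
        mat, np.array([f"r{i}" for i in range(n)], object), np.array(["g"], object)
    )
    return beta, pairs


class TestAuprDistanceBins:
    def test_perfect_ranking_gives_one(self):
        beta, pairs = _beta_pairs([5.0, 4.0, 1.0, 0.5], [100.0] * 4)
        out = aupr_distance_bins(beta, pairs, {(0, 0), (1, 0)})
        assert out.loc[out["bin"] == "0-3k", "aupr"].iloc[0] == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        beta, pairs = _beta_pairs([1.0] * 8, [100.0] * 8)
        out = aupr_distance_bins(beta, pairs, {(0, 0), (3, 0)})
        assert out.loc[out["bin"] == "0-3k", "aupr"].iloc[0] == pytest.approx(2 / 8)

    def test_matches_threshold_enumeration_oracle(self, rng):
        scores = rng.random(8)
        truth = {(1, 0), (4, 0), (6, 0)}
        beta, pairs = _beta_pairs(scores, [100.0] * 8)
        out = aupr_distance_bins(beta, pairs, truth)
        got = out.loc[out["bin"] == "0-3k", "aupr"].iloc[0]
        # step-wise integration over descending unique thresholds
        is_pos = np.array([(i, 0) in truth for i in range(8)])
        order = np.argsort(-scores, kind="stable")
        tp = fp = 0
        aupr, prev_recall = 0.0, 0.0
        npos = is_pos.sum()
        for idx in order:
            if is_pos[idx]:
                tp += 1
            else:
                fp += 1
            recall = tp / npos
            precision = tp / (tp + fp)
            aupr += (recall - prev_recall) * precision
            prev_recall = recall
        assert got == pytest.approx(aupr, rel=1e-12)

    def test_invariant_to_monotone_score_transform(self, rng):
        scores = rng.random(10) + 0.1
        truth = {(2, 0), (5, 0)}
        b1, pairs = _beta_pairs(scores, [5000.0] * 10)
        b2, _ = _beta_pairs(np.exp(3 * scores), [5000.0] * 10)
        o1 = aupr_distance_bins(b1, pairs, truth)
        o2 = aupr_distance_bins(b2, pairs, truth)
        assert o1.loc[1, "aupr"] == pytest.approx(o2.loc[1, "aupr"])

    def test_empty_bin_is_missing(self):
        beta, pairs = _beta_pairs([1.0, 2.0], [100.0, 120_000.0])
        out = aupr_distance_bins(beta, pairs, {(1, 0)})
        assert np.isnan(out.loc[out["bin"] == "0-3k", "aupr"].iloc[0])
        assert out.loc[out["bin"] == "100-150k", "aupr"].iloc[0] == pytest.approx(1.0)


class TestPairedDifference:
    def test_equal_vectors_degenerate_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        out = paired_difference_test(a, a)
        assert out["p"] == 1.0 and out["t"] == 0.0 and out["degenerate"]

    def test_constant_nonzero_difference(self):
        a = np.array([1.0, 2.0, 3.0])
        out = paired_difference_test(a + 0.5, a)
        assert np.isinf(out["t"]) and out["p"] == 0.0

    def test_matches_textbook_formula(self, rng):
        a = rng.random(5)
        b = rng.random(5)
        out = paired_difference_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert out["t"] == pytest.approx(t, rel=1e-12)
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df=4)
        assert out["p"] == pytest.approx(p, rel=1e-12)
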