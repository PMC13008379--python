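"""Profile distances, average linkage, KGS selection, cophenetic comparison."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import average_linkage_trace, cophenetic_from_trace, kgs_penalty_curve, pearson
from scnkit.cluster import (
    Dendrogram,
    SCDiffClustering,
    average_linkage,
    cluster_pairing_export,
    cophenetic_correlation,
    kgs_optimal_k,
    profile_distance,
)
from scnkit.stats import SCDiff


def _scdiff(matrix: np.ndarray, labels=None) -> SCDiff:
    labels = labels or [f"n{i}" for i in range(matrix.shape[0])]
    return SCDiff(labels=labels, matrix=matrix,
                  mask=~np.eye(matrix.shape[0], dtype=bool))


class TestProfileDistance:
    def test_identical_profiles_distance_zero(self):
        m = np.zeros((4, 4))
        m[0, 2], m[0, 3] = 0.5, -0.2
        m[1, 2], m[1, 3] = 0.5, -0.2
        m += m.T
        dist, _ = profile_distance(_scdiff(m), ["n0", "n1", "n2"])
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_distance_two(self):
        m = np.zeros((4, 4))
        m[0, 2], m[0, 3] = 0.5, -0.2
        m[1, 2], m[1, 3] = -0.5, 0.2
        m += m.T
        dist, _ = profile_distance(_scdiff(m), ["n0", "n1", "n2"])
        assert dist[0, 1] == pytest.approx(2.0)

    def test_matches_elementwise_correlation_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        sd = _scdiff(m)
        dist, leaves = profile_distance(sd, sd.labels)
        for a in range(4):
            for b in range(a + 1, 4):
                keep = [c for c in range(4) if c not in (a, b)]
                expected = 1 - pearson(m[a, keep], m[b, keep])
                assert dist[a, b] == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_rejected_by_name(self):
        m = np.zeros((4, 4))
        m[1, 2] = m[2, 1] = 0.5  # n0's profile is all zeros
        with pytest.raises(ValueError, match="n0"):
            profile_distance(_scdiff(m), ["n0", "n1", "n2", "n3"])

    def test_euclidean_metric_available(self):
        m = np.zeros((4, 4))
        m[0, 2], m[1, 2] = 0.3, 0.3
        m[0, 3], m[1, 3] = 0.1, 0.4
        m += m.T
        dist, _ = profile_distance(_scdiff(m), ["n0", "n1", "n2"], metric="euclidean")
        assert dist[0, 1] == pytest.approx(np.hypot(0.0, 0.3))


class TestAverageLinkage:
    def test_forced_merge_order_three_points(self):
        dist = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dend = average_linkage(dist, ["a", "b", "c"])
        assert dend.heights[0] == pytest.approx(0.1)
        assert dend.heights[1] == pytest.approx(1.0)

    def test_five_point_trace_matches_naive_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dend = average_linkage(dist, list("abcde"))
        oracle = average_linkage_trace(dist)
        assert np.allclose(sorted(dend.heights), sorted(h for *_, h in oracle), atol=1e-12)
        # cophenetic matrices agree entirely, not just heights
        coph_oracle = cophenetic_from_trace(5, oracle)
        assert np.allclose(dend.cophenetic_matrix(), coph_oracle, atol=1e-12)

    def test_heights_invariant_to_leaf_permutation(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(8, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        perm = rng.permutation(8)
        d1 = average_linkage(dist, [f"l{i}" for i in range(8)])
        d2 = average_linkage(dist[np.ix_(perm, perm)], [f"l{i}" for i in perm])
        assert np.allclose(np.sort(d1.heights), np.sort(d2.heights), atol=1e-12)

    def test_non_symmetric_rejected(self):
        bad = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(bad, ["a", "b"])

    def test_newick_roundtrips_leaf_names(self):
        dist = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]])
        nwk = average_linkage(dist, ["AV", "PuL", "Re"]).to_newick()
        assert nwk.endswith(";")
        for leaf in ("AV", "PuL", "Re"):
            assert leaf in nwk


def _clouds(rng, centers, n_per, sd, dims=3):
    pts = np.vstack([c + sd * rng.normal(size=(n_per, dims)) for c in centers])
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))


class TestKGS:
    def test_alpha_zero_selects_two(self):
        rng = np.random.default_rng(0)
        dist = _clouds(rng, [np.zeros(3), 10 * np.ones(3)], 5, 0.1)
        dend = average_linkage(dist, [f"l{i}" for i in range(10)])
        sel = kgs_optimal_k(dend, dist, alpha=0.0)
        assert sel.k == 2
        assert np.allclose(sel.penalties, sel.ks)

    def test_three_separated_clouds_selected(self):
        rng = np.random.default_rng(1)
        centers = [np.zeros(3), np.array([10.0, 0, 0]), np.array([0, 10.0, 0])]
        dist = _clouds(rng, centers, 6, 0.1)
        dend = average_linkage(dist, [f"l{i}" for i in range(18)])
        sel = kgs_optimal_k(dend, dist, alpha=1.0)
        assert sel.k == 3

    def test_matches_exhaustive_penalty_oracle(self):
        rng = np.random.default_rng(2)
        dist = _clouds(rng, [np.zeros(2), 5 * np.ones(2)], 4, 0.5, dims=2)
        labels = [f"l{i}" for i in range(8)]
        dend = average_linkage(dist, labels)
        sel = kgs_optimal_k(dend, dist)
        cuts = {k: dend.cut(k) for k in range(2, 8)}
        ks, penalties, best = kgs_penalty_curve(cuts, dist, 8)
        assert np.allclose(sel.penalties, penalties, atol=1e-12)
        assert sel.k == best

    def test_degenerate_spreads_fall_back_to_two(self):
        # 4 mutually equidistant points: every cut has the same spread
        dist = np.ones((4, 4)) - np.eye(4)
        dend = average_linkage(dist, list("abcd"))
        with pytest.warns(UserWarning, match="falling back"):
            sel = kgs_optimal_k(dend, dist)
        assert sel.k == 2

    def test_too_few_leaves_rejected(self):
        dist = np.ones((3, 3)) - np.eye(3)
        dend = average_linkage(dist, list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            kgs_optimal_k(dend, dist)


class TestCophenetic:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dend = average_linkage(dist, [f"l{i}" for i in range(6)])
        assert cophenetic_correlation(dend, dend) == pytest.approx(1.0)

    def test_four_leaf_hand_read_heights(self):
        # pairs (a,b) at 0.1 and (c,d) at 0.2; cross distances 1.0
        dist = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        dend = average_linkage(dist, list("abcd"))
        coph = dend.cophenetic_matrix()
        expected = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        assert np.allclose(coph, expected, atol=1e-12)

    def test_symmetric_and_relabeling_invariant(self):
        rng = np.random.default_rng(5)
        d1 = rng.uniform(0.1, 1, size=(7, 7))
        d1 = (d1 + d1.T) / 2
        np.fill_diagonal(d1, 0)
        d2 = rng.uniform(0.1, 1, size=(7, 7))
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        labels = [f"l{i}" for i in range(7)]
        da, db = average_linkage(d1, labels), average_linkage(d2, labels)
        r_ab = cophenetic_correlation(da, db)
        assert r_ab == pytest.approx(cophenetic_correlation(db, da))
        # same tree with shuffled leaf order: identical correlation
        perm = rng.permutation(7)
        db_shuffled = average_linkage(d2[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert cophenetic_correlation(da, db_shuffled) == pytest.approx(r_ab)

    def test_independent_trees_weakly_correlated(self):
        rng = np.random.default_rng(6)
        rs = []
        labels = [f"l{i}" for i in range(20)]
        for _ in range(100):
            d1 = rng.uniform(0.1, 1, size=(20, 20))
            d1 = (d1 + d1.T) / 2
            np.fill_diagonal(d1, 0)
            d2 = rng.uniform(0.1, 1, size=(20, 20))
            d2 = (d2 + d2.T) / 2
            np.fill_diagonal(d2, 0)
            rs.append(cophenetic_correlation(average_linkage(d1, labels),
                                             average_linkage(d2, labels)))
        assert np.mean(np.abs(rs)) < 0.3

    def test_leaf_mismatch_rejected(self):
        dist = np.ones((4, 4)) - np.eye(4)
        a = average_linkage(dist, list("abcd"))
        b = average_linkage(dist, list("wxyz"))
        with pytest.raises(ValueError, match="leaf sets"):
            cophenetic_correlation(a, b)


class TestPairingExport:
    def test_identical_dendrograms_all_agree(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dend = average_linkage(dist, [f"l{i}" for i in range(6)])
        table = cluster_pairing_export(dend, dend, kA=2, kB=2)
        assert table["partners_agree"].all()
        assert set(table.columns) >= {"leaf", "partners_agree", "cluster_a", "cluster_b"}

    def test_disjoint_pairings_never_agree(self):
        # A pairs (0,1),(2,3); B pairs (0,2),(1,3): no first-merge partner shared
        dist_a = np.array(
            [[0, 0.1, 1, 1], [0.1, 0, 1, 1], [1, 1, 0, 0.1], [1, 1, 0.1, 0]], float
        )
        dist_b = np.array(
            [[0, 1, 0.1, 1], [1, 0, 1, 0.1], [0.1, 1, 0, 1], [1, 0.1, 1, 0]], float
        )
        labels = list("abcd")
        table = cluster_pairing_export(average_linkage(dist_a, labels),
                                       average_linkage(dist_b, labels))
        assert not table["partners_agree"].any()

    def test_half_shared_structure_recovered(self):
        # 8 leaves; pairs 0..3 shared across trees, pairs 4..7 scrambled in B
        def pair_dist(pairs, n=8):
            d = np.ones((n, n))
            np.fill_diagonal(d, 0)
            for a, b in pairs:
                d[a, b] = d[b, a] = 0.05
            return d

        labels = [f"l{i}" for i in range(8)]
        da = pair_dist([(0, 1), (2, 3), (4, 5), (6, 7)])
        db = pair_dist([(0, 1), (2, 3), (4, 6), (5, 7)])
        table = cluster_pairing_export(average_linkage(da, labels),
                                       average_linkage(db, labels))
        assert table["partners_agree"].mean() == pytest.approx(0.5, abs=0.15)


def test_block_profiles_recovered_exactly():
    """High-separation profile blocks: KGS picks the block count, ARI = 1."""
    rng = np.random.default_rng(20)
    n_groups, per_group, n_cols = 4, 6, 30
    leaves = [f"t{i}" for i in range(n_groups * per_group)]
    cols = [f"c{j}" for j in range(n_cols)]
    prototypes = rng.normal(size=(n_groups, n_cols))
    block = np.vstack([
        prototypes[g] + 0.05 * rng.normal(size=n_cols)
        for g in range(n_groups) for _ in range(per_group)
    ])
    labels = leaves + cols
    m = np.zeros((len(labels), len(labels)))
    m[: len(leaves), len(leaves):] = block
    m += m.T
    sd = SCDiff(labels=labels, matrix=m, mask=~np.eye(len(labels), dtype=bool))
    clus = SCDiffClustering(leaves=leaves, columns=cols).fit(sd)
    truth = np.repeat(np.arange(n_groups), per_group)
    assert clus.k_ == n_groups
    assert adjusted_rand_score(truth, clus.labels_) == 1.0
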