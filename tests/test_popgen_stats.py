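import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from haplopaint.data_model import MISSING, GenotypeMatrix, ValidationError
from haplopaint.popgen_stats import (
    NEI_CAP,
    DistanceMatrix,
    amova,
    average_pairwise_fst,
    nei_distance,
    neighbor_joining,
    pairwise_fst,
    pca,
    wc_fst,
)

import oracles


def random_matrix(rng, n, m, missing=0.0):
    calls = rng.integers(0, 2, (n, m)).astype(np.int8)
    if missing:
        calls[rng.random((n, m)) < missing] = MISSING
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)], calls
    )


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------

class TestNei:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        g = random_matrix(rng, 6, 50)
        groups = {"a": g.sample_ids[:3], "b": g.sample_ids[:3]}
        d = nei_distance(g, groups)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixed_capped(self):
        calls = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2"], calls)
        d = nei_distance(g, {"x": ["a", "b"], "y": ["c", "d"]})
        assert d.values[0, 1] == NEI_CAP

    def test_two_locus_worked_example(self):
        # x freqs (0.5, 1.0); y freqs (0.5, 0.0)
        # J_x = J_y = 0.75, J_xy = 0.25 -> D = ln 3
        calls = np.array(
            [[0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8
        )
        g = GenotypeMatrix(["x1", "x2", "y1", "y2"], ["m1", "m2"], calls)
        d = nei_distance(g, {"x": ["x1", "x2"], "y": ["y1", "y2"]})
        assert d.values[0, 1] == pytest.approx(math.log(3.0), abs=1e-12)

    def test_against_brute_force(self):
        rng = np.random.default_rng(1)
        g = random_matrix(rng, 10, 30)
        groups = {"a": g.sample_ids[:5], "b": g.sample_ids[5:]}
        d = nei_distance(g, groups)
        fa = g.allele_freq(g.sample_index(groups["a"]))
        fb = g.allele_freq(g.sample_index(groups["b"]))
        expected = oracles.nei_distance_brute(list(fa), list(fb))
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_no_shared_loci_flagged(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b"], ["m1", "m2"], calls)
        with pytest.warns(UserWarning, match="no shared"):
            d = nei_distance(g, {"x": ["a"], "y": ["b"]})
        assert np.isnan(d.values[0, 1])


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def _random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (newick, DistanceMatrix) with additivity."""
    clusters = [({f"t{i}": 0.0}, f"t{i}") for i in range(n_taxa)]
    labels = [f"t{i}" for i in range(n_taxa)]
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        (da, na), (db, nb) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.5, 2.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                d.loc[x, y] = d.loc[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in da.items()}
        merged.update({y: dy + lb for y, dy in db.items()})
        newick = f"({na}:{la:.6f},{nb}:{lb:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, newick))
    return clusters[0][1] + ";", DistanceMatrix(labels, d.to_numpy())


class TestNJ:
    def test_three_taxa(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        newick = neighbor_joining(d)
        tree = TreeNode.read(io.StringIO(newick))
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_additive_four_taxon_recovery(self):
        rng = np.random.default_rng(5)
        true_newick, d = _random_additive_tree(rng, 4)
        est = TreeNode.read(io.StringIO(neighbor_joining(d)))
        true = TreeNode.read(io.StringIO(true_newick))
        assert est.compare_rfd(true) == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=4, max_value=8), st.integers(min_value=0, max_value=10_000))
    def test_additive_recovery_property(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        true_newick, d = _random_additive_tree(rng, n_taxa)
        est = TreeNode.read(io.StringIO(neighbor_joining(d)))
        true = TreeNode.read(io.StringIO(true_newick))
        assert est.compare_rfd(true) == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        _, d = _random_additive_tree(rng, 6)
        perm = rng.permutation(len(d.ids))
        d2 = DistanceMatrix([d.ids[i] for i in perm], d.values[np.ix_(perm, perm)])
        t1 = TreeNode.read(io.StringIO(neighbor_joining(d)))
        t2 = TreeNode.read(io.StringIO(neighbor_joining(d2)))
        assert t1.compare_rfd(t2) == 0.0

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(7)
        _, d = _random_additive_tree(rng, 6)
        tree = TreeNode.read(io.StringIO(neighbor_joining(d)))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------

class TestWcFst:
    def test_identical_pops_small_negative(self):
        # duplicated panels give the exact finite-sample value -1/(n-1),
        # matching the brute-force ANOVA oracle (the estimator is unbiased
        # around zero, not identically zero)
        rng = np.random.default_rng(2)
        half = random_matrix(rng, 50, 40)
        calls = np.concatenate([half.calls, half.calls])
        g = GenotypeMatrix(
            [f"s{i}" for i in range(100)], list(half.snp_ids), calls
        )
        labels = [1] * 50 + [2] * 50
        res = wc_fst(g, labels)
        oracle, _, _ = oracles.wc_fst_brute([half.calls, half.calls])
        assert res.estimate == pytest.approx(oracle, abs=1e-12)
        assert res.estimate == pytest.approx(-1.0 / 49.0, abs=1e-12)

    def test_fixed_opposite_is_one(self):
        calls = np.concatenate(
            [np.zeros((50, 20), dtype=np.int8), np.ones((50, 20), dtype=np.int8)]
        )
        g = GenotypeMatrix([f"s{i}" for i in range(100)], [f"m{j}" for j in range(20)], calls)
        res = wc_fst(g, [1] * 50 + [2] * 50)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(3)
        g = random_matrix(rng, 24, 15, missing=0.1)
        labels = [1] * 8 + [2] * 10 + [3] * 6
        res = wc_fst(g, labels)
        oracle, a, b = oracles.wc_fst_brute(
            [g.calls[:8], g.calls[8:18], g.calls[18:]]
        )
        assert res.estimate == pytest.approx(oracle, abs=1e-10)
        for got_a, got_b, exp_a, exp_b in zip(res.a, res.b, a, b):
            if math.isnan(exp_a):
                assert np.isnan(got_a)
            else:
                assert got_a == pytest.approx(exp_a, abs=1e-10)
                assert got_b == pytest.approx(exp_b, abs=1e-10)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(4)
        g = random_matrix(rng, 30, 25)
        labels = [1] * 15 + [2] * 15
        flipped = GenotypeMatrix(
            list(g.sample_ids), list(g.snp_ids), (1 - g.calls).astype(np.int8)
        )
        assert wc_fst(g, labels).estimate == pytest.approx(
            wc_fst(flipped, labels).estimate, abs=1e-12
        )

    def test_average_pairwise_23_pops_vs_oracle(self):
        # 23 subpops, <=5 loci: equality with the individual-sums oracle
        rng = np.random.default_rng(5)
        sizes = rng.integers(4, 9, size=23)
        blocks = [rng.integers(0, 2, (s, 5)).astype(np.int8) for s in sizes]
        calls = np.concatenate(blocks)
        labels = np.concatenate([[k + 1] * s for k, s in enumerate(sizes)])
        g = GenotypeMatrix(
            [f"s{i}" for i in range(calls.shape[0])], [f"m{j}" for j in range(5)], calls
        )
        got = pairwise_fst(g, labels)
        expected = []
        for i in range(23):
            for j in range(i + 1, 23):
                est, _, _ = oracles.wc_fst_brute([blocks[i], blocks[j]])
                expected.append(est)
        assert np.allclose(got["fst"].to_numpy(), expected, atol=1e-10)
        assert average_pairwise_fst(g, labels) == pytest.approx(
            np.mean(expected), abs=1e-10
        )

    def test_single_pop_rejected(self, toy_matrix):
        with pytest.raises(ValidationError):
            wc_fst(toy_matrix, [1, 1, 1])

    def test_underinformative_pop_rejected(self):
        calls = np.array([[0, 1], [MISSING, MISSING], [0, 1], [1, 0]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2"], calls)
        with pytest.raises(ValidationError, match="non-missing"):
            wc_fst(g, [1, 1, 2, 2])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def test_clonal_groups_all_among(self):
        a = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.int8), (5, 1))
        b = np.tile(np.array([1, 0, 1, 0, 0], dtype=np.int8), (5, 1))
        g = GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"m{j}" for j in range(5)],
            np.concatenate([a, b]),
        )
        res = amova(g, [1] * 5 + [2] * 5, n_perm=99, seed=1)
        assert res.percentages["among_subpops"] == pytest.approx(100.0, abs=1e-9)
        assert res.p_values["among_subpops"] <= 0.05

    def test_null_labels_near_zero(self):
        pcts = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = random_matrix(rng, 40, 60)
            labels = rng.permutation([1] * 20 + [2] * 20)
            res = amova(g, labels, n_perm=0)
            pcts.append(res.percentages["among_subpops"] or 0.0)
        assert abs(np.mean(pcts)) < 2.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        g = random_matrix(rng, 12, 8)
        labels = [1] * 4 + [2] * 5 + [3] * 3
        res = amova(g, labels, n_perm=0)
        oracle = oracles.amova_one_level_brute(g.calls, labels)
        assert res.variance_components["among_subpops"] == pytest.approx(
            oracle["among"], abs=1e-10
        )
        assert res.variance_components["within"] == pytest.approx(
            oracle["within"], abs=1e-10
        )
        assert res.percentages["among_subpops"] == pytest.approx(
            oracle["pct_among"], abs=1e-8
        )
        assert res.sums_of_squares["total"] == pytest.approx(oracle["sst"], abs=1e-10)

    def test_percentages_sum_100(self):
        rng = np.random.default_rng(10)
        g = random_matrix(rng, 24, 30)
        labels = [1] * 8 + [2] * 8 + [3] * 8
        regions = ["r1"] * 16 + ["r2"] * 8
        res = amova(g, labels, regions, n_perm=0)
        total = sum(v for v in res.percentages.values() if v is not None)
        assert total == pytest.approx(100.0, abs=0.01)

    def test_two_level_design_reports_three_levels(self):
        rng = np.random.default_rng(11)
        g = random_matrix(rng, 30, 40)
        labels = [1] * 10 + [2] * 10 + [3] * 10
        regions = ["early"] * 20 + ["late"] * 10
        res = amova(g, labels, regions, n_perm=49, seed=3)
        assert set(res.levels) == {"among_regions", "among_subpops", "within"}
        assert "among_regions" in res.p_values

    def test_permutation_p_uniform_under_null(self):
        # p-values from label shuffles of exchangeable data are ~Uniform(0,1)
        from scipy.stats import kstest

        ps = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            g = random_matrix(rng, 12, 10)
            labels = rng.permutation([1] * 6 + [2] * 6)
            res = amova(g, labels, n_perm=39, seed=seed)
            ps.append(res.p_values["among_subpops"])
        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_single_group_level_absent(self, toy_matrix):
        res = amova(toy_matrix, [1, 1, 1], n_perm=0)
        assert res.variance_components["among_subpops"] is None


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(12)
        proto_a = rng.integers(0, 2, 30).astype(np.int8)
        proto_b = 1 - proto_a
        calls = np.concatenate([np.tile(proto_a, (6, 1)), np.tile(proto_b, (6, 1))])
        g = GenotypeMatrix(
            [f"s{i}" for i in range(12)], [f"m{j}" for j in range(30)], calls
        )
        scores, evr = pca(g, 2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:6] > 0).all() != (pc1[6:] > 0).all()  # separated by sign
        assert evr[0] > evr[1]

    def test_evr_matches_eigendecomposition(self):
        rng = np.random.default_rng(13)
        g = random_matrix(rng, 10, 10)
        _, evr = pca(g, 5)
        expected = oracles.pca_evr_brute(g.calls, 5)
        assert np.allclose(evr, expected, atol=1e-10)

    def test_permutation_reproduces_scores(self):
        rng = np.random.default_rng(14)
        g = random_matrix(rng, 15, 20)
        perm = rng.permutation(15)
        g2 = g.take_samples([g.sample_ids[i] for i in perm])
        s1, _ = pca(g, 2)
        s2, _ = pca(g2, 2)
        aligned = s2.loc[s1.index]
        for col in s1.columns:
            match = np.allclose(s1[col], aligned[col], atol=1e-8)
            flipped = np.allclose(s1[col], -aligned[col], atol=1e-8)
            assert match or flipped

    def test_missing_rejected_without_policy(self):
        calls = np.array([[0, MISSING], [1, 0]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b"], ["m1", "m2"], calls)
        with pytest.raises(ValidationError):
            pca(g, 1)
        scores, _ = pca(g, 1, mean_fill=True)
        assert np.isfinite(scores.to_numpy()).all()
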