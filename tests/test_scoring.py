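"""Recovery-AUC, matched-control thresholds, module scores and GSEA."""

import numpy as np
import pandas as pd
import pytest

from racpipe.containers import GeneSignature
from racpipe.scoring import (
    activation_threshold,
    build_control_sets,
    module_score,
    preranked_gsea,
    rank_genes_per_cell,
    recovery_auc,
    recovery_auc_matrix,
    score_cells,
    ssgsea,
)
from tests.conftest import make_matrix


def brute_force_recovery_auc(ranking, sig_genes, m_top):
    """Independent step-curve oracle: explicit rectangle summation."""
    sig = set(sig_genes) & set(ranking)
    area, found = 0, 0
    for x in range(1, m_top + 1):
        if ranking[x - 1] in sig:
            found += 1
        area += found
    best_area, best_found = 0, 0
    s_eff = min(len(sig), m_top)
    for x in range(1, m_top + 1):
        if best_found < s_eff:
            best_found += 1
        best_area += best_found
    return area / best_area


class TestRecoveryAUC:
    def test_perfect_recovery(self):
        ranking = [f"g{i}" for i in range(100)]
        assert recovery_auc(ranking, ranking[:5], 0.05) == 1.0

    def test_no_recovery(self):
        ranking = [f"g{i}" for i in range(100)]
        assert recovery_auc(ranking, ranking[-3:], 0.05) == 0.0

    def test_oracle_ranks_2_and_4(self):
        # universe 100 genes, M = 5, signature at rank positions 2 and 4
        ranking = [f"g{i}" for i in range(100)]
        sig = [ranking[1], ranking[3]]
        expected = brute_force_recovery_auc(ranking, sig, 5)
        assert recovery_auc(ranking, sig, 0.05) == pytest.approx(expected, abs=1e-15)
        # hand computation: curve y = 0,1,1,2,2 -> area 6; best 1,2,2,2,2 -> 9
        assert expected == pytest.approx(6 / 9)

    def test_expression_invariance_given_ranking(self, rng):
        """The score depends on the ranking only, not the values behind it."""
        genes = [f"g{i:02d}" for i in range(40)]
        norm_a = np.sort(rng.random((40, 1)), axis=0)[::-1]
        norm_b = np.sort(rng.lognormal(0, 1, (40, 1)), axis=0)[::-1]
        sig = genes[3:8]
        ma = make_matrix(np.ones((40, 1), dtype=int), gene_ids=genes, normalized=norm_a)
        mb = make_matrix(np.ones((40, 1), dtype=int), gene_ids=genes, normalized=norm_b)
        oa = rank_genes_per_cell(ma, tie_break="symbol")
        ob = rank_genes_per_cell(mb, tie_break="symbol")
        mask = np.isin(genes, sig)[None, :]
        sa = recovery_auc_matrix(oa, mask, 0.25)
        sb = recovery_auc_matrix(ob, mask, 0.25)
        np.testing.assert_allclose(sa, sb)

    def test_matrix_matches_scalar(self, rng):
        genes = [f"g{i:02d}" for i in range(30)]
        norm = rng.random((30, 8))
        m = make_matrix(np.ones((30, 8), dtype=int), gene_ids=genes, normalized=norm)
        orders = rank_genes_per_cell(m, tie_break="symbol")
        sig = list(rng.choice(genes, size=6, replace=False))
        mask = np.isin(genes, sig)[None, :]
        mat = recovery_auc_matrix(orders, mask, 0.3)
        for c in range(8):
            ranking = [genes[i] for i in orders[c]]
            assert mat[0, c] == pytest.approx(recovery_auc(ranking, sig, 0.3))

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="intersect"):
            recovery_auc(["a", "b"], ["z"], 1.0)


class TestControlSets:
    def test_bin_histogram_conserved(self, small_matrix):
        sig = GeneSignature(name="s", genes=[f"g{i:03d}" for i in (0, 7, 13, 21, 33)])
        bundle = build_control_sets(small_matrix, sig, n_sets=20, n_bins=5, seed=1)
        target = bundle.bin_assignments.loc[bundle.signature_genes].value_counts()
        for cs in bundle.control_sets:
            got = bundle.bin_assignments.loc[cs].value_counts()
            assert got.sort_index().equals(target.sort_index())
            assert not set(cs) & set(bundle.signature_genes)

    def test_deterministic(self, small_matrix, signature):
        b1 = build_control_sets(small_matrix, signature, n_sets=10, seed=5)
        b2 = build_control_sets(small_matrix, signature, n_sets=10, seed=5)
        assert b1.control_sets == b2.control_sets

    def test_n_sets(self, small_matrix, signature):
        assert build_control_sets(small_matrix, signature, n_sets=100).n_sets == 100

    def test_small_bin_warns_and_samples_with_replacement(self, rng):
        # 6 genes, 3 bins of 2: a 2-gene signature filling one bin leaves
        # no non-signature genes there
        norm = np.sort(rng.random((6, 4)), axis=0)
        m = make_matrix(np.ones((6, 4), dtype=int), normalized=norm)
        top_two = list(
            pd.Series(m.mean_normalized(), index=m.gene_ids).nlargest(2).index
        )
        sig = GeneSignature(name="s", genes=top_two)
        with pytest.warns(UserWarning, match="replacement"):
            build_control_sets(m, sig, n_sets=3, n_bins=3, seed=0)


class TestActivationThreshold:
    def test_constant_background(self):
        assert activation_threshold([0.3] * 50, 0.95) == pytest.approx(0.3)

    def test_median(self):
        assert activation_threshold([1, 2, 3, 4, 5], 0.5) == pytest.approx(3)

    def test_uniform_background(self, rng):
        thr = activation_threshold(rng.random(200_000), 0.95)
        assert thr == pytest.approx(0.95, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            activation_threshold([], 0.95)


class TestModuleScore:
    def test_planted_shift_recovered(self, rng):
        """Signature genes shifted +delta above matched controls score ~delta."""
        n_genes, n_cells, delta = 200, 80, 1.5
        norm = rng.normal(3.0, 0.2, size=(n_genes, n_cells)).clip(min=0)
        sig_idx = rng.choice(n_genes, 10, replace=False)
        norm[sig_idx] += delta
        m = make_matrix(np.ones((n_genes, n_cells), dtype=int), normalized=norm)
        sig = GeneSignature(name="s", genes=[f"g{i:03d}" for i in sig_idx])
        scores = module_score(m, sig, n_sets=30, n_bins=10, seed=0)
        assert scores.mean() == pytest.approx(delta, abs=0.25)

    def test_all_zero_cell_scores_zero(self, rng):
        norm = rng.random((50, 5))
        norm[:, 2] = 0.0
        m = make_matrix(np.ones((50, 5), dtype=int), normalized=norm)
        sig = GeneSignature(name="s", genes=["g000", "g010"])
        scores = module_score(m, sig, n_sets=10, n_bins=5, seed=0)
        assert scores[2] == pytest.approx(0.0, abs=1e-12)


class TestScoreCells:
    def test_score_table_contract(self, small_matrix, signature):
        tab = score_cells(small_matrix, signature, n_controls=20, seed=0)
        assert set(tab.columns) == {"cell_id", "signature", "score", "threshold", "active"}
        assert ((tab["score"] >= 0) & (tab["score"] <= 1)).all()
        np.testing.assert_array_equal(
            tab["active"].to_numpy(), (tab["score"] > tab["threshold"]).to_numpy()
        )

    def test_deterministic(self, small_matrix, signature):
        a = score_cells(small_matrix, signature, n_controls=15, seed=9)
        b = score_cells(small_matrix, signature, n_controls=15, seed=9)
        pd.testing.assert_frame_equal(a, b)


def brute_force_ssgsea(values, genes, gene_set, alpha):
    """Independent running-sum enumeration."""
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    n = len(genes)
    in_set = [genes[i] in set(gene_set) for i in order]
    ranks = [n - pos for pos in range(n)]
    w = [r**alpha if m else 0.0 for r, m in zip(ranks, in_set)]
    denom = sum(w)
    n_out = n - sum(in_set)
    total, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos in range(n):
        cum_in += w[pos] / denom
        cum_out += (0 if in_set[pos] else 1) / n_out
        total += cum_in - cum_out
    return total / n


class TestSsgsea:
    def test_top_vs_bottom_monotonicity(self):
        expr = pd.Series({f"g{i}": 10.0 - i for i in range(10)})
        top = ssgsea(expr, ["g0"], alpha=0.75)
        bottom = ssgsea(expr, ["g9"], alpha=0.75)
        assert top > bottom

    def test_alpha_zero_oracle(self):
        genes = ["a", "b", "c", "d", "e"]
        values = [5.0, 4.0, 3.0, 2.0, 1.0]
        gene_set = ["b", "d"]
        expected = brute_force_ssgsea(values, genes, gene_set, 0.0)
        got = ssgsea(pd.Series(values, index=genes), gene_set, alpha=0.0)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.75, 1.0])
    def test_monotone_transform_invariance(self, rng, alpha):
        genes = [f"g{i:02d}" for i in range(30)]
        vals = rng.normal(size=30)
        expr = pd.Series(vals, index=genes)
        expr2 = pd.Series(np.exp(2 * vals) + 5, index=genes)  # strictly monotone
        gene_set = list(rng.choice(genes, 6, replace=False))
        assert ssgsea(expr, gene_set, alpha) == pytest.approx(
            ssgsea(expr2, gene_set, alpha), abs=1e-12
        )

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ssgsea(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0}), ["a"])


class TestPrerankedGsea:
    def test_top_set_enriched(self, rng):
        genes = [f"g{i:03d}" for i in range(300)]
        stats = pd.Series(np.sort(rng.normal(size=300))[::-1], index=genes)
        es, nes, p = preranked_gsea(stats, genes[:20], n_perm=200, seed=0)
        assert es > 0.5 and nes > 1.5
        assert p == pytest.approx(1 / 201, abs=1e-12)

    def test_random_set_null(self, rng):
        genes = [f"g{i:03d}" for i in range(300)]
        stats = pd.Series(rng.normal(size=300), index=genes)
        pvals, ness = [], []
        for rep in range(30):
            gs = list(rng.choice(genes, 15, replace=False))
            es, nes, p = preranked_gsea(stats, gs, n_perm=150, seed=rep)
            pvals.append(p)
            ness.append(nes)
        # null NES centred near +-1, p not concentrated at the floor
        assert 0.6 < np.mean(np.abs(ness)) < 1.6
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25

    def test_small_set_errors(self, rng):
        stats = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        with pytest.raises(ValueError, match="smaller than 2"):
            preranked_gsea(stats, ["g1"], n_perm=100)
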