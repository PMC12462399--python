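"""RAC identification, superclusters, cell-cycle phases, drug classes."""

import numpy as np
import pandas as pd
import pytest

from racpipe.containers import GeneSignature
from racpipe.states import (
    assign_cell_cycle,
    consensus_supercluster_signature,
    differential_mean_vectors,
    drug_class_enrichment,
    global_rac_signature,
    identify_racs,
    sample_odds_ratio,
    supercluster_racs,
)
from tests.conftest import make_matrix


def hypergeom_two_sided_p(a, b, c, d):
    """Exact Fisher p by enumeration of the conditional table distribution."""
    from math import comb

    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)
    p_obs = comb(row1, a) * comb(n - row1, col1 - a) / denom
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = comb(row1, x) * comb(n - row1, col1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestIdentifyRacs:
    def test_worked_odds_ratio(self):
        # cluster: 40 active / 60 inactive; rest: 100 active / 800 inactive
        active = np.array([True] * 40 + [False] * 60 + [True] * 100 + [False] * 800)
        clusters = np.array([0] * 100 + [1] * 900)
        out = identify_racs(active, clusters)
        rec = out[out["cluster_id"] == 0].iloc[0]
        assert rec["odds_ratio"] == pytest.approx((40 * 800) / (60 * 100), rel=1e-12)
        assert rec["odds_ratio"] == pytest.approx(5.333, abs=1e-3)
        expected_p = hypergeom_two_sided_p(40, 60, 100, 800)
        assert rec["p"] == pytest.approx(expected_p, rel=1e-6)
        assert bool(rec["is_rac"])

    def test_equal_fractions_not_rac(self):
        active = np.array(([True] * 10 + [False] * 40) * 2)
        clusters = np.repeat([0, 1], 50)
        out = identify_racs(active, clusters)
        assert np.allclose(out["odds_ratio"], 1.0)
        assert not out["is_rac"].any()

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="single cluster"):
            identify_racs([True, False] * 10, [0] * 20)

    def test_haldane_correction_on_zero_cell(self):
        active = np.array([True] * 20 + [False] * 0 + [False] * 80)
        clusters = np.array([0] * 20 + [1] * 80)
        out = identify_racs(active, clusters)
        rec = out[out["cluster_id"] == 0].iloc[0]
        expected = (20.5 * 80.5) / (0.5 * 0.5)
        assert rec["odds_ratio"] == pytest.approx(expected)

    def test_bh_within_line(self):
        rng = np.random.default_rng(0)
        active = rng.random(400) < 0.2
        clusters = np.tile(np.repeat([0, 1, 2, 3], 50), 2)
        lines = np.repeat(["A", "B"], 200)
        out = identify_racs(active, clusters, lines)
        assert len(out) == 8
        for _, grp in out.groupby("cell_line"):
            assert (grp["p_adj"] >= grp["p"] - 1e-12).all()


class TestGlobalRacSignature:
    def test_planted_program_heads_signature(self, rng):
        n_genes, n_cells = 200, 120
        norm = np.log1p(rng.poisson(5.0, size=(n_genes, n_cells)))
        flags = np.zeros(n_cells, dtype=bool)
        flags[:40] = True
        planted = rng.choice(n_genes, 30, replace=False)
        norm[np.ix_(planted, np.where(flags)[0])] += 1.2
        m = make_matrix(np.ones((n_genes, n_cells), dtype=int), normalized=norm)
        sig = global_rac_signature(m, flags, n_top=30)
        expected = {f"g{i:03d}" for i in planted}
        assert len(set(sig.genes) & expected) >= 27

    def test_n_top_larger_than_significant(self, rng):
        norm = np.log1p(rng.poisson(5.0, size=(50, 60)))
        flags = np.zeros(60, dtype=bool)
        flags[:20] = True
        norm[:3, :20] += 2.0
        m = make_matrix(np.ones((50, 60), dtype=int), normalized=norm)
        sig = global_rac_signature(m, flags, n_top=200)
        assert 0 < len(sig.genes) < 200

    def test_no_significant_warns_empty(self, rng):
        norm = np.log1p(rng.poisson(5.0, size=(30, 40)))
        flags = np.zeros(40, dtype=bool)
        flags[:15] = True
        m = make_matrix(np.ones((30, 40), dtype=int), normalized=norm)
        with pytest.warns(UserWarning, match="empty"):
            sig = global_rac_signature(m, flags)
        assert sig.genes == []

    def test_all_rac_errors(self, small_matrix):
        with pytest.raises(ValueError):
            global_rac_signature(small_matrix, np.ones(small_matrix.n_cells, dtype=bool))


def _line_matrices(rng, diff=1.0, n_genes=30):
    """Two cell lines, two clusters each; cluster 0 shifted by `diff`."""
    out = {}
    for line in ("A", "B"):
        norm = rng.normal(2.0, 0.1, size=(n_genes, 40)).clip(min=0)
        norm[:10, :20] += diff  # cluster 0 overexpresses genes 0..9
        m = make_matrix(
            np.ones((n_genes, 40), dtype=int),
            cell_ids=[f"{line}{i}" for i in range(40)],
            normalized=norm,
        )
        out[line] = (m, np.repeat([0, 1], 20))
    return out


class TestDifferentialMeanVectors:
    def test_zero_vector_for_identical_rac(self, rng):
        matrices = _line_matrices(rng, diff=0.0)
        # make cluster 0 exactly identical to cluster 1
        for m, labels in matrices.values():
            m.normalized[:, :20] = m.normalized[:, 20:]
        rt = pd.DataFrame(
            {"cell_line": ["A"], "cluster_id": [0], "is_rac": [True]}
        )
        vec = differential_mean_vectors(matrices, rt, list(matrices["A"][0].gene_ids))
        np.testing.assert_allclose(vec.to_numpy(), 0.0, atol=1e-12)

    def test_planted_entries_positive(self, rng):
        matrices = _line_matrices(rng, diff=1.0)
        rt = pd.DataFrame(
            {"cell_line": ["A", "B"], "cluster_id": [0, 0], "is_rac": [True, True]}
        )
        genes = list(matrices["A"][0].gene_ids)
        vec = differential_mean_vectors(matrices, rt, genes)
        assert (vec[genes[:10]].to_numpy() > 0.5).all()
        assert vec.index.tolist() == ["A:0", "B:0"]

    def test_empty_shared_genes(self, rng):
        matrices = _line_matrices(rng)
        rt = pd.DataFrame({"cell_line": ["A"], "cluster_id": [0], "is_rac": [True]})
        with pytest.raises(ValueError, match="empty shared"):
            differential_mean_vectors(matrices, rt, [])


class TestSuperclusterRacs:
    def test_identical_vectors_group(self, rng):
        v = rng.normal(size=50)
        vectors = pd.DataFrame(
            [v, v, rng.normal(size=50)],
            index=["A:0", "B:1", "A:2"],
            columns=[f"g{i}" for i in range(50)],
        )
        scs, unassigned, newick = supercluster_racs(vectors, corr_threshold=0.9)
        assert len(scs) == 1
        assert set(scs[0].members) == {("A", 0), ("B", 1)}
        assert ("A", 2) in unassigned
        assert newick.endswith(";") and "A:0" in newick

    def test_constant_vector_errors(self):
        vectors = pd.DataFrame(
            [[1.0] * 10, list(range(10))], index=["A:0", "B:0"]
        )
        with pytest.raises(ValueError, match="A:0"):
            supercluster_racs(vectors)

    def test_input_order_invariance(self, rng):
        base = rng.normal(size=(4, 60))
        base[1] = base[0] + rng.normal(0, 0.05, 60)
        base[3] = base[2] + rng.normal(0, 0.05, 60)
        idx = ["A:0", "B:0", "A:1", "B:1"]
        v1 = pd.DataFrame(base, index=idx)
        v2 = v1.iloc[::-1]
        s1, u1, _ = supercluster_racs(v1)
        s2, u2, _ = supercluster_racs(v2)
        assert [set(s.members) for s in s1] == [set(s.members) for s in s2]
        assert u1 == u2

    def test_min_lines_rule(self, rng):
        v = rng.normal(size=60)
        vectors = pd.DataFrame(
            [v, v + rng.normal(0, 0.01, 60), rng.normal(size=60), 2 * rng.normal(size=60)],
            index=["A:0", "A:1", "B:0", "B:1"],
        )
        scs, unassigned, _ = supercluster_racs(vectors, corr_threshold=0.8)
        # the correlated pair is same-line, so no supercluster forms
        assert scs == []
        assert len(unassigned) == 4


class TestConsensusSuperclusterSignature:
    def _table(self, rng, up):
        genes = [f"g{i:03d}" for i in range(150)]
        fc = rng.normal(0, 0.05, 150)
        p = np.full(150, 0.9)
        df = pd.DataFrame({"gene": genes, "log2_fc": fc, "p": p})
        for rank, g in enumerate(up):
            i = genes.index(g)
            df.loc[i, "log2_fc"] = 2.0 - 0.05 * rank
            df.loc[i, "p"] = 1e-9
        df["p_adj"] = np.minimum(df["p"] * 150, 1.0)
        df["group"] = "rac"
        return df

    def test_identical_tables(self, rng):
        up = [f"g{i:03d}" for i in range(8)]
        t = self._table(rng, up)
        sig = consensus_supercluster_signature([t.copy(), t.copy()])
        assert set(sig.genes) == set(up)

    def test_up_down_disjoint(self, rng):
        up = [f"g{i:03d}" for i in range(8)]
        t = self._table(rng, up)
        t2 = t.copy()
        down_idx = t2.index[20:26]
        t2.loc[down_idx, "log2_fc"] = -1.5
        t2.loc[down_idx, "p_adj"] = 1e-6
        sig_up = consensus_supercluster_signature([t2.copy(), t2.copy()], "up")
        sig_down = consensus_supercluster_signature([t2.copy(), t2.copy()], "down")
        assert not set(sig_up.genes) & set(sig_down.genes)
        assert len(sig_down.genes) == 6

    def test_single_table_errors(self, rng):
        t = self._table(rng, ["g000"])
        with pytest.raises(ValueError, match="two member"):
            consensus_supercluster_signature([t])


class TestAssignCellCycle:
    @staticmethod
    def _phase_world(rng, n_cells=60):
        genes = [f"g{i:03d}" for i in range(120)]
        sigs = {
            "G0": GeneSignature(name="G0", genes=genes[0:10]),
            "S": GeneSignature(name="S", genes=genes[10:20]),
            "G2M": GeneSignature(name="G2M", genes=genes[20:30]),
        }
        base = rng.uniform(1.0, 3.0, size=120)
        norm = (base[:, None] + rng.normal(0, 0.1, size=(120, n_cells))).clip(min=0)
        m = make_matrix(np.ones((120, n_cells), dtype=int), gene_ids=genes, normalized=norm)
        return m, sigs

    def test_g0_cells_called_g0(self, rng):
        m, sigs = self._phase_world(rng)
        m.normalized[0:10, :30] += 2.0  # G0 program on in half the cells
        out = assign_cell_cycle(m, sigs, n_controls=20, n_bins=8, seed=0)
        assert (out["phase"][:30] == "G0").mean() >= 0.95

    def test_planted_s_phase(self, rng):
        m, sigs = self._phase_world(rng)
        m.normalized[10:20, :40] += 2.0
        out = assign_cell_cycle(m, sigs, n_controls=20, n_bins=8, seed=0)
        assert (out["phase"][:40] == "S").mean() >= 0.95

    def test_all_nonpositive_scores_fall_back_to_g1(self, rng):
        m, sigs = self._phase_world(rng)
        # suppress every phase program in half the cells: those cells sit
        # below their expression-matched controls on all three programs
        m.normalized[0:30, :30] -= 1.0
        out = assign_cell_cycle(m, sigs, n_controls=20, n_bins=8, seed=0)
        assert (out["phase"][:30] == "G1").mean() >= 0.9

    def test_four_signature_tie_order(self, rng):
        m, sigs = self._phase_world(rng)
        genes = list(m.gene_ids)
        sigs = dict(sigs)
        sigs["G1"] = GeneSignature(name="G1", genes=genes[30:40])
        out = assign_cell_cycle(m, sigs, n_controls=20, n_bins=8, seed=0)
        # no phase planted: scores hover near zero; argmax ties broken by
        # the fixed order means G0 precedes the others when exactly equal
        assert set(out["phase"]) <= {"G0", "G1", "S", "G2M"}

    def test_missing_phase_errors(self, rng):
        m, sigs = self._phase_world(rng)
        del sigs["S"]
        with pytest.raises(ValueError, match="missing phase"):
            assign_cell_cycle(m, sigs)


class TestDrugClassEnrichment:
    @staticmethod
    def _meta(n_class_in, n_other_in, n_class_out, n_other_out):
        rows = []
        spec = [
            ("epi", 0, n_class_in),
            ("other", 0, n_other_in),
            ("epi", 1, n_class_out),
            ("other", 1, n_other_out),
        ]
        i = 0
        for dc, cl, n in spec:
            for _ in range(n):
                rows.append(
                    {
                        "cell_id": f"c{i}",
                        "cell_line": "A",
                        "treatment": f"{dc}_drug",
                        "drug_class": dc,
                        "timepoint": 24.0,
                        "cluster_id": cl,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_worked_table(self):
        meta = self._meta(30, 70, 20, 180)
        res = drug_class_enrichment(meta, [("A", 0)], "epi")
        assert res["odds_ratio"] == pytest.approx((30 * 180) / (70 * 20), rel=1e-12)
        assert res["odds_ratio"] == pytest.approx(3.857, abs=1e-3)

    def test_uniform_class_or_near_one(self):
        meta = self._meta(50, 150, 50, 150)
        res = drug_class_enrichment(meta, [("A", 0)], "epi")
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["fold_enrichment"] == pytest.approx(1.0)

    def test_absent_class_errors(self):
        meta = self._meta(5, 5, 5, 5)
        with pytest.raises(ValueError, match="absent"):
            drug_class_enrichment(meta, [("A", 0)], "nope")


def test_sample_odds_ratio_haldane():
    assert sample_odds_ratio(2, 3, 4, 5) == pytest.approx(10 / 12)
    assert sample_odds_ratio(0, 3, 4, 5) == pytest.approx((0.5 * 5.5) / (3.5 * 4.5))


def test_bundled_cell_cycle_signatures_load():
    from racpipe.resources import cell_cycle_signatures

    sigs = cell_cycle_signatures()
    assert {"G0", "S", "G2M"} <= set(sigs)
    assert "PCNA" in sigs["S"].genes and "CDK1" in sigs["G2M"].genes
    # the G0 default is a labelled stand-in, not the external signature
    assert "stand-in" in sigs["G0"].provenance or "synthetic" in sigs["G0"].provenance
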