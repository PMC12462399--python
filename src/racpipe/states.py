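"""Resistance-activated clusters (RACs) and cross-line superclusters.

A RAC is a transcriptional cluster significantly enriched (Fisher exact,
odds ratio > 1, BH-adjusted p < 0.05 within its cell line) for cells whose
signature score exceeds the matched-control activation threshold. RACs
from different cell lines are grouped into superclusters by hierarchical
clustering of their differential mean-expression vectors (1 - Spearman
distance, average linkage); groups spanning at least two lines become
superclusters, each with RRA consensus up/down signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .containers import ExpressionMatrix, GeneSignature
from .rank_aggregation import build_consensus_signature, find_markers
from .scoring import ControlSetBundle, module_score

__all__ = [
    "Supercluster",
    "sample_odds_ratio",
    "identify_racs",
    "global_rac_signature",
    "differential_mean_vectors",
    "supercluster_racs",
    "consensus_supercluster_signature",
    "assign_cell_cycle",
    "drug_class_enrichment",
]

PHASE_ORDER = ("G0", "G1", "S", "G2M")


@dataclass
class Supercluster:
    """A cross-line group of RACs interpreted as a shared resistance state."""

    id: int
    members: list[tuple[str, int]]  # (cell_line, cluster_id)
    consensus_up: GeneSignature | None = None
    consensus_down: GeneSignature | None = None
    drug_class_enrichment: pd.DataFrame | None = None

    @property
    def lines(self) -> set[str]:
        return {line for line, _ in self.members}


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with Haldane–Anscombe 0.5 on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def identify_racs(
    active_flags: Sequence[bool],
    clusters: Sequence[int],
    cell_lines: Sequence[str] | None = None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    adjust_scope: str = "per_line",
) -> pd.DataFrame:
    """Per-cluster Fisher enrichment of signature-active cells.

    Builds, for every cluster, the 2x2 table of active/inactive cells in
    versus out of the cluster (within the cluster's cell line), computes
    the Fisher exact p-value and the sample odds ratio, adjusts p-values
    by Benjamini–Hochberg across clusters (within each line by default),
    and flags RACs as odds_ratio > 1 with adjusted p < alpha.
    """
    active = np.asarray(active_flags, dtype=bool)
    clust = np.asarray(clusters)
    if active.size != clust.size:
        raise ValueError("active_flags and clusters must cover the same cells")
    lines = (
        np.asarray(cell_lines)
        if cell_lines is not None
        else np.full(active.size, "all", dtype=object)
    )
    if lines.size != active.size:
        raise ValueError("cell_lines must cover the same cells")
    if adjust_scope not in ("per_line", "global"):
        raise ValueError("adjust_scope must be 'per_line' or 'global'")

    rows = []
    for line in pd.unique(lines):
        in_line = lines == line
        line_clusters = pd.unique(clust[in_line])
        if len(line_clusters) < 2:
            raise ValueError(
                f"cell line {line!r} has a single cluster; no out-group exists"
            )
        for cl in sorted(line_clusters):
            in_cl = in_line & (clust == cl)
            out_cl = in_line & (clust != cl)
            a = int((active & in_cl).sum())
            b = int((~active & in_cl).sum())
            c = int((active & out_cl).sum())
            d = int((~active & out_cl).sum())
            _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append(
                {
                    "cell_line": line,
                    "cluster_id": cl,
                    "n_active_in": a,
                    "n_inactive_in": b,
                    "n_active_out": c,
                    "n_inactive_out": d,
                    "odds_ratio": sample_odds_ratio(a, b, c, d),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if adjust_scope == "per_line":
        out["p_adj"] = out.groupby("cell_line")["p"].transform(
            lambda p: scipy.stats.false_discovery_control(p.to_numpy(), method="bh")
        )
    else:
        out["p_adj"] = scipy.stats.false_discovery_control(
            out["p"].to_numpy(), method="bh"
        )
    out["is_rac"] = (out["odds_ratio"] > 1) & (out["p_adj"] < alpha)
    return out


def global_rac_signature(
    m: ExpressionMatrix,
    rac_flags: Sequence[bool],
    n_top: int = 200,
    name: str = "global_rac",
) -> GeneSignature:
    """Top up-regulated markers of RAC cells versus all other cells.

    Markers with adjusted p < 0.05 and positive log2 fold change, ranked
    by fold change; the top ``n_top`` (all, if fewer) form the signature.
    """
    flags = np.asarray(rac_flags, dtype=bool)
    if flags.all() or (~flags).all():
        raise ValueError("need both RAC and non-RAC cells")
    markers = find_markers(m, np.where(flags, "RAC", "rest"), "RAC")
    sel = markers[(markers["p_adj"] < 0.05) & (markers["log2_fc"] > 0)]
    if sel.empty:
        warnings.warn("no significant RAC markers; returning an empty signature")
        return GeneSignature(name=name, genes=[], direction="up")
    sel = sel.sort_values(["log2_fc", "gene"], ascending=[False, True], kind="stable")
    head = sel.head(n_top)
    return GeneSignature(
        name=name,
        genes=head["gene"].tolist(),
        direction="up",
        scores=dict(zip(head["gene"], head["log2_fc"])),
        provenance=f"top {n_top} RAC-vs-rest markers by log2FC",
    )


def differential_mean_vectors(
    matrices: Mapping[str, tuple[ExpressionMatrix, Sequence[int]]],
    rac_table: pd.DataFrame,
    shared_genes: Sequence[str],
) -> pd.DataFrame:
    """Differential mean expression of each RAC versus the rest of its line.

    Parameters
    ----------
    matrices
        cell_line -> (normalized ExpressionMatrix, per-cell cluster labels).
    rac_table
        Output of :func:`identify_racs`; only rows with ``is_rac`` are used.
    shared_genes
        Gene list shared across lines (the per-line HVG intersection).

    Returns
    -------
    DataFrame indexed by "line:cluster" with one column per shared gene.
    """
    shared = list(shared_genes)
    if not shared:
        raise ValueError("empty shared gene list")
    racs = rac_table[rac_table["is_rac"]]
    rows, index = [], []
    for _, rec in racs.sort_values(["cell_line", "cluster_id"]).iterrows():
        line, cl = rec["cell_line"], rec["cluster_id"]
        if line not in matrices:
            raise ValueError(f"no matrix supplied for cell line {line!r}")
        m, labels = matrices[line]
        labels = np.asarray(labels)
        missing = [g for g in shared if g not in set(m.gene_ids)]
        if missing:
            raise ValueError(
                f"shared genes absent from line {line!r}: {missing[:5]}..."
            )
        idx = m.gene_index(shared)
        norm = m.require_normalized()[idx, :]
        in_cl = labels == cl
        rows.append(norm[:, in_cl].mean(axis=1) - norm[:, ~in_cl].mean(axis=1))
        index.append(f"{line}:{cl}")
    return pd.DataFrame(rows, index=index, columns=shared)


def _newick_from_linkage(link: np.ndarray, leaf_names: list[str]) -> str:
    tree = scipy.cluster.hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return rec(tree) + ";"


def supercluster_racs(
    vectors: pd.DataFrame,
    min_lines: int = 2,
    corr_threshold: float = 0.4,
    linkage: str = "average",
) -> tuple[list[Supercluster], list[tuple[str, int]], str]:
    """Group RACs into superclusters by Spearman similarity.

    Pairwise distance is ``1 - Spearman correlation`` of the differential
    mean vectors; the average-linkage tree is cut at height
    ``1 - corr_threshold``. Groups spanning at least ``min_lines`` cell
    lines become superclusters; the rest are reported unassigned.

    Returns ``(superclusters, unassigned_members, newick_dendrogram)``.
    """
    # canonical row order makes the output invariant to input order
    vectors = vectors.sort_index()
    members = [
        (idx.split(":", 1)[0], int(idx.split(":", 1)[1])) for idx in vectors.index
    ]
    if len(vectors) < 2:
        raise ValueError("need at least two RACs to group")
    if len({line for line, _ in members}) < 2:
        raise ValueError("need RACs from at least two cell lines")
    values = vectors.to_numpy(dtype=float)
    const = values.std(axis=1) == 0
    if const.any():
        bad = vectors.index[const].tolist()
        raise ValueError(f"constant differential vector(s): {bad}; Spearman undefined")
    corr = scipy.stats.spearmanr(values, axis=1).statistic
    corr = np.atleast_2d(corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    link = scipy.cluster.hierarchy.linkage(condensed, method=linkage)
    labels = scipy.cluster.hierarchy.fcluster(
        link, t=1.0 - corr_threshold, criterion="distance"
    )
    newick = _newick_from_linkage(link, list(vectors.index))

    superclusters: list[Supercluster] = []
    unassigned: list[tuple[str, int]] = []
    next_id = 1
    for lab in sorted(set(labels)):
        group = [members[i] for i in range(len(members)) if labels[i] == lab]
        if len({line for line, _ in group}) >= min_lines:
            superclusters.append(Supercluster(id=next_id, members=group))
            next_id += 1
        else:
            unassigned.extend(group)
    return superclusters, unassigned, newick


def consensus_supercluster_signature(
    member_marker_tables: Iterable[pd.DataFrame],
    direction: str = "up",
    alpha: float = 0.05,
    name: str | None = None,
    **kwargs,
) -> GeneSignature:
    """RRA consensus signature over the member RACs' marker tables."""
    tables = list(member_marker_tables)
    if len(tables) < 2:
        raise ValueError("need marker tables from at least two member RACs")
    return build_consensus_signature(
        tables, direction=direction, alpha=alpha, name=name, **kwargs
    )


def assign_cell_cycle(
    m: ExpressionMatrix,
    phase_signatures: Mapping[str, GeneSignature],
    n_controls: int = 100,
    n_bins: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-cycle phase per cell from module scores.

    With all four of G0/G1/S/G2M supplied, each cell takes the argmax
    phase (ties resolved in the fixed order G0 < G1 < S < G2M). Without an
    explicit G1 signature, a cell is called G1 when all of its G0/S/G2M
    scores are <= 0, otherwise argmax of the three.
    """
    has_g1 = "G1" in phase_signatures
    needed = [p for p in PHASE_ORDER if has_g1 or p != "G1"]
    missing = [p for p in needed if p not in phase_signatures]
    if missing:
        raise ValueError(f"missing phase signature(s): {missing}")
    scores = {
        phase: module_score(
            m, phase_signatures[phase], n_sets=n_controls, n_bins=n_bins, seed=seed
        )
        for phase in needed
    }
    score_mat = np.vstack([scores[p] for p in needed])  # phases x cells
    # argmax returns the first maximum, so ordering rows by PHASE_ORDER
    # implements the documented tie rule
    best = np.argmax(score_mat, axis=0)
    phases = np.array(needed, dtype=object)[best]
    if not has_g1:
        all_nonpos = (score_mat <= 0).all(axis=0)
        phases = np.where(all_nonpos, "G1", phases)
    out = pd.DataFrame({"cell_id": m.cell_ids, "phase": phases})
    for p in needed:
        out[f"score_{p}"] = scores[p]
    return out


def drug_class_enrichment(
    meta: pd.DataFrame,
    member_clusters: Iterable[tuple[str, int]],
    drug_class: str,
    cluster_col: str = "cluster_id",
) -> dict:
    """Over-representation of one drug class inside a supercluster.

    2x2 table of (class vs other class) x (inside vs outside the
    supercluster's component clusters) over treated cells; sample odds
    ratio, two-sided Fisher p, and fold enrichment relative to the random
    expectation.
    """
    treated = meta[meta["drug_class"].notna() & (meta["treatment"] != "vehicle")]
    if drug_class not in set(treated["drug_class"]):
        raise ValueError(f"drug class {drug_class!r} absent from metadata")
    member_set = set(member_clusters)
    in_sc = treated.apply(
        lambda r: (r["cell_line"], r[cluster_col]) in member_set, axis=1
    ).to_numpy()
    is_class = (treated["drug_class"] == drug_class).to_numpy()
    a = int((is_class & in_sc).sum())
    b = int((~is_class & in_sc).sum())
    c = int((is_class & ~in_sc).sum())
    d = int((~is_class & ~in_sc).sum())
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    frac_in = a / max(a + b, 1)
    frac_all = (a + c) / len(treated)
    return {
        "drug_class": drug_class,
        "odds_ratio": sample_odds_ratio(a, b, c, d),
        "p": float(p),
        "fold_enrichment": frac_in / frac_all if frac_all > 0 else np.nan,
        "n_class_in": a,
        "n_other_in": b,
        "n_class_out": c,
        "n_other_out": d,
    }
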