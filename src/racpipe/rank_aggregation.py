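"""Marker detection and robust rank aggregation (RRA).

RRA scores each gene by the minimum over order statistics j of
``BetaCDF(r_(j); j, k - j + 1)`` where ``r_(1) <= ... <= r_(m)`` are the
gene's normalized ranks across ``k`` input lists. Under the null of
uniformly random ranks this rho is a p-value-like score; multiplying by
``k`` (Bonferroni over the minimum) gives the rank p-value, which is then
adjusted across genes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "find_markers",
    "rra_rho",
    "rra_aggregate",
    "build_consensus_signature",
]


def find_markers(
    m: ExpressionMatrix,
    labels: Sequence,
    group,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of ``group`` versus all other cells.

    Per gene: two-sided rank-sum p-value on the normalized layer,
    Bonferroni-adjusted over tested genes, and a log2 fold change computed
    on de-logged means with a pseudocount of 1 on each side.
    """
    labels = np.asarray(labels)
    if labels.size != m.n_cells:
        raise ValueError("labels length must equal the number of cells")
    in_group = labels == group
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError(
            f"degenerate group sizes for marker test: {n1} vs {n2} (need >= 3 each)"
        )
    norm = m.require_normalized()
    x = norm[:, in_group]
    y = norm[:, ~in_group]
    res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p_adj = np.minimum(p * m.n_genes, 1.0)
    expr = np.expm1(norm)
    mean_in = expr[:, in_group].mean(axis=1)
    mean_out = expr[:, ~in_group].mean(axis=1)
    log2_fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2_fc": log2_fc,
            "p": p,
            "p_adj": p_adj,
            "group": str(group),
        }
    )


def rra_rho(normalized_ranks: Sequence[float], k_lists: int) -> float:
    """Beta order-statistic rho for one gene.

    Parameters
    ----------
    normalized_ranks
        The gene's normalized ranks, each in (0, 1], from the lists where
        it appears (at most ``k_lists`` of them).
    k_lists
        Number of lists the order statistics are taken over.
    """
    r = np.asarray(normalized_ranks, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank vector")
    if r.size > k_lists:
        raise ValueError("more ranks than lists")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    r = np.sort(r)
    j = np.arange(1, r.size + 1)
    cdfs = scipy.stats.beta.cdf(r, j, k_lists - j + 1)
    return float(cdfs.min())


def _normalized_rank_map(ranked_genes: Sequence[str], universe_size: int) -> dict:
    return {
        g: (i + 1) / universe_size for i, g in enumerate(ranked_genes)
    }


def rra_aggregate(
    lists: Iterable[Sequence[str] | GeneSignature],
    missing: str = "worst",
    adjust: str = "bh",
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Aggregate ranked gene lists into a consensus ranking.

    Parameters
    ----------
    lists
        Two or more ranked gene lists, best gene first.
    missing
        How genes absent from a list are treated. ``"worst"`` (default)
        assigns them the worst normalized rank 1.0, matching the published
        RRA behaviour for top-k lists; ``"ignore"`` computes rho only over
        the lists containing the gene, with k equal to that count.
    adjust
        Across-gene adjustment of the rank p-value: ``"bh"`` (default) or
        ``"bonferroni"``.
    universe_size
        Size of the underlying gene universe the lists were selected
        from. When the lists are top-k selections (e.g. the significant
        head of a genome-wide test), pass the number of genes tested;
        the default (the union of the lists) treats the lists as
        complete rankings.

    Returns
    -------
    DataFrame with columns gene, rho, p_rank, p_rank_adj, n_lists_present,
    sorted ascending by rho (ties by gene symbol).
    """
    if missing not in ("worst", "ignore"):
        raise ValueError("missing must be 'worst' or 'ignore'")
    if adjust not in ("bh", "bonferroni"):
        raise ValueError("adjust must be 'bh' or 'bonferroni'")
    ranked_lists: list[list[str]] = []
    for lst in lists:
        genes = list(lst.genes) if isinstance(lst, GeneSignature) else list(lst)
        if not genes:
            raise ValueError("empty input list")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes within a ranked list")
        ranked_lists.append(genes)
    k = len(ranked_lists)
    if k < 2:
        raise ValueError("need at least two ranked lists")
    universe = sorted(set().union(*ranked_lists))
    n_uni = len(universe) if universe_size is None else int(universe_size)
    if n_uni < max(len(lst) for lst in ranked_lists):
        raise ValueError("universe_size smaller than the longest list")
    rank_maps = [_normalized_rank_map(lst, n_uni) for lst in ranked_lists]

    rows = []
    for gene in universe:
        present = [rm[gene] for rm in rank_maps if gene in rm]
        n_present = len(present)
        if missing == "worst":
            ranks = present + [1.0] * (k - n_present)
            rho = rra_rho(ranks, k)
            k_eff = k
        else:
            rho = rra_rho(present, n_present)
            k_eff = n_present
        rows.append((gene, rho, min(1.0, rho * k_eff), n_present))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p_rank", "n_lists_present"])
    if adjust == "bh":
        out["p_rank_adj"] = scipy.stats.false_discovery_control(
            out["p_rank"].to_numpy(), method="bh"
        )
    else:
        out["p_rank_adj"] = np.minimum(out["p_rank"] * len(out), 1.0)
    out = out.sort_values(["rho", "gene"], kind="stable").reset_index(drop=True)
    return out[["gene", "rho", "p_rank", "p_rank_adj", "n_lists_present"]]


def _ranked_list_from_markers(
    table: pd.DataFrame, direction: str, sig_alpha: float
) -> list[str]:
    if direction == "up":
        sel = table[(table["log2_fc"] > 0) & (table["p_adj"] < sig_alpha)]
    else:
        sel = table[(table["log2_fc"] < 0) & (table["p_adj"] < sig_alpha)]
    sel = sel.assign(absfc=sel["log2_fc"].abs())
    sel = sel.sort_values(["absfc", "gene"], ascending=[False, True], kind="stable")
    return sel["gene"].tolist()


def build_consensus_signature(
    marker_tables: Iterable[pd.DataFrame],
    direction: str = "up",
    alpha: float = 0.05,
    sig_alpha: float = 0.05,
    name: str | None = None,
    missing: str = "worst",
    adjust: str = "bh",
    select_on: str = "p_rank",
    min_lists: int = 2,
) -> GeneSignature:
    """Consensus signature by RRA over direction-filtered marker lists.

    Each marker table is filtered to significant genes of the requested
    sign (``p_adj < sig_alpha``), ranked by absolute log2 fold change, and
    the lists are aggregated with the number of tested genes as the rank
    universe; genes whose adjusted rank p-value falls below ``alpha``
    and that appear in at least ``min_lists`` input lists form the
    signature, ordered by rho. The corroboration requirement exists
    because a gene ranked near the top of a single list can reach a
    small rho without any cross-list support.

    ``select_on`` decides what "adjusted rank p-value" means:
    ``"p_rank"`` (default) thresholds the Bonferroni-corrected rho
    (``min(1, rho * k)``), the published RRA tool's corrected score;
    ``"p_rank_adj"`` additionally applies the across-gene adjustment.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if select_on not in ("p_rank", "p_rank_adj"):
        raise ValueError("select_on must be 'p_rank' or 'p_rank_adj'")
    # order-invariance: aggregate over a canonical ordering of the lists
    lists = []
    n_tested = 0
    for i, table in enumerate(marker_tables):
        n_tested = max(n_tested, len(table))
        ranked = _ranked_list_from_markers(table, direction, sig_alpha)
        if not ranked:
            warnings.warn(
                f"marker table {i} has no qualifying {direction} genes; dropped"
            )
            continue
        lists.append(ranked)
    if len(lists) < 2:
        raise ValueError("fewer than two marker tables with qualifying genes")
    lists = sorted(lists, key=lambda lst: tuple(lst))
    agg = rra_aggregate(
        lists, missing=missing, adjust=adjust, universe_size=n_tested
    )
    hits = agg[(agg[select_on] < alpha) & (agg["n_lists_present"] >= min_lists)]
    return GeneSignature(
        name=name or f"consensus_{direction}",
        genes=hits["gene"].tolist(),
        direction=direction,
        scores=dict(zip(hits["gene"], hits["rho"])),
        provenance=f"RRA consensus of {len(lists)} marker lists (alpha={alpha})",
    )
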