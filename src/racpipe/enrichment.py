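"""Hypergeometric over-representation analysis of gene signatures.

The test asks, for each term in a GMT collection, whether the query
signature overlaps it more than expected when drawing ``|query|`` genes
uniformly from the universe: ``p = P(X >= overlap)`` with
``X ~ Hypergeometric(universe, |term|, |query|)``, BH-adjusted across the
tested terms. Overlap counts and overlapping genes are reported alongside.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSignature

__all__ = ["overrepresentation_test", "conserved_overlap"]


def overrepresentation_test(
    query: GeneSignature | Sequence[str],
    terms: Iterable[GeneSignature],
    universe: Sequence[str],
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``query`` in each term.

    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe and filtered to
    ``[min_term_size, max_term_size]`` genes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q_genes = list(query.genes) if isinstance(query, GeneSignature) else list(query)
    if not q_genes:
        raise ValueError("empty query signature")
    q_in = [g for g in q_genes if g in uni]
    if len(q_in) < len(q_genes):
        warnings.warn(
            f"{len(q_genes) - len(q_in)} query gene(s) outside the universe dropped"
        )
    if not q_in:
        raise ValueError("query has no genes in the universe")
    q_set = set(q_in)
    n_uni, n_query = len(uni), len(q_set)

    rows = []
    for term in terms:
        t_genes = sorted(set(term.genes) & uni)
        if not min_term_size <= len(t_genes) <= max_term_size:
            continue
        overlap = sorted(q_set & set(t_genes))
        k = len(overlap)
        # P(X >= k); sf(k-1) is exact for the discrete upper tail
        p = float(scipy.stats.hypergeom.sf(k - 1, n_uni, len(t_genes), n_query))
        rows.append(
            {
                "term": term.name,
                "term_size": len(t_genes),
                "overlap_count": k,
                "overlap_genes": ",".join(overlap),
                "p": p,
                "universe_size": n_uni,
                "query_size": n_query,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "term_size",
            "overlap_count",
            "overlap_genes",
            "p",
            "universe_size",
            "query_size",
        ],
    )
    if not out.empty:
        out["p_adj"] = scipy.stats.false_discovery_control(
            out["p"].to_numpy(), method="bh"
        )
        out = out.sort_values(["p_adj", "p", "term"], kind="stable").reset_index(
            drop=True
        )
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def conserved_overlap(
    sig_a: GeneSignature | Sequence[str], sig_b: GeneSignature | Sequence[str]
) -> list[str]:
    """Sorted intersection of two signatures (input for ORA of conserved genes)."""
    a = set(sig_a.genes) if isinstance(sig_a, GeneSignature) else set(sig_a)
    b = set(sig_b.genes) if isinstance(sig_b, GeneSignature) else set(sig_b)
    if not a or not b:
        raise ValueError("both signatures must be non-empty")
    return sorted(a & b)
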