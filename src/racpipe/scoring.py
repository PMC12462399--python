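"""Gene-set activity scoring.

Implements the recovery-AUC statistic (area under the curve of cumulative
signature genes recovered within the top fraction of a cell's
expression-ranked genes), expression-matched control gene sets and the
activation threshold derived from their pooled score distribution,
average-based module scores, single-sample GSEA, and preranked GSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "ControlSetBundle",
    "rank_genes_per_cell",
    "recovery_auc",
    "recovery_auc_matrix",
    "build_control_sets",
    "activation_threshold",
    "score_cells",
    "module_score",
    "ssgsea",
    "preranked_gsea",
]


# ---------------------------------------------------------------------------
# recovery-AUC (AUCell-style)
# ---------------------------------------------------------------------------

def rank_genes_per_cell(
    m: ExpressionMatrix, tie_break: str = "random", seed: int = 0
) -> np.ndarray:
    """Gene order (indices, highest expression first) per cell.

    ``tie_break="random"`` shuffles genes with a per-cell seeded RNG before
    a stable sort, so ties resolve randomly but reproducibly;
    ``"symbol"`` resolves ties by gene symbol instead.
    """
    norm = m.require_normalized()
    n_genes, n_cells = norm.shape
    orders = np.empty((n_cells, n_genes), dtype=np.int64)
    if tie_break == "symbol":
        sym_order = np.argsort(m.gene_ids, kind="stable")
        for c in range(n_cells):
            vals = norm[sym_order, c]
            orders[c] = sym_order[np.argsort(-vals, kind="stable")]
    elif tie_break == "random":
        for c in range(n_cells):
            rng = np.random.default_rng([seed, c])
            perm = rng.permutation(n_genes)
            vals = norm[perm, c]
            orders[c] = perm[np.argsort(-vals, kind="stable")]
    else:
        raise ValueError("tie_break must be 'random' or 'symbol'")
    return orders


def _max_rank(n_genes: int, max_rank_fraction: float) -> int:
    if not 0 < max_rank_fraction <= 1:
        raise ValueError("max_rank_fraction must be in (0, 1]")
    return max(1, int(np.floor(max_rank_fraction * n_genes)))


def recovery_auc(
    cell_ranking: Sequence[str],
    signature: GeneSignature | Sequence[str],
    max_rank_fraction: float = 0.05,
) -> float:
    """Normalized area under the signature-recovery step curve.

    ``cell_ranking`` is the full gene universe ordered by decreasing
    expression. The step curve counts signature genes recovered within the
    top ``M = floor(max_rank_fraction * n_genes)`` positions; the area is
    normalized so the best attainable arrangement scores 1.
    """
    genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    ranking = list(cell_ranking)
    sig = set(genes) & set(ranking)
    if not sig:
        raise ValueError("signature does not intersect the ranked universe")
    m_top = _max_rank(len(ranking), max_rank_fraction)
    hits = np.fromiter((g in sig for g in ranking[:m_top]), dtype=bool, count=m_top)
    area = int(np.cumsum(hits).sum())
    return area / _max_area(len(sig), m_top)


def _max_area(sig_size: int, m_top: int) -> float:
    s = min(sig_size, m_top)
    return s * (s + 1) / 2 + s * (m_top - s)


def recovery_auc_matrix(
    orders: np.ndarray,
    set_masks: np.ndarray,
    max_rank_fraction: float = 0.05,
) -> np.ndarray:
    """Vectorized recovery-AUC for many gene sets over many cells.

    Parameters
    ----------
    orders
        (n_cells, n_genes) gene indices from :func:`rank_genes_per_cell`.
    set_masks
        (n_sets, n_genes) boolean membership matrix.

    Returns
    -------
    (n_sets, n_cells) array of scores.
    """
    n_cells, n_genes = orders.shape
    m_top = _max_rank(n_genes, max_rank_fraction)
    top = orders[:, :m_top]  # (cells, M)
    # hits[s, c, x] = set s contains the gene at rank x of cell c
    hits = set_masks[:, top]  # (sets, cells, M)
    areas = np.cumsum(hits, axis=2).sum(axis=2)
    sizes = set_masks.sum(axis=1)
    if (sizes == 0).any():
        raise ValueError("empty gene set in membership matrix")
    max_areas = np.array([_max_area(int(s), m_top) for s in sizes])
    return areas / max_areas[:, None]


# ---------------------------------------------------------------------------
# expression-matched control sets and the activation threshold
# ---------------------------------------------------------------------------

@dataclass
class ControlSetBundle:
    """Expression-matched control gene sets for one signature.

    Each control set replicates the signature's per-expression-bin gene
    counts, sampling non-signature genes from the same bins.
    """

    signature_name: str
    signature_genes: list[str]
    control_sets: list[list[str]]
    bin_assignments: pd.Series  # gene -> bin id
    n_bins: int
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.control_sets)


def build_control_sets(
    m: ExpressionMatrix,
    signature: GeneSignature,
    n_sets: int = 100,
    n_bins: int = 24,
    seed: int = 0,
) -> ControlSetBundle:
    """Sample ``n_sets`` control gene sets matched on mean expression.

    Genes are placed into ``n_bins`` quantile bins of mean normalized
    expression; each control set draws, per bin, as many non-signature
    genes as the signature has in that bin (without replacement when the
    bin allows it).
    """
    means = m.mean_normalized()
    present = [g for g in signature.genes if g in set(m.gene_ids)]
    dropped = len(signature.genes) - len(present)
    if dropped:
        warnings.warn(
            f"{dropped} signature gene(s) absent from the matrix were dropped"
        )
    if not present:
        raise ValueError("no signature genes present in the matrix")
    n_bins_eff = min(n_bins, m.n_genes)
    bins = pd.qcut(
        pd.Series(means, index=m.gene_ids).rank(method="first"),
        n_bins_eff,
        labels=False,
    )
    sig_set = set(present)
    rng = np.random.default_rng(seed)
    by_bin_pool: dict[int, np.ndarray] = {}
    sig_bin_counts = bins.loc[present].value_counts().to_dict()
    for b in sig_bin_counts:
        pool = bins.index[(bins == b) & (~bins.index.isin(sig_set))].to_numpy()
        by_bin_pool[b] = pool
    all_pool = np.asarray([g for g in m.gene_ids if g not in sig_set], dtype=object)
    if all_pool.size == 0:
        raise ValueError("no non-signature genes available for control sets")
    control_sets: list[list[str]] = []
    warned = False
    for _ in range(n_sets):
        chosen: list[str] = []
        for b, need in sorted(sig_bin_counts.items()):
            pool = by_bin_pool[b]
            if len(pool) >= need:
                chosen.extend(rng.choice(pool, size=need, replace=False))
            else:
                if not warned:
                    warnings.warn(
                        f"bin {b} has only {len(pool)} non-signature genes for "
                        f"{need} needed; sampling with replacement"
                    )
                    warned = True
                # degenerate bin: fall back to the global pool if empty
                src = pool if len(pool) else all_pool
                chosen.extend(rng.choice(src, size=need, replace=True))
        control_sets.append(chosen)
    return ControlSetBundle(
        signature_name=signature.name,
        signature_genes=present,
        control_sets=control_sets,
        bin_assignments=bins,
        n_bins=n_bins_eff,
        seed=seed,
    )


def activation_threshold(background_scores: Sequence[float], q: float = 0.95) -> float:
    """Empirical ``q``-quantile of the pooled control-score background."""
    scores = np.asarray(background_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty background score distribution")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(scores, q))


def _set_mask(genes: Sequence[str], gene_ids: np.ndarray) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros(gene_ids.size, dtype=bool)
    for g in genes:
        if g in lookup:
            mask[lookup[g]] = True
    return mask


def score_cells(
    m: ExpressionMatrix,
    signature: GeneSignature,
    n_controls: int = 100,
    q: float = 0.95,
    max_rank_fraction: float = 0.05,
    n_bins: int = 24,
    seed: int = 0,
    tie_break: str = "random",
    per_cell_background: bool = False,
    orders: np.ndarray | None = None,
) -> pd.DataFrame:
    """Recovery-AUC per cell with a matched-control activation threshold.

    The background pools recovery-AUC scores of ``n_controls``
    expression-matched control sets over all cells (or per cell when
    ``per_cell_background``); a cell is active when its signature score
    exceeds the ``q`` background quantile.

    Returns a ScoreTable frame: cell_id, signature, score, threshold,
    active.
    """
    if orders is None:
        orders = rank_genes_per_cell(m, tie_break=tie_break, seed=seed)
    bundle = build_control_sets(m, signature, n_sets=n_controls, n_bins=n_bins, seed=seed)
    masks = np.vstack(
        [_set_mask(bundle.signature_genes, m.gene_ids)]
        + [_set_mask(cs, m.gene_ids) for cs in bundle.control_sets]
    )
    scores = recovery_auc_matrix(orders, masks, max_rank_fraction=max_rank_fraction)
    sig_scores = scores[0]
    background = scores[1:]
    if per_cell_background:
        thr = np.quantile(background, q, axis=0)
    else:
        thr = np.full(m.n_cells, activation_threshold(background.ravel(), q))
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "signature": signature.name,
            "score": sig_scores,
            "threshold": thr,
            "active": sig_scores > thr,
        }
    )


def module_score(
    m: ExpressionMatrix,
    signature: GeneSignature,
    controls: ControlSetBundle | None = None,
    n_sets: int = 100,
    n_bins: int = 24,
    seed: int = 0,
) -> np.ndarray:
    """Average-based module score per cell.

    Mean normalized expression of the signature genes minus the mean over
    control sets of each set's mean expression.
    """
    if controls is None:
        controls = build_control_sets(m, signature, n_sets=n_sets, n_bins=n_bins, seed=seed)
    norm = m.require_normalized()
    sig_idx = m.gene_index(controls.signature_genes)
    sig_mean = norm[sig_idx, :].mean(axis=0)
    ctrl_means = np.vstack(
        [norm[m.gene_index(cs), :].mean(axis=0) for cs in controls.control_sets]
    )
    return sig_mean - ctrl_means.mean(axis=0)


# ---------------------------------------------------------------------------
# single-sample GSEA and preranked GSEA
# ---------------------------------------------------------------------------

def ssgsea(
    sample_expression: Mapping[str, float] | pd.Series,
    gene_set: GeneSignature | Sequence[str],
    alpha: float = 0.75,
) -> float:
    """Single-sample enrichment score.

    Genes are ordered by decreasing expression (ties by symbol, with a
    warning); the in-set cumulative distribution weights gene ranks by
    ``rank ** alpha`` while the out-of-set one is uniform. The score is
    the mean running-sum difference over gene positions.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    expr = pd.Series(sample_expression, dtype=float)
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSignature) else list(gene_set)
    in_set = expr.index.isin(set(genes))
    if not in_set.any():
        raise ValueError("gene set does not intersect the expression universe")
    if expr.nunique() == 1:
        raise ValueError("constant expression vector: ranks undefined")
    if expr.duplicated().any() and expr.nunique() < len(expr):
        warnings.warn("ties in expression resolved by gene symbol order")
    order = expr.to_frame("v").assign(gene=expr.index.astype(str))
    order = order.sort_values(["v", "gene"], ascending=[False, True], kind="stable")
    n = len(order)
    in_mask = order["gene"].isin(set(genes)).to_numpy()
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank n
    w = np.where(in_mask, ranks**alpha, 0.0)
    denom_in = w.sum()
    p_in = np.cumsum(w) / denom_in
    n_out = n - in_mask.sum()
    if n_out == 0:
        raise ValueError("gene set covers the whole universe")
    p_out = np.cumsum(~in_mask) / n_out
    return float((p_in - p_out).sum() / n)


def preranked_gsea(
    ranked_stats: Mapping[str, float] | pd.Series,
    gene_set: GeneSignature | Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float, float]:
    """Classic preranked GSEA with a gene-label permutation null.

    Returns ``(ES, NES, p)``: the weighted Kolmogorov–Smirnov enrichment
    score, its normalization by the mean absolute same-sign null score,
    and a permutation p-value with +1 continuity on the absolute score.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats = pd.Series(ranked_stats, dtype=float)
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSignature) else list(gene_set)
    order = stats.to_frame("v").assign(gene=stats.index.astype(str))
    order = order.sort_values(["v", "gene"], ascending=[False, True], kind="stable")
    in_mask = order["gene"].isin(set(genes)).to_numpy()
    n_in = int(in_mask.sum())
    if n_in < 2:
        raise ValueError("gene set smaller than 2 after intersection with ranking")
    vals = np.abs(order["v"].to_numpy()) ** weight

    def es_for(mask: np.ndarray) -> float:
        w_in = np.where(mask, vals, 0.0)
        denom = w_in.sum()
        if denom == 0:
            p_hit = np.cumsum(mask) / mask.sum()
        else:
            p_hit = np.cumsum(w_in) / denom
        p_miss = np.cumsum(~mask) / (mask.size - mask.sum())
        dev = p_hit - p_miss
        return float(dev[np.argmax(np.abs(dev))])

    es = es_for(in_mask)
    rng = np.random.default_rng(seed)
    n = len(order)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_in, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null_es[i] = es_for(mask)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_es).mean()
    nes = es / denom if denom > 0 else 0.0
    p = (1 + int((np.abs(null_es) >= abs(es)).sum())) / (1 + n_perm)
    return es, float(nes), float(p)
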