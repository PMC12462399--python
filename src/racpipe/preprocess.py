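"""Quality control, normalization, variable-gene selection and clustering.

The filtering order is fixed: cells first (detected-feature bounds), then
genes (minimum cell count). Feature bounds are inclusive. Normalization is
``log(1 + count / cell_total * scale_factor)`` with the natural log and a
default scale factor of 10,000.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "qc_filter_cells",
    "filter_genes",
    "normalize",
    "select_hvg",
    "cluster_cells",
]


def qc_filter_cells(
    m: ExpressionMatrix, min_features: int = 200, max_features: int = 2500
) -> ExpressionMatrix:
    """Keep cells whose detected-feature count lies in [min, max] inclusive."""
    if min_features >= max_features:
        raise ValueError("min_features must be < max_features")
    detected = m.detected_features()
    keep = (detected >= min_features) & (detected <= max_features)
    if not keep.any():
        raise ValueError("no cells pass QC with the given feature bounds")
    return m.subset_cells(keep)


def filter_genes(m: ExpressionMatrix, min_cells: int = 100) -> ExpressionMatrix:
    """Keep genes with count > 0 in at least ``min_cells`` cells."""
    if min_cells > m.n_cells:
        raise ValueError(
            f"min_cells={min_cells} exceeds the number of cells ({m.n_cells})"
        )
    keep = (m.counts > 0).sum(axis=1) >= min_cells
    if not keep.any():
        raise ValueError("no genes pass the min_cells filter")
    return m.subset_genes(keep)


def normalize(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size scale to ``scale_factor`` and log1p (natural log)."""
    totals = m.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][:5]
        raise ValueError(f"cells with zero total counts: {list(bad)}")
    norm = np.log1p(m.counts / totals[None, :] * scale_factor)
    return ExpressionMatrix(
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        counts=m.counts,
        normalized=norm,
    )


def select_hvg(m: ExpressionMatrix, n_top: int = 2000, n_bins: int = 20) -> list[str]:
    """Top ``n_top`` highly variable genes.

    Dispersion of the de-logged normalized layer (variance/mean) is
    z-scored within quantile bins of mean expression, which removes the
    mean-variance trend. Ties break by gene symbol so the ranking is
    deterministic.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > m.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    expr = np.expm1(m.require_normalized())
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    logdisp = np.log1p(disp)
    df = pd.DataFrame({"gene": m.gene_ids, "mean": mean, "logdisp": logdisp})
    n_bins = min(n_bins, max(1, m.n_genes // 2))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), n_bins, labels=False)
    grouped = df.groupby("bin")["logdisp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std").fillna(0.0)
    df["norm_disp"] = np.where(sd > 0, (df["logdisp"] - mu) / sd, 0.0)
    df = df.sort_values(["norm_disp", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(n_top).tolist()


def cluster_cells(
    m: ExpressionMatrix,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Graph-based clustering of cells.

    PCA on the normalized layer, a symmetrized k-nearest-neighbor graph,
    then Leiden community detection (RB configuration modularity) at the
    given resolution. Reproducible for a fixed seed.

    Returns
    -------
    ndarray of int cluster labels, one per cell.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    if m.n_cells <= n_neighbors:
        raise ValueError("need more cells than n_neighbors")
    x = m.require_normalized().T  # cells x genes
    n_comp = min(n_pcs, min(x.shape) - 1)
    if n_comp >= 1:
        x = PCA(n_components=n_comp, random_state=seed, svd_solver="full").fit_transform(x)
    adj = kneighbors_graph(x, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=m.n_cells, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)
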