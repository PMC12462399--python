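"""Core in-memory containers shared across the pipeline.

The pipeline works on dense genes x cells matrices at desk scale. The raw
layer (``counts``) is integer UMI-like counts; the ``normalized`` layer is
filled by :func:`racpipe.preprocess.normalize` and holds
``log(1 + count / cell_total * scale_factor)`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneSignature", "META_COLUMNS"]

#: required columns of a per-cell metadata table
META_COLUMNS = ("cell_id", "cell_line", "treatment", "drug_class", "timepoint")


def _as_str_array(values: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    if arr.size == 0:
        raise ValueError(f"{what}: empty identifier list")
    if any(not isinstance(v, str) or not v for v in arr):
        raise ValueError(f"{what}: identifiers must be non-empty strings")
    if len(set(arr)) != arr.size:
        raise ValueError(f"{what}: duplicate identifiers")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x cells expression container.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    cell_ids
        Unique cell barcodes, one per matrix column.
    counts
        Non-negative integer matrix of shape ``(n_genes, n_cells)``.
    normalized
        Optional log-normalized layer of the same shape; present only
        after :func:`racpipe.preprocess.normalize`.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        counts = np.asarray(self.counts)
        if counts.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({self.gene_ids.size} genes, {self.cell_ids.size} cells)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if self.normalized is not None:
            norm = np.asarray(self.normalized, dtype=float)
            if norm.shape != counts.shape:
                raise ValueError("normalized layer shape mismatch")
            if (norm < 0).any():
                raise ValueError("normalized layer must be non-negative")
            self.normalized = norm

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def detected_features(self) -> np.ndarray:
        """Number of genes with count > 0, per cell."""
        return (self.counts > 0).sum(axis=0)

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer missing; run normalize() first")
        return self.normalized

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes`` that are present, in the given order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids.copy(),
            counts=self.counts[mask, :],
            normalized=None if self.normalized is None else self.normalized[mask, :],
        )

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[mask],
            counts=self.counts[:, mask],
            normalized=None if self.normalized is None else self.normalized[:, mask],
        )

    def mean_normalized(self) -> np.ndarray:
        """Per-gene mean of the normalized layer."""
        return self.require_normalized().mean(axis=1)


@dataclass
class GeneSignature:
    """A named gene list, optionally directional and score-ranked.

    ``genes`` preserve order (best first for ranked signatures).
    """

    name: str
    genes: list[str] = field(default_factory=list)
    direction: str | None = None  # "up", "down" or None
    scores: dict[str, float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature needs a name")
        genes = [str(g) for g in self.genes]
        if any(not g for g in genes):
            raise ValueError("signature genes must be non-empty strings")
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r}: duplicate genes")
        if self.direction not in (None, "up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe: Sequence[str]) -> "GeneSignature":
        """Restrict to genes present in ``universe`` (order preserved)."""
        uni = set(universe)
        kept = [g for g in self.genes if g in uni]
        return replace(self, genes=kept)


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cell metadata table for the required columns."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValueError("metadata contains duplicate cell_id values")
    tp = pd.to_numeric(meta["timepoint"], errors="coerce")
    if (tp.dropna() < 0).any():
        raise ValueError("timepoint must be >= 0")
    return meta
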