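"""Readers and writers for the pipeline's on-disk formats.

Count matrices come in as a 10x-style MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, genes x cells) or as
a dense TSV with gene rows and cell columns. Gene sets travel as GMT
lines, everything tabular as TSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, GeneSignature, validate_cell_meta

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_cell_meta",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "read_crispr_ranking",
]


def read_mtx_triplet(directory: str | os.PathLike) -> ExpressionMatrix:
    """Load a genes x cells MatrixMarket triplet directory."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    counts = np.asarray(scipy.sparse.csr_matrix(mat).todense())
    return ExpressionMatrix(gene_ids=genes, cell_ids=cells, counts=counts)


def write_mtx_triplet(
    m: ExpressionMatrix, directory: str | os.PathLike, layer: str = "counts"
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = m.counts if layer == "counts" else m.require_normalized()
    scipy.io.mmwrite(str(directory / "matrix.mtx"), scipy.sparse.coo_matrix(data))
    pd.Series(m.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    """Dense genes x cells TSV with gene symbols in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=df.index.astype(str).tolist(),
        cell_ids=df.columns.astype(str).tolist(),
        counts=df.to_numpy(),
    )


def write_dense_tsv(
    m: ExpressionMatrix, path: str | os.PathLike, layer: str = "counts"
) -> None:
    data = m.counts if layer == "counts" else m.require_normalized()
    pd.DataFrame(data, index=m.gene_ids, columns=m.cell_ids).to_csv(path, sep="\t")


def read_cell_meta(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return validate_cell_meta(meta)


def read_gmt(path: str | os.PathLike) -> list[GeneSignature]:
    """Parse a GMT file into signatures (name, description, genes...)."""
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            direction = None
            if name.endswith("_up"):
                direction = "up"
            elif name.endswith("_down"):
                direction = "down"
            sigs.append(
                GeneSignature(name=name, genes=genes, direction=direction, provenance=desc)
            )
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.provenance or "."
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def read_ortholog_map(path: str | os.PathLike) -> pd.DataFrame:
    """Two-column TSV mapping source (non-human) genes to human genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (source_gene, human_gene)")
    df = df.iloc[:, :2]
    df.columns = ["source_gene", "human_gene"]
    if df.isna().any().any() or (df == "").any().any():
        raise ValueError("ortholog map contains empty symbols")
    return df


# column names MAGeCK writes in its gene_summary output, tried in order
_MAGECK_RANK_COLUMNS = ("pos|rank", "neg|rank", "rank")
_MAGECK_GENE_COLUMNS = ("id", "gene", "Gene")


def read_crispr_ranking(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CRISPR gene ranking TSV (plain or MAGeCK gene-summary style).

    Returns a frame with columns ``gene`` and ``rank``; ranks are a
    permutation of 1..n.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = next((c for c in _MAGECK_GENE_COLUMNS if c in df.columns), None)
    if gene_col is None:
        gene_col = df.columns[0]
    rank_col = next((c for c in _MAGECK_RANK_COLUMNS if c in df.columns), None)
    if rank_col is None:
        if "score" in df.columns:
            out = pd.DataFrame({"gene": df[gene_col].astype(str), "score": df["score"]})
            out["rank"] = out["score"].rank(method="first").astype(int)
            return _check_ranking(out)
        raise ValueError("no rank or score column found in CRISPR ranking table")
    out = pd.DataFrame(
        {"gene": df[gene_col].astype(str), "rank": df[rank_col].astype(int)}
    )
    if "score" in df.columns:
        out["score"] = df["score"]
    return _check_ranking(out)


def _check_ranking(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene"].duplicated().any():
        raise ValueError("CRISPR ranking contains duplicate genes")
    ranks = np.sort(df["rank"].to_numpy())
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ValueError("CRISPR ranks must be a permutation of 1..n")
    return df
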