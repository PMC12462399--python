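"""Shared fixtures: small expression matrices built in memory."""

import numpy as np
import pytest

from racpipe.containers import ExpressionMatrix, GeneSignature


def make_matrix(counts, gene_ids=None, cell_ids=None, normalized=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i:03d}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i:03d}" for i in range(c)],
        counts=counts,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_matrix(rng):
    """50 genes x 40 cells of Poisson counts, normalized."""
    from racpipe.preprocess import normalize

    counts = rng.poisson(5.0, size=(50, 40))
    counts[0, :] += 1  # guard against all-zero cells
    return normalize(make_matrix(counts))


@pytest.fixture
def signature():
    return GeneSignature(name="sig", genes=[f"g{i:03d}" for i in range(5)], direction="up")
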