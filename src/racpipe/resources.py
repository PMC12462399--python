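"""Bundled default gene lists.

The S and G2M lists are the standard Tirosh-derived cell-cycle sets that
common single-cell toolkits ship. The bundled G0 list is a small
synthetic/representative quiescence marker set standing in for an
external G0 signature; supply your own via ``phase_signatures`` for real
analyses.
"""

from __future__ import annotations

from importlib import resources

from .containers import GeneSignature
from .io import read_gmt

__all__ = ["cell_cycle_signatures"]


def cell_cycle_signatures() -> dict[str, GeneSignature]:
    """Default G0/S/G2M phase signatures keyed by phase name."""
    path = resources.files("racpipe.data") / "cell_cycle.gmt"
    with resources.as_file(path) as p:
        sigs = read_gmt(p)
    return {s.name: s for s in sigs}
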