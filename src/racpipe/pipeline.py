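"""End-to-end orchestration: preprocess -> score -> states, plus the
planted-truth recovery run used for self-validation.

A run is driven by a declarative :class:`RunConfig` (YAML-serializable);
every stage parameter defaults to the pipeline's documented value, the
config is written next to the outputs, and a manifest records a content
hash for every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .containers import ExpressionMatrix, GeneSignature
from .preprocess import cluster_cells, filter_genes, normalize, qc_filter_cells, select_hvg
from .rank_aggregation import find_markers
from .scoring import rank_genes_per_cell, score_cells
from .states import (
    consensus_supercluster_signature,
    differential_mean_vectors,
    drug_class_enrichment,
    identify_racs,
    supercluster_racs,
)

__all__ = ["RunConfig", "run_pipeline", "run_planted_recovery"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    counts_dir: str
    meta_path: str
    signatures_path: str
    out_dir: str
    min_features: int = 200
    max_features: int = 2500
    min_cells: int = 100
    scale_factor: float = 1e4
    n_pcs: int = 50
    n_neighbors: int = 15
    resolution: float = 1.0
    n_controls: int = 100
    q: float = 0.95
    max_rank_fraction: float = 0.05
    n_bins: int = 24
    hvg_top: int = 2000
    corr_threshold: float = 0.4
    min_lines: int = 2
    consensus_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("run config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"counts_dir", "meta_path", "signatures_path", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute preprocess -> score -> states and return the run manifest.

    Pre-flight checks fail before any compute; stage failures raise with
    the failing stage named. All artifacts land under ``cfg.out_dir`` and
    are hashed into ``manifest.json``.
    """
    counts_dir, meta_path = Path(cfg.counts_dir), Path(cfg.meta_path)
    sig_path, out_dir = Path(cfg.signatures_path), Path(cfg.out_dir)
    for p, what in ((counts_dir, "counts_dir"), (meta_path, "meta_path"), (sig_path, "signatures_path")):
        if not p.exists():
            raise FileNotFoundError(f"{what} does not exist: {p}")
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "run_config.yaml")
    signatures = rio.read_gmt(sig_path)
    if not signatures:
        raise ValueError("no signatures in the GMT file")
    meta = rio.read_cell_meta(meta_path)

    artifacts: list[Path] = [out_dir / "run_config.yaml"]
    stages: list[dict] = []

    def _stage(name):
        start = time.time()

        def done():
            stages.append({"stage": name, "seconds": round(time.time() - start, 3)})

        return done

    # ---- preprocess, per cell line -------------------------------------
    done = _stage("preprocess")
    matrices: dict[str, tuple[ExpressionMatrix, np.ndarray]] = {}
    cluster_rows = []
    try:
        m_all = rio.read_mtx_triplet(counts_dir)
        meta = meta.set_index("cell_id").loc[list(m_all.cell_ids)].reset_index()
        for line in pd.unique(meta["cell_line"]):
            mask = (meta["cell_line"] == line).to_numpy()
            m = m_all.subset_cells(mask)
            m = qc_filter_cells(m, cfg.min_features, cfg.max_features)
            m = filter_genes(m, cfg.min_cells)
            m = normalize(m, cfg.scale_factor)
            labels = cluster_cells(
                m, n_pcs=cfg.n_pcs, n_neighbors=cfg.n_neighbors,
                resolution=cfg.resolution, seed=cfg.seed,
            )
            matrices[line] = (m, labels)
            cluster_rows.append(pd.DataFrame({"cell_id": m.cell_ids, "cluster_id": labels}))
    except Exception as err:
        raise RuntimeError(f"stage 'preprocess' failed: {err}") from err
    clusters_df = pd.concat(cluster_rows, ignore_index=True)
    clusters_path = out_dir / "clusters.tsv"
    clusters_df.to_csv(clusters_path, sep="\t", index=False)
    artifacts.append(clusters_path)
    done()

    # ---- scoring -------------------------------------------------------
    done = _stage("score")
    score_frames = []
    try:
        for line, (m, _) in matrices.items():
            orders = rank_genes_per_cell(m, seed=cfg.seed)
            for sig in signatures:
                table = score_cells(
                    m, sig, n_controls=cfg.n_controls, q=cfg.q,
                    max_rank_fraction=cfg.max_rank_fraction, n_bins=cfg.n_bins,
                    seed=cfg.seed, orders=orders,
                )
                table.insert(1, "cell_line", line)
                score_frames.append(table)
    except Exception as err:
        raise RuntimeError(f"stage 'score' failed: {err}") from err
    scores_df = pd.concat(score_frames, ignore_index=True)
    scores_path = out_dir / "scores.tsv"
    scores_df.to_csv(scores_path, sep="\t", index=False)
    artifacts.append(scores_path)
    done()

    # ---- resistance states (first signature drives RAC calling) -------
    done = _stage("states")
    try:
        primary = signatures[0].name
        prim = scores_df[scores_df["signature"] == primary].set_index("cell_id")
        all_flags, all_clusters, all_lines = [], [], []
        for line, (m, labels) in matrices.items():
            flags = prim.loc[list(m.cell_ids), "active"].to_numpy(dtype=bool)
            all_flags.append(flags)
            all_clusters.append(labels)
            all_lines.append(np.full(m.n_cells, line, dtype=object))
        rac_table = identify_racs(
            np.concatenate(all_flags),
            np.concatenate(all_clusters),
            np.concatenate(all_lines),
        )
        rac_path = out_dir / "rac_records.tsv"
        rac_table.to_csv(rac_path, sep="\t", index=False)
        artifacts.append(rac_path)

        result: dict = {"n_racs": int(rac_table["is_rac"].sum())}
        if rac_table["is_rac"].sum() >= 2:
            hvg_sets = [
                set(select_hvg(m, min(cfg.hvg_top, m.n_genes)))
                for m, _ in matrices.values()
            ]
            shared = sorted(set.intersection(*hvg_sets))
            result["n_shared_hvg"] = len(shared)
            vectors = differential_mean_vectors(matrices, rac_table, shared)
            try:
                scs, unassigned, newick = supercluster_racs(
                    vectors, min_lines=cfg.min_lines, corr_threshold=cfg.corr_threshold
                )
            except ValueError:
                scs, unassigned, newick = [], [], ""
            (out_dir / "rac_dendrogram.nwk").write_text(newick + "\n")
            artifacts.append(out_dir / "rac_dendrogram.nwk")
            membership = [
                {"supercluster": sc.id, "cell_line": line, "cluster_id": cl}
                for sc in scs
                for line, cl in sc.members
            ] + [
                {"supercluster": 0, "cell_line": line, "cluster_id": cl}
                for line, cl in unassigned
            ]
            mem_path = out_dir / "superclusters.tsv"
            pd.DataFrame(membership).to_csv(mem_path, sep="\t", index=False)
            artifacts.append(mem_path)
            result["n_superclusters"] = len(scs)

            # consensus signatures per supercluster; markers are member
            # RAC vs non-RAC cells so shared resistance genes are not
            # diluted by the other RACs in the out-group
            rac_clusters_of = {
                line: set(
                    rac_table.loc[
                        (rac_table["cell_line"] == line) & rac_table["is_rac"],
                        "cluster_id",
                    ]
                )
                for line in matrices
            }
            marker_cache: dict[tuple[str, int], pd.DataFrame] = {}
            consensus: list[GeneSignature] = []
            for sc in scs:
                tables = []
                for line, cl in sc.members:
                    if (line, cl) not in marker_cache:
                        m, labels = matrices[line]
                        other_racs = rac_clusters_of[line] - {cl}
                        keep = ~np.isin(labels, list(other_racs))
                        marker_cache[(line, cl)] = find_markers(
                            m.subset_cells(keep),
                            np.where(labels[keep] == cl, "in", "out"),
                            "in",
                        )
                    tables.append(marker_cache[(line, cl)])
                for direction in ("up", "down"):
                    try:
                        consensus.append(
                            consensus_supercluster_signature(
                                tables, direction=direction,
                                alpha=cfg.consensus_alpha,
                                name=f"supercluster{sc.id}_{direction}",
                            )
                        )
                    except ValueError:
                        pass
            if consensus:
                gmt_path = out_dir / "supercluster_signatures.gmt"
                rio.write_gmt(consensus, gmt_path)
                artifacts.append(gmt_path)

            # drug-class enrichment per supercluster
            meta_cl = meta.merge(clusters_df, on="cell_id", how="inner")
            enr_rows = []
            for sc in scs:
                for dc in pd.unique(meta_cl["drug_class"].dropna()):
                    rec = drug_class_enrichment(meta_cl, sc.members, dc)
                    rec["supercluster"] = sc.id
                    enr_rows.append(rec)
            if enr_rows:
                enr_path = out_dir / "drug_class_enrichment.tsv"
                pd.DataFrame(enr_rows).to_csv(enr_path, sep="\t", index=False)
                artifacts.append(enr_path)
    except RuntimeError:
        raise
    except Exception as err:
        raise RuntimeError(f"stage 'states' failed: {err}") from err
    done()

    manifest = {
        "stages": stages,
        "seed": cfg.seed,
        "results": result,
        "artifacts": {str(p.relative_to(out_dir)): _sha256(p) for p in artifacts},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# planted-truth recovery (simulation -> full pipeline -> truth metrics)
# ---------------------------------------------------------------------------

def run_planted_recovery(
    cfg=None,
    seed: int = 0,
    hvg_top: int = 1000,
    n_controls: int = 100,
    q: float = 0.95,
    corr_threshold: float = 0.4,
    use_true_clusters: bool = False,
) -> dict:
    """Simulate the default preset and measure pipeline recovery of truth.

    Runs normalize -> cluster -> score (union-of-programs signature) ->
    RAC calling -> superclusters -> consensus signatures, then compares
    against the planted truth. ``hvg_top=1000`` covers the simulated
    world's structured genes (cluster-identity plus program genes, ~800
    of 2,000) so the per-line HVG intersection is enriched for cross-line
    program genes, as the full-scale top-2,000 rule is for real data.

    Returns a dict of metrics: planted_rac_detection (fraction of planted
    RACs flagged), supercluster_ari, consensus precision/recall per
    supercluster, and the raw tables.
    """
    from sklearn.metrics import adjusted_rand_score

    from .simulate import SimConfig, scoring_signature_from_truth, simulate_cell_lines

    if cfg is None:
        cfg = SimConfig(seed=seed)
    matrices_raw, meta, truth = simulate_cell_lines(cfg)
    signature = scoring_signature_from_truth(truth)

    matrices: dict[str, tuple[ExpressionMatrix, np.ndarray]] = {}
    all_flags, all_clusters, all_lines = [], [], []
    for line, m in matrices_raw.items():
        m = normalize(m)
        truth_labels = meta.loc[meta["cell_line"] == line, "true_cluster"].to_numpy()
        if use_true_clusters:
            labels = truth_labels
        else:
            labels = cluster_cells(m, seed=cfg.seed)
        matrices[line] = (m, labels)
        flags = score_cells(
            m, signature, n_controls=n_controls, q=q, seed=cfg.seed
        )["active"].to_numpy()
        all_flags.append(flags)
        all_clusters.append(labels)
        all_lines.append(np.full(m.n_cells, line, dtype=object))

    rac_table = identify_racs(
        np.concatenate(all_flags), np.concatenate(all_clusters), np.concatenate(all_lines)
    )

    # map detected clusters back to planted clusters (majority vote)
    planted = {
        (line, cl): prog for (line, cl), prog in cfg.planted_rac_map.items()
    }
    detected_prog: dict[str, int] = {}
    n_detected_planted = 0
    for (line, cl), prog in planted.items():
        m, labels = matrices[line]
        truth_labels = meta.loc[meta["cell_line"] == line, "true_cluster"].to_numpy()
        cells_in_planted = truth_labels == cl
        rac_clusters = set(
            rac_table.loc[
                (rac_table["cell_line"] == line) & rac_table["is_rac"], "cluster_id"
            ]
        )
        in_rac = np.isin(labels, list(rac_clusters))
        if (in_rac & cells_in_planted).sum() / max(cells_in_planted.sum(), 1) > 0.5:
            n_detected_planted += 1
    for _, rec in rac_table[rac_table["is_rac"]].iterrows():
        line, cl = rec["cell_line"], rec["cluster_id"]
        m, labels = matrices[line]
        truth_labels = meta.loc[meta["cell_line"] == line, "true_cluster"].to_numpy()
        members = truth_labels[labels == cl]
        maj = int(pd.Series(members).mode().iloc[0])
        detected_prog[f"{line}:{cl}"] = planted.get((line, maj), -1)

    metrics: dict = {
        "seed": cfg.seed,
        "n_racs_detected": int(rac_table["is_rac"].sum()),
        "n_planted": len(planted),
        "planted_rac_detection": n_detected_planted / max(len(planted), 1),
        "rac_table": rac_table,
    }

    if rac_table["is_rac"].sum() >= 2:
        hvg_sets = [set(select_hvg(m, min(hvg_top, m.n_genes))) for m, _ in matrices.values()]
        shared = sorted(set.intersection(*hvg_sets))
        metrics["n_shared_hvg"] = len(shared)
        vectors = differential_mean_vectors(matrices, rac_table, shared)
        scs, unassigned, newick = supercluster_racs(
            vectors, min_lines=2, corr_threshold=corr_threshold
        )
        metrics["n_superclusters"] = len(scs)
        metrics["newick"] = newick

        assignment, truth_prog = [], []
        sc_of: dict[tuple[str, int], int] = {}
        for sc in scs:
            for member in sc.members:
                sc_of[member] = sc.id
        for key, prog in detected_prog.items():
            line, cl = key.split(":", 1)
            assignment.append(sc_of.get((line, int(cl)), 0))
            truth_prog.append(prog)
        metrics["supercluster_ari"] = (
            float(adjusted_rand_score(truth_prog, assignment)) if assignment else 0.0
        )

        # consensus signature quality per supercluster; the marker
        # contrast is member RAC vs non-RAC cells so genes shared between
        # resistance states are not diluted by the other RACs
        rac_clusters_of = {
            line: set(
                rac_table.loc[
                    (rac_table["cell_line"] == line) & rac_table["is_rac"],
                    "cluster_id",
                ]
            )
            for line in matrices
        }
        marker_cache: dict[tuple[str, int], pd.DataFrame] = {}
        precisions, recalls = [], []
        for sc in scs:
            progs = [
                detected_prog.get(f"{line}:{cl}", -1) for line, cl in sc.members
            ]
            maj_prog = int(pd.Series(progs).mode().iloc[0])
            if maj_prog < 0:
                continue
            # member RACs up-regulate both the shared core and their program
            truth_genes = set(truth["program_genes"][str(maj_prog)]) | set(
                truth["core_genes"]
            )
            tables = []
            for line, cl in sc.members:
                if (line, cl) not in marker_cache:
                    m, labels = matrices[line]
                    other_racs = rac_clusters_of[line] - {cl}
                    keep = ~np.isin(labels, list(other_racs))
                    marker_cache[(line, cl)] = find_markers(
                        m.subset_cells(keep),
                        np.where(labels[keep] == cl, "in", "out"),
                        "in",
                    )
                tables.append(marker_cache[(line, cl)])
            try:
                sig_up = consensus_supercluster_signature(tables, direction="up")
            except ValueError:
                continue
            pred = set(sig_up.genes)
            if pred:
                precisions.append(len(pred & truth_genes) / len(pred))
                recalls.append(len(pred & truth_genes) / len(truth_genes))
        metrics["consensus_precision"] = float(np.mean(precisions)) if precisions else 0.0
        metrics["consensus_recall"] = float(np.mean(recalls)) if recalls else 0.0
    return metrics
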