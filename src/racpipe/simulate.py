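"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a multi-cell-line
early drug-response experiment: negative-binomial counts with lognormal
baseline means and per-cell size factors, per-cluster identity programs
(a random subset of genes shifted up or down), and planted "resistance
programs" — gene sets multiplied by ``2**program_log2fc`` in designated
(line, cluster) pairs. Programs planted in clusters from two or more
lines define the true superclusters. Drug-class labels are sampled with
program-conditional bias so class enrichment is recoverable, and
companion generators produce CRISPR rankings, survival cohorts and
ortholog maps correlated with the planted programs.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature
from .validation import SurvivalCohort

__all__ = [
    "SimConfig",
    "simulate_cell_lines",
    "simulate_crispr_ranking",
    "simulate_survival",
    "simulate_ortholog_transfer",
]


def _default_rac_map() -> dict:
    # each program spans all three lines (superclusters draw members from
    # every line), giving 9 planted RACs in 3 true superclusters
    return {(f"L{line}", prog): prog for line in range(3) for prog in range(3)}


def _default_class_bias() -> dict:
    # program -> preferred drug class (epigenetic drugs dominate program 0,
    # mirroring a class-specific resistance state)
    return {0: "epigenetic", 1: "kinase", 2: "dna_damage"}


@dataclass
class SimConfig:
    """Fully-specified world for the synthetic experiment.

    Defaults are the desk-scale preset: 3 cell lines x 6 clusters x 150
    cells, 2,000 genes, dispersion 0.3, three planted 60-gene programs at
    log2 fold change 1.0, one program active pre-treatment.
    """

    n_cell_lines: int = 3
    clusters_per_line: int = 6
    cells_per_cluster: int = 150
    n_genes: int = 2000
    nb_dispersion: float = 0.3
    core_size: int = 60
    program_size: int = 60
    program_log2fc: float = 1.0
    effect_heterogeneity: float = 0.1
    cluster_shift_frac: float = 0.05
    cluster_log2fc: float = 1.0
    treated_fraction: float = 0.8
    planted_rac_map: dict = field(default_factory=_default_rac_map)
    pretreatment_active: set = field(default_factory=lambda: {("L0", 0)})
    drug_classes: tuple = ("epigenetic", "kinase", "dna_damage", "antimetabolite")
    class_bias: dict = field(default_factory=_default_class_bias)
    class_bias_weight: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 < self.treated_fraction <= 1:
            raise ValueError("treated_fraction must be in (0, 1]")
        lines = {f"L{i}" for i in range(self.n_cell_lines)}
        for (line, cl), prog in self.planted_rac_map.items():
            if line not in lines or not 0 <= cl < self.clusters_per_line:
                raise ValueError(f"planted RAC ({line}, {cl}) outside the grid")
        for key in self.pretreatment_active:
            if key not in self.planted_rac_map:
                raise ValueError(f"pretreatment_active entry {key} is not a planted RAC")
        if not 0 <= self.effect_heterogeneity < 1:
            raise ValueError("effect_heterogeneity must be in [0, 1)")
        n_programs = len(set(self.planted_rac_map.values()))
        if n_programs * self.program_size + self.core_size > self.n_genes // 2:
            raise ValueError("programs exceed the upper-expression gene pool")

    @property
    def lines(self) -> list[str]:
        return [f"L{i}" for i in range(self.n_cell_lines)]

    @property
    def program_ids(self) -> list[int]:
        return sorted(set(self.planted_rac_map.values()))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by mean and dispersion."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_cell_lines(
    cfg: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, dict]:
    """Generate per-line count matrices, cell metadata and truth tables.

    The planted resistance structure has two layers: a shared ``core``
    program boosted in every planted RAC cell — the analogue of a single
    consensus resistance signature that marks all resistant states — and
    one state-specific program per supercluster, boosted only in that
    program's RACs. Each planted gene carries a fixed per-gene effect
    multiplier in ``1 ± effect_heterogeneity`` (shared across lines), so
    strong genes rank consistently high in every marker list, as graded
    real programs do. Planted genes are drawn from the upper half of
    baseline expression — differential programs are only observable on
    expressed genes — and are excluded from the cluster-identity shift
    pools so that a zero-effect configuration is a true null for
    signature activity.

    Returns
    -------
    matrices
        cell_line -> ExpressionMatrix (raw counts).
    meta
        Per-cell table with cell_id, cell_line, treatment, drug_class,
        timepoint and the planted true_cluster label.
    truth
        Dict with core and program gene lists, the planted RAC map,
        pre-treatment active RACs and the scoring signature (= core).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)

    upper_half = np.argsort(baseline)[cfg.n_genes // 2 :]
    pool = rng.permutation(upper_half)
    core_idx = np.sort(pool[: cfg.core_size])
    core_genes = sorted(genes[core_idx])
    used = cfg.core_size
    program_genes: dict[int, list[str]] = {}
    program_idx: dict[int, np.ndarray] = {}
    for prog in cfg.program_ids:
        idx = np.sort(pool[used : used + cfg.program_size])
        used += cfg.program_size
        program_idx[prog] = idx
        program_genes[prog] = sorted(genes[idx])
    all_planted_idx = np.concatenate([core_idx, *program_idx.values()]) if program_idx else core_idx
    # per-gene effect multiplier, fixed across lines and clusters
    effect_mult = np.ones(cfg.n_genes)
    h = cfg.effect_heterogeneity
    effect_mult[all_planted_idx] = rng.uniform(1 - h, 1 + h, size=all_planted_idx.size)

    n_shift = int(round(cfg.cluster_shift_frac * cfg.n_genes))
    shiftable = np.setdiff1d(np.arange(cfg.n_genes), all_planted_idx)

    matrices: dict[str, ExpressionMatrix] = {}
    meta_rows = []
    drugs_per_class = {c: [f"{c}_{k}" for k in range(3)] for c in cfg.drug_classes}
    classes = np.array(cfg.drug_classes, dtype=object)

    for line in cfg.lines:
        cell_ids, cols = [], []
        for cl in range(cfg.clusters_per_line):
            shift_idx = rng.choice(shiftable, size=min(n_shift, len(shiftable)), replace=False)
            shift_sign = rng.choice([-1.0, 1.0], size=len(shift_idx))
            log2_shift = np.zeros(cfg.n_genes)
            log2_shift[shift_idx] = shift_sign * cfg.cluster_log2fc

            prog = cfg.planted_rac_map.get((line, cl))
            pre_active = (line, cl) in cfg.pretreatment_active
            for j in range(cfg.cells_per_cluster):
                cell_id = f"{line}_c{cl}_{j:03d}"
                treated = rng.random() < cfg.treated_fraction
                if treated:
                    if prog is not None and prog in cfg.class_bias:
                        w = np.ones(len(classes))
                        w[classes == cfg.class_bias[prog]] = cfg.class_bias_weight
                        w /= w.sum()
                        drug_class = str(rng.choice(classes, p=w))
                    else:
                        drug_class = str(rng.choice(classes))
                    drug = str(rng.choice(drugs_per_class[drug_class]))
                else:
                    drug_class, drug = None, "vehicle"

                cell_log2 = log2_shift.copy()
                if prog is not None and (pre_active or treated):
                    boosted = np.concatenate([core_idx, program_idx[prog]])
                    cell_log2[boosted] += cfg.program_log2fc * effect_mult[boosted]

                size_factor = rng.lognormal(mean=0.0, sigma=0.2)
                mu = baseline * np.exp2(cell_log2) * size_factor
                cols.append(_nb_counts(rng, mu, cfg.nb_dispersion))
                cell_ids.append(cell_id)
                meta_rows.append(
                    {
                        "cell_id": cell_id,
                        "cell_line": line,
                        "treatment": drug,
                        "drug_class": drug_class,
                        "timepoint": 24.0,
                        "true_cluster": cl,
                    }
                )
        counts = np.column_stack(cols)
        matrices[line] = ExpressionMatrix(gene_ids=genes.copy(), cell_ids=cell_ids, counts=counts)

    meta = pd.DataFrame(meta_rows)
    truth = {
        "core_genes": core_genes,
        "program_genes": {str(k): v for k, v in program_genes.items()},
        "planted_rac_map": {f"{line}:{cl}": prog for (line, cl), prog in cfg.planted_rac_map.items()},
        "pretreatment_active": sorted(f"{line}:{cl}" for line, cl in cfg.pretreatment_active),
        "scoring_signature": core_genes,
        "seed": cfg.seed,
    }
    return matrices, meta, truth


def scoring_signature_from_truth(truth: Mapping) -> GeneSignature:
    """The shared-core signature used to flag resistance activity."""
    return GeneSignature(
        name="planted_resistance",
        genes=list(truth["scoring_signature"]),
        direction="up",
        provenance="planted shared resistance program (core)",
    )


def simulate_crispr_ranking(
    up_sig: GeneSignature | Sequence[str],
    down_sig: GeneSignature | Sequence[str],
    n_genes: int = 18000,
    effect: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genome-wide knockout ranking correlated with a signature.

    A latent sensitization score ~N(0,1) is shifted by ``+effect`` for
    up-signature genes and ``-effect`` for down-signature genes; ranks are
    assigned so larger rank = stronger sensitization upon knockout.
    """
    up = list(up_sig.genes) if isinstance(up_sig, GeneSignature) else list(up_sig)
    down = list(down_sig.genes) if isinstance(down_sig, GeneSignature) else list(down_sig)
    if set(up) & set(down):
        raise ValueError("up and down signatures overlap")
    named = list(dict.fromkeys(up + down))
    if len(named) > n_genes:
        raise ValueError("n_genes smaller than the signatures")
    background = [f"bg{i:05d}" for i in range(n_genes - len(named))]
    genes = np.array(named + background, dtype=object)
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n_genes)
    latent[np.isin(genes, up)] += effect
    latent[np.isin(genes, down)] -= effect
    rank = np.empty(n_genes, dtype=int)
    rank[np.argsort(latent, kind="stable")] = np.arange(1, n_genes + 1)
    return pd.DataFrame({"gene": genes, "rank": rank, "score": latent})


def simulate_survival(
    n: int,
    signature: GeneSignature | Sequence[str],
    score_effect: float,
    censor_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 365.0,
    n_background_genes: int = 200,
    seed: int = 0,
) -> SurvivalCohort:
    """Survival cohort whose hazard follows the signature's ssGSEA score.

    Each sample has a latent activity that elevates expression of the
    signature genes; event times are exponential with hazard
    ``baseline * exp(score_effect * z)`` where ``z`` is the standardized
    ssGSEA score. Censoring is Bernoulli(``censor_rate``) with a uniform
    time in (0, T), so the event fraction is ~``1 - censor_rate`` by
    construction.
    """
    from .scoring import ssgsea

    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    sig = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    if not sig:
        raise ValueError("empty signature")
    rng = np.random.default_rng(seed)
    samples = [f"s{i:04d}" for i in range(n)]
    background = [f"bg{i:04d}" for i in range(n_background_genes)]
    genes = sig + background
    activity = rng.normal(size=n)
    expr = rng.normal(loc=5.0, scale=1.0, size=(len(genes), n))
    expr[: len(sig), :] += 2.0 * activity[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    scores = np.array([ssgsea(expression[s], sig) for s in samples])
    z = (scores - scores.mean()) / scores.std(ddof=0)
    hazard = baseline_hazard * np.exp(score_effect * z)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, rng.uniform(0.0, t_event), t_event)
    time = np.maximum(time, 1e-3)
    samples_df = pd.DataFrame(
        {"sample_id": samples, "time": time, "event": (~censored).astype(int)}
    )
    return SurvivalCohort(samples=samples_df, expression=expression)


def simulate_ortholog_transfer(
    program_genes: Sequence[str],
    overlap_fraction: float,
    n_source_genes: int = 50,
    n_decoy_human_genes: int = 500,
    seed: int = 0,
) -> tuple[GeneSignature, pd.DataFrame]:
    """Non-human signature plus an ortholog map overlapping a planted program.

    ``round(overlap_fraction * n_source_genes)`` source genes map onto
    planted program genes; the rest map onto decoy human genes.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    program = list(program_genes)
    rng = np.random.default_rng(seed)
    n_overlap = int(round(overlap_fraction * n_source_genes))
    if n_overlap > len(program):
        raise ValueError("overlap exceeds the planted program size")
    source = [f"src_{i:04d}" for i in range(n_source_genes)]
    targets = list(rng.choice(np.array(program, dtype=object), size=n_overlap, replace=False))
    decoys = [f"hx{i:04d}" for i in range(n_decoy_human_genes)]
    targets += list(
        rng.choice(np.array(decoys, dtype=object), size=n_source_genes - n_overlap, replace=False)
    )
    ortholog_map = pd.DataFrame({"source_gene": source, "human_gene": targets})
    sig = GeneSignature(
        name="source_resistance",
        genes=source,
        direction="up",
        provenance=f"synthetic cross-species signature (overlap={overlap_fraction})",
    )
    return sig, ortholog_map
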