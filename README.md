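# racpipe

Early drug-resistance state inference from single-cell transcriptomes.

When cancer cell lines are profiled shortly after drug exposure, a small
subset of transcriptional cell states already expresses the programs that
characterize long-term resistant populations. `racpipe` implements the
analysis that finds those states and validates them:

1. **Consensus resistance signatures** — differential-expression marker
   lists from multiple experiments are combined by robust rank aggregation
   (RRA). For a gene with sorted normalized ranks
   r₍₁₎ ≤ … ≤ r₍ₖ₎ across *k* lists, the score is
   ρ = minⱼ B(r₍ⱼ₎; j, k−j+1), where B is the Beta CDF — the probability
   that the j-th smallest of k uniform ranks is this small. Genes with a
   small Bonferroni-corrected ρ·k that appear in at least two lists form
   the consensus signature.
2. **Per-cell activity** — the recovery-AUC statistic: the normalized area
   under the curve of cumulative signature genes recovered within the top
   5% of a cell's expression-ranked genes. An activation threshold is the
   0.95 quantile of scores from 100 expression-matched control gene sets,
   so "active" means "above what matched random gene sets achieve".
3. **Resistance-activated clusters (RACs)** — transcriptional clusters
   enriched for active cells by Fisher's exact test (odds ratio > 1,
   BH-adjusted p < 0.05 within each cell line).
4. **Superclusters** — RACs from different cell lines are grouped by
   hierarchical clustering (average linkage) of 1 − Spearman distance
   between their differential mean-expression vectors over the
   intersection of per-line highly variable genes; groups spanning ≥ 2
   lines are shared resistance states, each with RRA consensus up/down
   signatures.
5. **Validation** — CRISPR knockout rank shifts (Wilcoxon), Kaplan–Meier /
   log-rank survival splits on ssGSEA scores, responder comparisons with
   Cohen's d, and transfer of non-human (yeast / bacterial) resistance
   signatures through ortholog maps.

A fully specified synthetic-data module plants known resistance programs
in negative-binomial count matrices so every stage is testable without
external downloads.

## Worked example

Simulate the default three-line experiment (3 cell lines × 6 clusters ×
150 cells, 2,000 genes, a shared 60-gene resistance program planted in
three clusters per line) and identify the RACs:

```python
import numpy as np
from racpipe.simulate import SimConfig, simulate_cell_lines, scoring_signature_from_truth
from racpipe.preprocess import normalize, cluster_cells
from racpipe.scoring import score_cells
from racpipe.states import identify_racs

cfg = SimConfig(seed=1)
matrices, meta, truth = simulate_cell_lines(cfg)
signature = scoring_signature_from_truth(truth)

flags, clusters, lines = [], [], []
for line, m in matrices.items():
    m = normalize(m)                          # log1p(counts / total * 1e4)
    labels = cluster_cells(m, seed=cfg.seed)  # PCA -> kNN -> Leiden
    table = score_cells(m, signature, n_controls=100, q=0.95, seed=cfg.seed)
    flags.append(table["active"].to_numpy())
    clusters.append(labels)
    lines.append(np.full(m.n_cells, line))

racs = identify_racs(np.concatenate(flags), np.concatenate(clusters), np.concatenate(lines))
print(racs[racs.is_rac].to_string(index=False))
```

```
cell_line  cluster_id  n_active_in  n_inactive_in  n_active_out  n_inactive_out  odds_ratio            p        p_adj  is_rac
       L0           3           80             71           104             645    6.988082 2.506123e-23 1.503674e-22    True
       L0           4           55             80           129             636    3.389535 3.092405e-09 3.710886e-09    True
       L0           5           49             85           135             631    2.694466 2.352294e-06 2.352294e-06    True
       L1           3           78             63           137             622    5.621133 1.058377e-18 1.587566e-18    True
       L1           4           68             68           147             617    4.197279 4.011369e-13 4.011369e-13    True
       L1           5           69             65           146             620    4.507903 3.498087e-14 4.197705e-14    True
       L2           3           66             78           135             621    3.892308 5.331590e-12 6.397909e-12    True
       L2           4           63             79           138             620    3.582829 1.205286e-10 1.205286e-10    True
       L2           5           72             66           129             633    5.353066 2.482789e-17 3.724184e-17    True
```

Nine clusters — three per line, exactly the nine planted ones — are
flagged: 36–53% of their cells exceed the matched-control activation
threshold versus ~17% elsewhere (the out-groups include the other planted
clusters), giving odds ratios of 2.7–7.0. Downstream,
`differential_mean_vectors` + `supercluster_racs` group these nine RACs
into the three planted superclusters, and
`consensus_supercluster_signature` recovers the planted program genes.

A command-line interface mirrors the library:

```bash
rac simulate --preset default --seed 0 --out sim/
rac run --config run.yaml          # preprocess -> score -> states + manifest
rac score --matrix sim/ --signatures sim/signatures.gmt --method aucell --out scores.tsv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's end-to-end planted-truth recovery at the default
simulation preset — simulation, normalization, clustering, scoring, RAC
identification, superclustering and consensus-signature construction —
prints the recovery metrics to stderr and writes the results JSON to the
given path.

## Layout

- `racpipe.preprocess` — QC, normalization, HVG selection, Leiden clustering
- `racpipe.rank_aggregation` — marker tests, RRA, consensus signatures
- `racpipe.scoring` — recovery-AUC, control sets, module scores, ssGSEA, preranked GSEA
- `racpipe.states` — RACs, superclusters, cell-cycle phases, drug-class enrichment
- `racpipe.enrichment` — hypergeometric over-representation analysis
- `racpipe.validation` — CRISPR rank shifts, survival, group comparisons, orthologs
- `racpipe.simulate` — synthetic data with planted ground truth
- `racpipe.pipeline`, `racpipe.cli` — orchestration and the `rac` command

See `docs/methods.md` for the statistical details and design rationale.
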