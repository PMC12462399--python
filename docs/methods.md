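# Methods

This note documents the statistical procedures implemented in `racpipe`,
the parameters that matter, the synthetic world the generator states, and
the design choices made where the underlying methodology is genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Cells are filtered on detected features (genes with count > 0), keeping
the inclusive range [200, 2500] by default; genes are then filtered to
those detected in ≥ 100 cells. The order is fixed — cells first, then
genes — because the thresholds are quoted on raw per-dataset inputs.
Normalization is `log(1 + count / cell_total × scale_factor)` with the
natural log and scale factor 10,000, making values invariant to per-cell
library size.

Highly variable genes are ranked by the dispersion (variance/mean of the
de-logged normalized layer) z-scored within 20 quantile bins of mean
expression; the binning removes the mean–variance trend, and ties break
by gene symbol so the ranking is deterministic. This statistic assumes
gene means spread over a nontrivial range; when all means are equal the
bins are arbitrary (a degenerate case exercised and documented in the
test suite).

Clustering runs PCA (50 components) on the normalized layer, builds a
symmetrized 15-nearest-neighbor graph, and applies Leiden community
detection (RB-configuration modularity, resolution 1.0, fixed seed).
Clusters are computed per cell line, jointly over vehicle and treated
cells.

## Robust rank aggregation

For a gene with sorted normalized ranks r₍₁₎ ≤ … ≤ r₍ₘ₎ over k ranked
lists, ρ = minⱼ BetaCDF(r₍ⱼ₎; j, k−j+1). Each Beta order-statistic CDF is
exactly uniform under the null of random ranks; ρ is their minimum, and
`p_rank = min(1, ρ·k)` is its Bonferroni correction — a valid, slightly
conservative p-value. Note that `p_rank` is *sub*-uniform under the null
for k > 1 (it has an atom at 1); only its low tail is calibrated, which
is what selection uses.

Choices that needed deciding:

- **Missing genes.** A gene absent from a list receives the worst
  normalized rank 1.0 (`missing="worst"`), matching the published RRA
  implementation for top-k lists. The alternative — computing ρ only over
  the lists containing the gene with k reduced accordingly
  (`missing="ignore"`) — lets a gene ranked well in a single list reach a
  small score with no cross-list corroboration, defeating the purpose of
  a consensus; it remains available as an option.
- **Rank universe.** Marker lists are the significant head of a
  genome-wide test, i.e. top-k selections from all tested genes. Ranks
  are therefore normalized by the number of genes *tested*
  (`universe_size`), not by the size of the union of the short lists.
  With union normalization the best attainable ρ at k = 3 lists of ~150
  genes is far too large for any gene ever to be selected.
- **Selection rule.** "Adjusted rank p-value < 0.05" is read as the
  Bonferroni-corrected score ρ·k — the published RRA tool's corrected
  score — with Benjamini–Hochberg across genes additionally computed and
  reported (`select_on="p_rank_adj"` switches the rule).
- **Corroboration.** Selected genes must appear in ≥ 2 input lists
  (`min_lists`); because ρ minimizes over all order statistics including
  j = 1, a top rank in one list alone can otherwise reach significance.

Marker detection (`find_markers`) is a two-sided Wilcoxon rank-sum test
per gene on the normalized layer with Bonferroni adjustment over tested
genes, and log2 fold change `log2((mean_in + 1)/(mean_out + 1))` on
de-logged means. Consensus construction filters each table to significant
genes of the requested sign, ranks by |log2FC| (ties by symbol), and
aggregates.

## Recovery-AUC and the activation threshold

A cell's genes are ordered by decreasing normalized expression (ties
resolved by a per-cell seeded shuffle; a symbol-ordered deterministic
mode exists). For a signature of size s and M = ⌊0.05 × n_genes⌋, the
step curve y(x) = number of signature genes at rank ≤ x is summed over
x = 1..M and divided by the maximum attainable area given s and M, so a
perfect arrangement scores 1 and no recovery scores 0. The statistic
depends only on the ranking, never on the expression values behind it.

The activation threshold is the 0.95 quantile of recovery-AUC scores of
100 control gene sets, pooled over all cells (a per-cell background mode
exists). Control sets replicate the signature's per-bin gene counts over
24 quantile bins of mean expression, sampling non-signature genes without
replacement (with replacement, with a warning, when a bin is too small;
from the global non-signature pool when a bin is empty). Because the
controls are expression-matched, a random signature is exchangeable with
its controls and ~5% of cells exceed the threshold by construction — the
false-activation calibration the acceptance suite verifies.

Module scores (used for cell-cycle phases) are the mean normalized
expression of the signature minus the mean over control sets of each
set's mean — the average-based analogue of the same matched-control idea.

ssGSEA orders genes by expression, weights in-set ranks by rank^α
(α = 0.75; the top gene has rank n) against a uniform out-of-set ECDF,
and reports the mean running-sum difference over gene positions (the
division by n is the normalization choice; scores are rank-based and
invariant to monotone transforms of expression). Preranked GSEA is the
classic weighted Kolmogorov–Smirnov enrichment score with a gene-label
permutation null, NES = ES / mean |same-sign null ES|, and a two-sided
permutation p with +1 continuity.

## RACs, superclusters, consensus signatures

Per cluster, the 2×2 table (active/inactive × in/out of cluster, within
the cell line) is tested two-sided by Fisher's exact test; the reported
odds ratio is the sample cross-product ratio with Haldane–Anscombe 0.5
correction on zero cells. BH adjustment runs across clusters within each
cell line (a global mode exists); a RAC is odds ratio > 1 with adjusted
p < 0.05.

Differential mean vectors (RAC mean minus same-line rest mean, over the
intersection of per-line HVGs) are compared by Spearman correlation;
average-linkage hierarchical clustering of 1 − ρ is cut at height
1 − 0.4. The 0.4 correlation default operationalizes "highly correlated"
and is deliberately exposed, with the dendrogram (Newick) always written
for audit. Groups spanning ≥ 2 cell lines become superclusters.

Supercluster consensus signatures aggregate the member RACs' marker
tables (up and down separately) with the RRA machinery above. The marker
contrast is member RAC versus **non-RAC** cells of the line: resistance
genes shared by all RACs would otherwise be diluted by the other RACs in
the out-group — exactly the genes a consensus exists to find. Up- and
down-signatures are disjoint by the sign partition.

Cell-cycle phases are argmax module scores over G0/G1/S/G2M with the
fixed tie order G0 < G1 < S < G2M. When no explicit G1 list is supplied,
a cell is called G1 when all of G0/S/G2M score ≤ 0 (below matched
controls on every program), else argmax of the three. The bundled S/G2M
lists are the standard Tirosh-derived sets; the bundled G0 list is a
small representative quiescence marker set standing in for an external
signature — supply your own for real analyses.

Drug-class enrichment per supercluster is a two-sided Fisher test on
(class vs other) × (inside vs outside the component clusters) over
treated cells, plus the fold enrichment of the class fraction inside
relative to overall.

## Validation statistics

- **CRISPR rank shift**: one-sided Wilcoxon rank-sum comparing knockout
  ranks of up- versus down-signature genes (disjointness enforced,
  ≥ 5 genes each after intersection), with rank-biserial effect size.
  Rank polarity is normalized so larger rank = stronger sensitization; a
  flag handles tables with the opposite convention, and a KS alternative
  exists.
- **Survival**: per-sample ssGSEA scores, median split (ties to the low
  group), two-group log-rank test via lifelines, KM curves emitted as
  tables. Times are in days.
- **Group comparisons**: Wilcoxon rank-sum (two-sided) or one-sided
  t-test, with Cohen's d on the pooled SD (n−1 denominators).
- **Cross-species transfer**: k-of-n consensus gene sets (e.g. 5 of 9
  experiments), then ortholog mapping through a two-column table
  (many-to-many allowed, unmapped genes reported).
- **One-sample log test**: one-sided t-test that log hazard ratios exceed
  zero.

Cox regression is deliberately not implemented; the survival module
prepares analysis-ready tables for standard implementations.

## The synthetic world

`simulate_cell_lines` states a fully seeded world:

| parameter | default | meaning |
|---|---|---|
| lines × clusters × cells | 3 × 6 × 150 | per-line design |
| n_genes | 2,000 | gene universe |
| baseline means | lognormal(0, 1) | per-gene NB means |
| nb_dispersion | 0.3 | NB dispersion (var = μ + 0.3 μ²) |
| size factors | lognormal(0, 0.2) | per-cell depth |
| cluster_shift_frac | 0.05 | genes per cluster-identity program |
| cluster_log2fc | ±1.0 | identity-program effect |
| core_size / program_size | 60 / 60 | shared core and per-state programs |
| program_log2fc | 1.0 | planted effect (mean) |
| effect_heterogeneity | 0.1 | per-gene effect jitter (fixed across lines) |
| treated_fraction | 0.8 | cells receiving a drug |

The planted structure has two layers mirroring the biology: a shared
*core* program boosted in every planted RAC cell — the analogue of a
single consensus resistance signature marking all resistant states (and
the signature the pipeline scores) — and one *program* per supercluster
boosted only in that state's RACs. One planted RAC is active
pre-treatment (vehicle cells included); the others are induced (treated
cells only). Planted genes are drawn from the upper half of baseline
expression (differential programs are only observable on expressed
genes), carry a fixed ±10% per-gene effect multiplier shared across lines
(graded effects rank consistently across marker lists, as real programs
do), and are excluded from the cluster-identity shift pools so that a
zero-effect configuration is a true null for signature activity. Drug
classes are sampled with program-conditional bias (weight 6 toward each
program's preferred class), reproducing class-specific resistance states.

Companion generators produce CRISPR rankings (latent N(0,1)
sensitization ± effect on signature genes), survival cohorts (expression
driven by a latent activity; exponential event times with hazard
∝ exp(effect × standardized ssGSEA score); Bernoulli censoring uniform in
(0, T), so the event fraction is ~1 − censor_rate by construction), and
ortholog maps overlapping a planted program by a stated fraction.

**What a green test establishes — and does not.** The generator emulates
multi-line NB counts with cluster structure, planted programs, biased
drug classes, and truth tables sufficient to score every stage. It does
not emulate batch effects, doublets, ambient RNA, transcriptome-scale
gene counts, or realistic gene–gene correlation beyond the planted
programs; recovery at desk scale demonstrates the pipeline's statistical
machinery, not performance on any particular real dataset. The planted
recovery harness selects the top 1,000 of 2,000 genes per line for the
HVG intersection — covering the world's ~800 structured genes, as the
full-scale top-2,000-of-~18,000 rule is meant to for real data.

## Numerical and determinism choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; per-cell tie-shuffles derive from `(seed, cell_index)`.
- Sorting ties break by gene symbol everywhere a ranking is emitted.
- Spearman distance matrices are symmetrized and clipped at 0 before
  linkage; constant vectors raise an error naming the offending RAC.
- Fisher odds ratios use the Haldane–Anscombe 0.5 correction only when a
  cell is zero; p-values always come from the uncorrected table.
- BH adjustment uses `scipy.stats.false_discovery_control`.
- Degenerate inputs raise errors rather than returning silent defaults:
  empty QC results, zero-total cells, constant expression vectors in
  ssGSEA, zero pooled variance in Cohen's d, all-identical survival
  scores.

## Known limitations

- The recovery-AUC ranking treats a cell's zeros as exchangeable (ties
  broken by seeded shuffle); in very sparse cells the bottom of the
  ranking is arbitrary, which is why only the top 5% contributes.
- The HVG statistic assumes means spread over a range; it degrades when
  all genes share a mean.
- The log-rank test is delegated to lifelines and inherits its handling
  of tied event times.
- `identify_racs` requires ≥ 2 clusters per line and treats lines
  independently; no cross-line batch correction is attempted (input data
  are assumed processed identically).
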