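"""Downstream validation of resistance signatures.

Covers CRISPR rank-shift comparisons (do knockouts of up-signature genes
sensitize more than down-signature genes?), Kaplan–Meier/log-rank survival
splits on ssGSEA scores, two-group score comparisons with Cohen's d,
one-sample tests on log hazard ratios, k-of-n consensus gene sets, and
ortholog transfer of non-human signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSignature
from .scoring import ssgsea

__all__ = [
    "SurvivalCohort",
    "crispr_rank_shift",
    "km_logrank",
    "group_score_compare",
    "one_sample_log_test",
    "consensus_across_experiments",
    "apply_ortholog_map",
]


@dataclass
class SurvivalCohort:
    """Samples with follow-up time (days), event flags and expression.

    ``expression`` is a genes x samples frame; ``scores`` and ``groups``
    are filled by :func:`km_logrank`.
    """

    samples: pd.DataFrame  # columns: sample_id, time, event
    expression: pd.DataFrame
    scores: pd.Series | None = None
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"samples table needs columns {sorted(required)}")
        if (self.samples["time"] <= 0).any():
            raise ValueError("survival times must be positive (days)")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.samples["sample_id"]) - set(self.expression.columns)
        if missing:
            raise ValueError(f"samples missing from expression: {sorted(missing)[:5]}")


def crispr_rank_shift(
    ranking: pd.DataFrame,
    up_sig: GeneSignature | Sequence[str],
    down_sig: GeneSignature | Sequence[str],
    polarity: str = "high_sensitizing",
    test: str = "wilcoxon",
    min_overlap: int = 5,
) -> dict:
    """Compare CRISPR ranks of up- versus down-signature genes.

    With ``polarity="high_sensitizing"`` (default) larger rank values mean
    stronger sensitization upon knockout and the one-sided alternative is
    "up-signature ranks exceed down-signature ranks";
    ``polarity="low_sensitizing"`` flips the input ranks first.

    Returns a dict with the statistic, one-sided p, direction, and the
    rank-biserial effect size.
    """
    if polarity not in ("high_sensitizing", "low_sensitizing"):
        raise ValueError("unknown polarity")
    if test not in ("wilcoxon", "ks"):
        raise ValueError("test must be 'wilcoxon' or 'ks'")
    up = set(up_sig.genes) if isinstance(up_sig, GeneSignature) else set(up_sig)
    down = set(down_sig.genes) if isinstance(down_sig, GeneSignature) else set(down_sig)
    if up & down:
        raise ValueError("up and down signatures must be disjoint")
    ranks = ranking.set_index("gene")["rank"].astype(float)
    if polarity == "low_sensitizing":
        ranks = len(ranks) + 1 - ranks
    up_ranks = ranks.loc[ranks.index.intersection(sorted(up))].to_numpy()
    down_ranks = ranks.loc[ranks.index.intersection(sorted(down))].to_numpy()
    if len(up_ranks) < min_overlap or len(down_ranks) < min_overlap:
        raise ValueError(
            f"signature/ranking overlap below {min_overlap} "
            f"({len(up_ranks)} up, {len(down_ranks)} down)"
        )
    if test == "wilcoxon":
        res = scipy.stats.mannwhitneyu(up_ranks, down_ranks, alternative="greater")
        stat, p = float(res.statistic), float(res.pvalue)
        effect = 2.0 * stat / (len(up_ranks) * len(down_ranks)) - 1.0
    else:
        res = scipy.stats.ks_2samp(up_ranks, down_ranks, alternative="less")
        stat, p = float(res.statistic), float(res.pvalue)
        effect = float(np.mean(up_ranks) > np.mean(down_ranks))
    direction = "up_higher" if np.mean(up_ranks) > np.mean(down_ranks) else "down_higher"
    return {
        "statistic": stat,
        "p": p,
        "direction": direction,
        "rank_biserial": float(effect),
        "n_up": len(up_ranks),
        "n_down": len(down_ranks),
    }


def km_logrank(
    cohort: SurvivalCohort,
    signature: GeneSignature | Sequence[str],
    alpha: float = 0.75,
) -> dict:
    """Median-split survival comparison on per-sample ssGSEA scores.

    Scores every sample, splits at the score median (ties to the low
    group), runs the two-group log-rank test, and emits Kaplan–Meier step
    curves as tables. Survival time is in days.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    scores = pd.Series(
        {
            s: ssgsea(cohort.expression[s], signature, alpha=alpha)
            for s in cohort.samples["sample_id"]
        },
        name="score",
    )
    if scores.nunique() == 1:
        raise ValueError("all ssGSEA scores identical; median split undefined")
    median = scores.median()
    groups = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="group"
    )
    n_high, n_low = int((groups == "high").sum()), int((groups == "low").sum())
    if min(n_high, n_low) < 2:
        raise ValueError("fewer than 2 samples in a group after the median split")
    cohort.scores, cohort.groups = scores, groups

    df = cohort.samples.set_index("sample_id")
    high, low = df[groups == "high"], df[groups == "low"]
    res = logrank_test(
        high["time"], low["time"], event_observed_A=high["event"], event_observed_B=low["event"]
    )
    curves = []
    for label, sub in (("high", high), ("low", low)):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=label)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curve["group"] = label
        curves.append(curve)
    return {
        "chi_sq": float(res.test_statistic),
        "p": float(res.p_value),
        "n_high": n_high,
        "n_low": n_low,
        "km_curves": pd.concat(curves, ignore_index=True),
        "scores": scores,
        "groups": groups,
    }


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference (n-1 variance denominators)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance; Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def group_score_compare(
    scores: Sequence[float],
    labels: Sequence,
    test: str = "wilcoxon",
) -> dict:
    """Two-group comparison of signature scores.

    ``test="wilcoxon"`` runs the two-sided rank-sum test;
    ``test="t_one_sided"`` a one-sided t-test (first group greater).
    Cohen's d is reported as group_a minus group_b over the pooled SD.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    a, b = scores[labels == uniq[0]], scores[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if test == "wilcoxon":
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t_one_sided":
        res = scipy.stats.ttest_ind(a, b, alternative="greater")
    else:
        raise ValueError("test must be 'wilcoxon' or 't_one_sided'")
    return {
        "group_a": uniq[0],
        "group_b": uniq[1],
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "cohens_d": cohens_d(a, b),
        "n_a": len(a),
        "n_b": len(b),
    }


def one_sample_log_test(values: Sequence[float]) -> tuple[float, float]:
    """One-sided t-test that log(values) exceeds zero (e.g. hazard ratios)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 values")
    if (vals <= 0).any():
        raise ValueError("all values must be positive")
    logs = np.log(vals)
    if logs.std(ddof=1) == 0:
        raise ValueError("zero variance in log values; t undefined")
    res = scipy.stats.ttest_1samp(logs, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def consensus_across_experiments(
    gene_lists: Iterable[Sequence[str]], k_min: int, name: str = "consensus"
) -> GeneSignature:
    """Genes appearing in at least ``k_min`` of the input lists.

    Output is sorted by occurrence count (descending), then symbol.
    """
    lists = [set(lst) for lst in gene_lists]
    if k_min < 1 or k_min > len(lists):
        raise ValueError("need n_lists >= k_min >= 1")
    counts: dict[str, int] = {}
    for lst in lists:
        for g in lst:
            counts[g] = counts.get(g, 0) + 1
    kept = sorted(
        (g for g, c in counts.items() if c >= k_min),
        key=lambda g: (-counts[g], g),
    )
    return GeneSignature(
        name=name,
        genes=kept,
        provenance=f"present in >= {k_min} of {len(lists)} experiments",
    )


def apply_ortholog_map(
    sig: GeneSignature | Sequence[str],
    ortholog_map: pd.DataFrame,
    name: str | None = None,
) -> tuple[GeneSignature, list[str]]:
    """Translate a non-human signature to human genes via a mapping table.

    Many-to-many maps are allowed: every human ortholog of any signature
    gene is included once. Returns the mapped signature and the list of
    unmapped source genes.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    genes = list(sig.genes) if isinstance(sig, GeneSignature) else list(sig)
    src_name = sig.name if isinstance(sig, GeneSignature) else "signature"
    mapped = ortholog_map[ortholog_map["source_gene"].isin(set(genes))]
    human = sorted(set(mapped["human_gene"]))
    unmapped = sorted(set(genes) - set(mapped["source_gene"]))
    if not human:
        warnings.warn("no signature genes present in the ortholog map")
    return (
        GeneSignature(
            name=name or f"{src_name}_human_orthologs",
            genes=human,
            provenance=f"ortholog transfer of {src_name} ({len(unmapped)} unmapped)",
        ),
        unmapped,
    )
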