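"""Attribution of pathway expression shifts to abundance vs regulation.

For a pathway and a treatment comparison, each genus gets three log2 fold
changes: the mean over its pathway genes (pathway-specific expression), its
total RNA (summed expression over all its genes), and its 16S relative
abundance.  Deviations |pathway - reference| close to zero mean the pathway
shift merely tracks how much of that organism (or its RNA) is present;
large deviations indicate pathway-specific regulation.  A one-sample
one-sided Wilcoxon signed-rank test asks whether the median deviation over
taxa exceeds a null value.

Genus is the taxon unit throughout.  Genera missing from the 16S table are
excluded from the abundance-referenced comparisons (lower phylogenetic
resolution of 16S), not from the RNA-referenced ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedTranscriptTable, FeatureTable, collapse_to_rank

__all__ = [
    "AttributionRecord",
    "AttributionTest",
    "pathway_taxon_log2fc",
    "global_rna_log2fc",
    "abundance_log2fc",
    "build_attribution_records",
    "attribution_test",
    "signed_rank_greater_p",
]

EXPR_PSEUDOCOUNT = 1.0
RELABUND_PSEUDOCOUNT = 1e-6


@dataclass
class AttributionRecord:
    taxon: str
    pathway: str
    comparison: str
    pathway_log2fc: float
    abundance_log2fc: float | None
    global_rna_log2fc: float
    dev_abundance: float | None
    dev_global: float


@dataclass
class AttributionTest:
    pathway: str
    comparison: str
    reference: str  # "abundance" or "global_rna"
    n_taxa: int
    frac_deviating: float
    wilcoxon_p: float


def _mean_expr(expr: pd.DataFrame, samples) -> pd.Series:
    return expr[list(samples)].mean(axis=1)


def pathway_taxon_log2fc(
    table: AnnotatedTranscriptTable,
    pathway_ecs: set,
    samples_a,
    samples_b,
    pseudocount: float = EXPR_PSEUDOCOUNT,
    rank: str = "genus",
) -> pd.Series:
    """Per-genus mean log2 fold change (a over b) of pathway-mapped genes.

    A gene belongs to the pathway when it carries at least one of the
    pathway's EC numbers; genera with no pathway genes are omitted.
    """
    if not pathway_ecs:
        raise ValueError("empty pathway")
    if not list(samples_a) or not list(samples_b):
        raise ValueError("comparison groups must be nonempty")
    ecs = set(pathway_ecs)
    in_pathway = table.annotations["ec_numbers"].map(lambda s: bool(s & ecs))
    tids = table.annotations.index[in_pathway]
    if len(tids) == 0:
        return pd.Series(dtype=float)
    ma = _mean_expr(table.expression.loc[tids], samples_a) + pseudocount
    mb = _mean_expr(table.expression.loc[tids], samples_b) + pseudocount
    gene_fc = np.log2(ma / mb)
    taxa = table.taxon_labels(rank).loc[tids]
    return gene_fc.groupby(taxa).mean()


def global_rna_log2fc(
    table: AnnotatedTranscriptTable,
    samples_a,
    samples_b,
    pseudocount: float = EXPR_PSEUDOCOUNT,
    rank: str = "genus",
) -> pd.Series:
    """Per-genus log2 ratio of total RNA (summed expression over all genes)."""
    taxa = table.taxon_labels(rank)
    tot_a = _mean_expr(table.expression, samples_a).groupby(taxa).sum()
    tot_b = _mean_expr(table.expression, samples_b).groupby(taxa).sum()
    present = (tot_a > 0) | (tot_b > 0)
    return np.log2((tot_a[present] + pseudocount) / (tot_b[present] + pseudocount))


def abundance_log2fc(
    otu_table: FeatureTable,
    taxonomy: dict,
    samples_a,
    samples_b,
    pseudocount: float = RELABUND_PSEUDOCOUNT,
    rank: str = "genus",
) -> pd.Series:
    """Per-genus log2 ratio of mean 16S relative abundance between groups."""
    genus_table = collapse_to_rank(otu_table, taxonomy, rank)
    rel = genus_table.relative_abundance()
    ma = rel[list(samples_a)].mean(axis=1) + pseudocount
    mb = rel[list(samples_b)].mean(axis=1) + pseudocount
    return np.log2(ma / mb)


def build_attribution_records(
    pathway_fc: pd.Series,
    global_fc: pd.Series,
    abundance_fc: pd.Series | None,
    pathway: str,
    comparison: str,
) -> list:
    """Join the three per-genus fold changes into attribution records.

    Taxa must have both a pathway and a global-RNA value; the abundance value
    may be missing (16S resolution gap) and is then excluded from
    abundance-referenced deviations only.
    """
    records = []
    for taxon, pfc in pathway_fc.items():
        if taxon not in global_fc.index:
            continue
        gfc = float(global_fc.loc[taxon])
        afc = (
            float(abundance_fc.loc[taxon])
            if abundance_fc is not None and taxon in abundance_fc.index
            else None
        )
        records.append(
            AttributionRecord(
                taxon=taxon,
                pathway=pathway,
                comparison=comparison,
                pathway_log2fc=float(pfc),
                abundance_log2fc=afc,
                global_rna_log2fc=gfc,
                dev_abundance=abs(pfc - afc) if afc is not None else None,
                dev_global=abs(float(pfc) - gfc),
            )
        )
    return records


def attribution_test(
    records: list,
    reference: str = "global_rna",
    threshold: float = 1.0,
    wilcoxon_null: float = 2.0,
) -> AttributionTest:
    """Summarize deviations of pathway fold change from a reference.

    ``frac_deviating`` is the fraction of taxa whose absolute deviation
    exceeds ``threshold`` (default one log2 unit, i.e. twofold).  The
    one-sided one-sample Wilcoxon signed-rank test asks whether the median
    deviation exceeds ``wilcoxon_null`` (default 2); it is skipped (p = nan)
    with fewer than 3 usable taxa.
    """
    if reference not in ("abundance", "global_rna"):
        raise ValueError("reference must be 'abundance' or 'global_rna'")
    devs = [
        r.dev_abundance if reference == "abundance" else r.dev_global
        for r in records
    ]
    devs = np.array([d for d in devs if d is not None], dtype=float)
    if devs.size == 0:
        raise ValueError("no taxa with defined deviations")
    frac = float(np.mean(devs > threshold))
    if devs.size < 3:
        p = float("nan")
    else:
        p = signed_rank_greater_p(devs - wilcoxon_null)
    pw = records[0].pathway if records else ""
    cmp_ = records[0].comparison if records else ""
    return AttributionTest(
        pathway=pw,
        comparison=cmp_,
        reference=reference,
        n_taxa=int(devs.size),
        frac_deviating=frac,
        wilcoxon_p=p,
    )


def signed_rank_greater_p(diffs, exact_n_max: int = 12) -> float:
    """One-sided Wilcoxon signed-rank p for H1: median(diffs) > 0.

    Zeros are dropped (Wilcoxon convention); |diffs| receive average ranks.
    For n <= ``exact_n_max`` the sign-flip null is enumerated exactly
    (valid with tied ranks); larger samples use the normal approximation
    with tie-corrected variance via :func:`scipy.stats.wilcoxon`.
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    n = nz.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    if n <= exact_n_max:
        signs = np.array(
            [[(m >> i) & 1 for i in range(n)] for m in range(2**n)], dtype=float
        )
        w_null = signs @ ranks
        return float(np.mean(w_null >= w_obs - 1e-12))
    return float(stats.wilcoxon(nz, alternative="greater", method="approx").pvalue)
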