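"""Rank-shift analysis of antimicrobial-resistance gene expression.

To damp the influence of a few very highly expressed AMR genes, every
(gene, sample) expression value is ranked on a single pooled scale across
all samples (rank 1 = highest expression anywhere); each gene is then
summarized per condition by its mean rank, and the shift in ranking between
AGP-supplemented and control birds is tested with a paired t-test over genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable

__all__ = [
    "MECHANISMS",
    "RankShiftResult",
    "read_amr_genes",
    "rank_amr_expression",
    "rank_shift_test",
]

MECHANISMS = (
    "efflux",
    "target_protection",
    "inactivation",
    "target_alteration",
    "reduced_permeability",
)


@dataclass
class RankShiftResult:
    condition_pair: tuple
    mean_rank_shift: float  # positive: higher ranking (smaller rank) under AGP
    t_statistic: float
    p: float
    n_genes: int
    zero_variance: bool = False


def read_amr_genes(path) -> pd.DataFrame:
    """Read an AMR gene list TSV (gene_id, mechanism, source_taxon).

    Mechanisms must come from the five-category resistance set
    (:data:`MECHANISMS`); the gene_id column becomes the index.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mechanism"}
    if not required <= set(df.columns):
        raise ValueError(f"AMR gene list needs columns {sorted(required)}")
    bad = set(df["mechanism"]) - set(MECHANISMS)
    if bad:
        raise ValueError(f"unknown resistance mechanisms: {sorted(bad)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in AMR gene list")
    return df.set_index("gene_id")


def rank_amr_expression(
    table: FeatureTable, scheme: str = "pooled"
) -> pd.DataFrame:
    """Rank AMR gene expression, descending (rank 1 = highest).

    ``pooled`` ranks every (gene, sample) value on one scale across the
    whole table, matching "highest expression across all samples"; each
    gene's per-sample rank is returned (genes x samples).  ``per_sample``
    ranks genes within each sample instead.  Ties get average ranks.
    """
    if len(table.features) < 2:
        raise ValueError("need at least 2 genes")
    X = table.values()
    if scheme == "pooled":
        flat = stats.rankdata(-X.ravel(), method="average")
        ranks = flat.reshape(X.shape)
    elif scheme == "per_sample":
        ranks = np.apply_along_axis(lambda col: stats.rankdata(-col), 0, X)
    else:
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    return pd.DataFrame(ranks, index=table.features, columns=table.samples)


def rank_shift_test(ranks_control: pd.Series, ranks_agp: pd.Series) -> RankShiftResult:
    """Paired t-test of per-gene mean-rank shifts between conditions.

    Inputs are per-gene summary ranks (e.g. mean pooled rank over each
    condition's samples) over the same gene set.  The paired difference is
    control minus AGP, so a positive mean shift means genes rank higher
    (smaller rank number) when AGPs are fed.  A constant nonzero shift has
    zero variance: the t statistic is infinite and p is reported as 0 with
    a warning flag.
    """
    if not ranks_control.index.equals(ranks_agp.index):
        ranks_agp = ranks_agp.reindex(ranks_control.index)
        if ranks_agp.isna().any():
            raise ValueError("gene sets differ between conditions")
    if len(ranks_control) < 3:
        raise ValueError("need at least 3 genes for the paired test")
    diffs = (ranks_control - ranks_agp).to_numpy(float)
    mean_shift = float(diffs.mean())
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            return RankShiftResult(("control", "agp"), 0.0, 0.0, 1.0, len(diffs))
        warnings.warn("constant rank shift: zero variance, p reported as 0")
        return RankShiftResult(
            ("control", "agp"),
            mean_shift,
            float(np.sign(mean_shift) * np.inf),
            0.0,
            len(diffs),
            zero_variance=True,
        )
    t, p = stats.ttest_rel(ranks_control.to_numpy(float), ranks_agp.to_numpy(float))
    return RankShiftResult(("control", "agp"), mean_shift, float(t), float(p), len(diffs))
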