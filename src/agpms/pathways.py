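"""Enzyme-level aggregation, enrichment and rarefaction of transcript data.

Transcript expression annotated with EC numbers is pooled per enzyme, with
each taxon's share of the pooled (untransformed) expression retained for
taxonomic-contribution profiles.  Enzyme significance propagates from
transcript-level differential expression (an enzyme is called as soon as one
of its transcripts is significant), pathway enrichment is an upper-tail
hypergeometric test over gene sets, and enzyme richness is rarefied by read
subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedTranscriptTable, bh_adjust

__all__ = [
    "EnzymeProfile",
    "PathwayEnrichment",
    "read_gmt",
    "write_gmt",
    "aggregate_enzymes",
    "enzyme_differential",
    "gsea_hypergeometric",
    "enzyme_rarefaction",
]

LOG2_PSEUDOCOUNT = 1.0


@dataclass
class EnzymeProfile:
    """Pooled expression of one enzyme under one condition, split by taxon."""

    ec: str
    condition: str
    mean_log2_expression: float
    taxon_shares: dict = field(default_factory=dict)
    n_transcripts: int = 0
    degenerate: bool = False  # all-zero expression; shares undefined


@dataclass
class PathwayEnrichment:
    pathway_id: str
    k_significant_in_set: int
    set_size: int
    total_significant: int
    universe_size: int
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read GMT (set name, description, member ids per line) into a dict."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Enzyme aggregation with taxonomic contributions
# ---------------------------------------------------------------------------

def aggregate_enzymes(
    table: AnnotatedTranscriptTable,
    sample_ids,
    condition: str,
    taxon_rank: str = "family",
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> list:
    """Per-enzyme pooled expression and taxon shares under one condition.

    For each EC, expression of all mapped transcripts is summed per sample,
    averaged over the condition's samples and log2-transformed with a
    pseudocount.  A transcript with several ECs contributes in full to each.
    Taxon shares are fractions of the pooled untransformed expression at
    ``taxon_rank``.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError(f"condition {condition!r} has no samples")
    ec_map = table.ec_map()
    if not ec_map:
        raise ValueError("no transcript carries an EC annotation")
    taxa = table.taxon_labels(taxon_rank)
    expr = table.expression[sample_ids]

    profiles = []
    for ec, tids in sorted(ec_map.items()):
        sub = expr.loc[tids]
        pooled_mean = float(sub.to_numpy().sum(axis=0).mean())
        by_taxon = sub.groupby(taxa.loc[tids]).sum().mean(axis=1)
        total = by_taxon.sum()
        if total > 0:
            shares = (by_taxon / total).to_dict()
            degenerate = False
        else:
            shares = {}
            degenerate = True
        profiles.append(
            EnzymeProfile(
                ec=ec,
                condition=condition,
                mean_log2_expression=float(np.log2(pooled_mean + pseudocount)),
                taxon_shares=shares,
                n_transcripts=len(tids),
                degenerate=degenerate,
            )
        )
    return profiles


def enzyme_differential(de: pd.DataFrame, ec_map: dict) -> pd.DataFrame:
    """Propagate transcript-level significance calls to enzymes.

    An enzyme is ``up`` if at least one significantly differentially
    expressed transcript mapped to it has positive log2fc, ``down`` for
    negative, ``both`` when it has significant transcripts in both
    directions, and ``ns`` otherwise.
    """
    de = de.set_index("feature_id")
    rows = []
    for ec, tids in sorted(ec_map.items()):
        present = [t for t in tids if t in de.index]
        sig = de.loc[present]
        sig = sig[sig["significant"]]
        n_up = int((sig["log2fc"] > 0).sum())
        n_down = int((sig["log2fc"] < 0).sum())
        if n_up and n_down:
            call = "both"
        elif n_up:
            call = "up"
        elif n_down:
            call = "down"
        else:
            call = "ns"
        rows.append(dict(ec=ec, call=call, n_up=n_up, n_down=n_down, n_transcripts=len(present)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

def gsea_hypergeometric(
    significant: set,
    universe: set,
    gene_sets: dict,
    min_set_size: int = 2,
    q_cutoff: float = 0.05,
) -> list:
    """Upper-tail hypergeometric enrichment of significant members per set.

    Sets are intersected with the universe first; sets with fewer than
    ``min_set_size`` members in the universe are dropped.  p = P(X >= k)
    for k significant members in a set of size s, with the universe of size
    N containing K significant elements overall; BH over retained sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    significant = set(significant) & universe
    K, N = len(significant), len(universe)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        s = len(members)
        if s < min_set_size:
            continue
        k = len(members & significant)
        # P(X >= k), X ~ Hypergeometric(N, K, s)
        p = float(stats.hypergeom.sf(k - 1, N, K, s))
        results.append(
            PathwayEnrichment(
                pathway_id=name,
                k_significant_in_set=k,
                set_size=s,
                total_significant=K,
                universe_size=N,
                p=min(p, 1.0),
            )
        )
    q = bh_adjust([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


# ---------------------------------------------------------------------------
# Enzyme rarefaction
# ---------------------------------------------------------------------------

def enzyme_rarefaction(
    table: AnnotatedTranscriptTable,
    depths,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean unique-EC richness per sample as a function of read depth.

    Expression is rounded to integer read counts; at each depth, reads are
    subsampled without replacement ``n_reps`` times per sample and the mean
    number of distinct EC numbers with at least one read is reported.
    Depths above a sample's total are truncated to the total with a warning.
    """
    rng = np.random.default_rng(seed)
    counts = np.round(table.expression.to_numpy()).astype(np.int64)
    ec_sets = [sorted(ecs) for ecs in table.annotations["ec_numbers"]]
    annotated = np.array([len(e) > 0 for e in ec_sets])

    rows = []
    for j, sid in enumerate(table.samples):
        y = counts[:, j]
        total = int(y.sum())
        for depth in depths:
            d = int(depth)
            if d > total:
                warnings.warn(
                    f"sample {sid!r}: depth {d} exceeds total {total}; truncated"
                )
                d = total
            richness = []
            for _ in range(n_reps):
                sub = rng.multivariate_hypergeometric(y, d)
                seen = set()
                for i in np.nonzero((sub > 0) & annotated)[0]:
                    seen.update(ec_sets[i])
                richness.append(len(seen))
            rows.append(
                dict(sample_id=sid, depth=int(depth), mean_unique_ec=float(np.mean(richness)))
            )
    return pd.DataFrame(rows)
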