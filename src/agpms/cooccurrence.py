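"""Differential Spearman co-occurrence networks between treatment groups.

Genus-level normalized abundances are filtered by central tendency (median
above a percentile of all genus medians), correlated within each treatment
group by Spearman rank, and pairs are compared between two groups with the
Fisher z statistic z_diff = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)), BH
adjusted over all tested pairs.
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable, bh_adjust

__all__ = [
    "central_tendency_filter",
    "spearman_with_p",
    "group_correlation_network",
    "differential_correlation",
]

EXACT_N_MAX = 8  # exact permutation null of rho up to this sample size


def central_tendency_filter(
    table: FeatureTable, percentile: float = 30.0
) -> FeatureTable:
    """Keep genera whose median abundance strictly exceeds the given
    percentile of all genus medians (DGCA ``filterGenes`` median method)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    medians = table.data.median(axis=1)
    cutoff = np.percentile(medians.to_numpy(), percentile)
    keep = medians > cutoff
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 genera exceed the {percentile}th percentile of medians"
        )
    return FeatureTable(table.data.loc[keep], kind=table.kind)


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Exact permutation null of Spearman rho for sample size n (no ties)."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    bc = base - base.mean()
    pc = perms - base.mean()
    denom = (bc**2).sum()
    return (pc @ bc) / denom


def spearman_with_p(x, y, exact_n_max: int = EXACT_N_MAX):
    """Spearman rho with a two-sided p-value.

    Exact permutation p for small samples (n <= ``exact_n_max``, no ties),
    t-approximation otherwise; returns (nan, nan) for constant input.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p_t = stats.spearmanr(x, y)
    n = len(x)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_n_max and not has_ties:
        null = _exact_rho_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_t)


def group_correlation_network(
    table: FeatureTable,
    groups,
    p_cutoff: float = 0.05,
    exact_n_max: int = EXACT_N_MAX,
) -> pd.DataFrame:
    """Within-group Spearman correlations for every genus pair.

    Returns one row per (group, pair) with rho, p and an ``edge`` flag
    (p < ``p_cutoff``).  Pairs involving a genus that is constant within a
    group are skipped with a warning.
    """
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    rows = []
    feats = table.features
    for g in pd.unique(groups):
        sel = groups[groups == g].index
        sub = table.data.loc[:, [s for s in table.samples if s in set(sel)]]
        if sub.shape[1] < 4:
            raise ValueError(f"group {g!r} has fewer than 4 samples")
        vals = sub.to_numpy()
        constant = [f for f, row in zip(feats, vals) if np.all(row == row[0])]
        if constant:
            warnings.warn(
                f"group {g!r}: skipping pairs with constant genera {constant[:5]}"
            )
        for i, j in itertools.combinations(range(len(feats)), 2):
            rho, p = spearman_with_p(vals[i], vals[j], exact_n_max)
            if np.isnan(rho):
                continue
            rows.append(
                dict(
                    group=g,
                    genus_a=feats[i],
                    genus_b=feats[j],
                    n=sub.shape[1],
                    rho=rho,
                    p=p,
                    edge=bool(p < p_cutoff),
                )
            )
    return pd.DataFrame(rows)


def differential_correlation(
    correlations: pd.DataFrame,
    group_pair: tuple,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Fisher-z differential correlation between two treatment groups.

    ``correlations`` is the output of :func:`group_correlation_network`;
    for every genus pair present in both groups,
    ``z_diff = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3))``
    with a two-sided normal p, BH adjusted over all pairs.  |rho| = 1 is
    clamped to 1 - 1e-6 with a warning.
    """
    g1, g2 = group_pair
    c1 = correlations[correlations["group"] == g1].set_index(["genus_a", "genus_b"])
    c2 = correlations[correlations["group"] == g2].set_index(["genus_a", "genus_b"])
    common = c1.index.intersection(c2.index)
    if len(common) == 0:
        raise ValueError("no genus pairs shared between the two groups")
    n1 = c1["n"].iloc[0]
    n2 = c2["n"].iloc[0]
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z requires more than 3 samples per group")

    def clamp(r):
        if np.abs(r) >= 1.0:
            warnings.warn("|rho| = 1 clamped for Fisher z transform")
            return np.sign(r) * (1.0 - 1e-6)
        return r

    rho1 = c1.loc[common, "rho"].map(clamp).to_numpy()
    rho2 = c2.loc[common, "rho"].map(clamp).to_numpy()
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_diff = (np.arctanh(rho1) - np.arctanh(rho2)) / se
    p = 2 * stats.norm.sf(np.abs(z_diff))
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "genus_a": [a for a, _ in common],
            "genus_b": [b for _, b in common],
            f"rho_{g1}": rho1,
            f"rho_{g2}": rho2,
            "z_diff": z_diff,
            "p": p,
            "q": q,
            "significant": q < q_cutoff,
        }
    )
    return out
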