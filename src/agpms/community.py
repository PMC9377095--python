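"""Alpha/beta diversity and permutation tests on community composition.

Shannon diversity, rarefaction, weighted UniFrac distances over a rooted
phylogeny, adonis-style sequential PERMANOVA and PERMDISP (dispersion
homogeneity).  Distances are held in :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats

from .core import FeatureTable

__all__ = [
    "PermTestResult",
    "shannon",
    "rarefy",
    "weighted_unifrac",
    "permanova",
    "permdisp",
    "pcoa_embedding",
]


@dataclass
class PermTestResult:
    """Result of a permutation test on a distance matrix."""

    term: str
    statistic: float  # pseudo-F
    r2: float | None
    p: float
    n_permutations: int

    def as_dict(self):
        return dict(
            term=self.term,
            statistic=self.statistic,
            r2=self.r2,
            p=self.p,
            n_permutations=self.n_permutations,
        )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(table: FeatureTable, base: float = 2.0) -> pd.Series:
    """Shannon index H = -sum p_i log_base p_i per sample.

    Zero-abundance features contribute nothing; an all-zero sample is an
    error (diversity undefined).
    """
    X = table.values()
    totals = X.sum(axis=0)
    zero = [s for s, t in zip(table.samples, totals) if t == 0]
    if zero:
        raise ValueError(f"all-zero samples: {zero}")
    P = X / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    H = -terms.sum(axis=0) / np.log(base)
    return pd.Series(H, index=table.samples, name="shannon")


def rarefy(table: FeatureTable, depth: int = 219, seed: int = 0) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` counts without replacement.

    Samples with fewer than ``depth`` total counts are dropped with a
    warning (the study retained as many samples as possible by rarefying to
    the smallest library, 219 reads).
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    X = np.round(table.values()).astype(np.int64)
    totals = X.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample has at least {depth} counts")
    dropped = [s for s, k in zip(table.samples, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}: {dropped}")
    rng = np.random.default_rng(seed)
    cols = {}
    for j, sid in enumerate(table.samples):
        if not keep[j]:
            continue
        cols[sid] = rng.multivariate_hypergeometric(X[:, j], depth)
    out = pd.DataFrame(cols, index=table.features)
    return FeatureTable(out, kind=table.kind)


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def weighted_unifrac(
    table: FeatureTable, tree: skbio.TreeNode, normalized: bool = False
) -> skbio.DistanceMatrix:
    """Weighted UniFrac distance between all sample pairs.

    For each branch i with length b_i, let p(i) be the fraction of a
    sample's total counts on leaves descending from that branch; then
    d(A, B) = sum_i b_i |p_A(i) - p_B(i)|.  With ``normalized`` the raw
    distance is divided by sum_j d_j (p_A(j) + p_B(j)) over leaves j at
    root-to-leaf depth d_j, scaling distances into [0, 1].
    """
    leaf_names = {leaf.name for leaf in tree.tips()}
    nonzero = table.data.index[(table.values() > 0).any(axis=1)]
    missing = [f for f in nonzero if f not in leaf_names]
    if missing:
        raise ValueError(f"features absent from tree: {missing[:10]}")

    rel = table.relative_abundance()
    samples = table.samples
    n = len(samples)

    # postorder accumulation of per-branch descendant mass
    branch_lengths = []
    branch_mass = []  # rows align with branch_lengths, columns = samples
    node_mass = {}
    leaf_depth = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mass = (
                rel.loc[node.name].to_numpy()
                if node.name in rel.index
                else np.zeros(n)
            )
        else:
            mass = np.zeros(n)
            for child in node.children:
                mass = mass + node_mass[id(child)]
        node_mass[id(node)] = mass
        if node.parent is not None:
            branch_lengths.append(node.length if node.length is not None else 0.0)
            branch_mass.append(mass)
    B = np.asarray(branch_mass)  # branches x samples
    L = np.asarray(branch_lengths)

    D = np.zeros((n, n))
    for i in range(n):
        diffs = np.abs(B[:, i, None] - B[:, i + 1 :])
        D[i, i + 1 :] = L @ diffs
    D = D + D.T

    if normalized:
        for leaf in tree.tips():
            d, node = 0.0, leaf
            while node.parent is not None:
                d += node.length if node.length is not None else 0.0
                node = node.parent
            leaf_depth[leaf.name] = d
        depth_vec = np.array(
            [leaf_depth.get(f, 0.0) for f in table.features]
        )
        sample_depth = depth_vec @ rel.to_numpy()  # abundance-weighted depth
        denom = sample_depth[:, None] + sample_depth[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(denom > 0, D / denom, 0.0)
    return skbio.DistanceMatrix(D, ids=samples)


# ---------------------------------------------------------------------------
# PERMANOVA (sequential, adonis-style) and PERMDISP
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    J = np.eye(D.shape[0]) - np.ones_like(A) / D.shape[0]
    return J @ A @ J


def _term_design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded (drop-first) columns for a term; 'a:b' is an interaction."""
    parts = term.replace("×", ":").split(":")
    mats = []
    for part in parts:
        part = part.strip()
        if part not in metadata.columns:
            raise ValueError(f"unknown metadata column {part!r}")
        col = metadata[part]
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"factor {part!r} has a single level")
        dummies = pd.get_dummies(col, drop_first=True).to_numpy(float)
        mats.append(dummies)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(
    dm: skbio.DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list,
    n_perm: int = 9999,
    seed: int = 0,
) -> list:
    """Sequential (Type-I) PERMANOVA over an ordered list of model terms.

    The distance-based total sum of squares is partitioned in the order
    given, so "factor B accounting for factor A" is realized by listing A
    before B.  Pseudo-F per term uses the residual from the full model;
    p-values come from permuting sample labels, p = (b + 1) / (m + 1).
    """
    ids = list(dm.ids)
    md = metadata.loc[ids]
    D = dm.data
    n = len(ids)
    G = _gower_center(D)
    total_ss = np.trace(G)

    designs = [_term_design(md, t) for t in terms]
    ones = np.ones((n, 1))
    hats, dfs = [], []
    X = ones
    prev_trace = np.trace(_hat(X) @ G)
    prev_rank = 1
    cum = []
    for Xt in designs:
        X = np.hstack([X, Xt])
        rank = np.linalg.matrix_rank(X)
        dfs.append(rank - prev_rank)
        cum.append(X)
        prev_rank = rank
    H_full = _hat(cum[-1])
    df_resid = n - prev_rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(Gm):
        ss, Fs = [], []
        prev = np.trace(_hat(ones) @ Gm)
        resid = np.trace((np.eye(n) - H_full) @ Gm)
        for Xc, df in zip(cum, dfs):
            cur = np.trace(_hat(Xc) @ Gm)
            ss_t = cur - prev
            prev = cur
            ss.append(ss_t)
            Fs.append((ss_t / df) / (resid / df_resid) if df > 0 else np.nan)
        return np.array(ss), np.array(Fs)

    ss_obs, F_obs = term_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, F_p = term_stats(G[np.ix_(perm, perm)])
        exceed += F_p >= F_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    return [
        PermTestResult(
            term=t,
            statistic=float(F_obs[i]),
            r2=float(ss_obs[i] / total_ss),
            p=float(pvals[i]),
            n_permutations=n_perm,
        )
        for i, t in enumerate(terms)
    ]


def pcoa_embedding(dm: skbio.DistanceMatrix) -> np.ndarray:
    """Principal-coordinate embedding; negative eigenvalues are dropped with
    a warning (non-Euclidean distances)."""
    G = _gower_center(dm.data)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals < -1e-8 * max(vals.max(), 1.0)).any():
        warnings.warn("negative PCoA eigenvalues dropped (non-Euclidean distances)")
    keep = vals > 1e-10 * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def permdisp(
    dm: skbio.DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermTestResult:
    """Homogeneity-of-dispersion test (PERMDISP) with centroid distances.

    Samples are embedded by principal coordinates; each sample's Euclidean
    distance to its group centroid is the response of a one-way ANOVA F,
    whose null distribution comes from permuting group labels.  When every
    group collapses to identical points the F is undefined and p = 1 is
    reported with a warning.
    """
    groups = pd.Series(list(groups), index=list(dm.ids))
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError(f"groups of size 1: {counts[counts < 2].index.tolist()}")
    coords = pcoa_embedding(dm)
    labels = groups.to_numpy()

    def centroid_distances(lbls):
        d = np.empty(len(lbls))
        for g in np.unique(lbls):
            mask = lbls == g
            cent = coords[mask].mean(axis=0)
            d[mask] = np.linalg.norm(coords[mask] - cent, axis=1)
        return d

    def anova_f(d, lbls):
        grand = d.mean()
        ss_b = ss_w = 0.0
        k = 0
        for g in np.unique(lbls):
            dg = d[lbls == g]
            ss_b += len(dg) * (dg.mean() - grand) ** 2
            ss_w += ((dg - dg.mean()) ** 2).sum()
            k += 1
        df_b, df_w = k - 1, len(d) - k
        if ss_w <= 1e-12 and ss_b <= 1e-12:
            return np.nan
        if ss_w <= 1e-12:
            return np.inf
        return (ss_b / df_b) / (ss_w / df_w)

    d_obs = centroid_distances(labels)
    F_obs = anova_f(d_obs, labels)
    if np.isnan(F_obs):
        warnings.warn("all centroid distances are zero; dispersion F undefined, p = 1")
        return PermTestResult("dispersion", float("nan"), None, 1.0, n_perm)

    # classic PERMDISP: the centroid distances are fixed and the group
    # labels are permuted against them
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        F_p = anova_f(d_obs, perm_labels)
        if not np.isnan(F_p) and F_p >= F_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return PermTestResult("dispersion", float(F_obs), None, float(p), n_perm)
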