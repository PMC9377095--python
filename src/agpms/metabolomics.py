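"""Serum metabolomics: PQN normalization, age-pattern correlation and
permutation factorial ANOVA.

Concentrations are normalized by the probabilistic quotient against a
reference sample (removing per-sample dilution), autoscaled per metabolite,
correlated against the ordinal age pattern 1-2-3 (days 10/24/40) by
Spearman rank, and tested metabolite-by-metabolite for diet, AGP and
diet x AGP effects with a permutation two-way ANOVA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable, bh_adjust

__all__ = [
    "pqn_normalize",
    "autoscale",
    "pattern_correlation",
    "perm_factorial_anova",
    "age_pattern_analysis",
]

AGE_PATTERN = {10: 1, 24: 2, 40: 3}


def pqn_normalize(table: FeatureTable, reference_sample: str) -> FeatureTable:
    """Probabilistic quotient normalization against one reference sample.

    Each sample is divided by the median over metabolites of its quotients
    against the reference; the reference maps to itself.  Removes a scalar
    dilution factor exactly whenever most metabolites are unchanged.
    """
    if reference_sample not in table.samples:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    ref = table.data[reference_sample]
    if (ref <= 0).any():
        raise ValueError("reference sample must be all-positive")
    quotients = table.data.div(ref, axis=0)
    factors = quotients.median(axis=0)
    return FeatureTable(table.data.div(factors, axis=1), kind=table.kind)


def autoscale(table: FeatureTable) -> pd.DataFrame:
    """Per-metabolite standardization (mean 0, SD 1 across samples).

    Returns a plain DataFrame since autoscaled values are signed.  Constant
    metabolites become all-zero rows with a warning.  Idempotent.
    """
    if len(table.samples) < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    X = table.data
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant metabolites set to zero: {X.index[constant].tolist()[:5]}"
        )
    sd = sd.mask(constant, 1.0)
    return X.sub(mean, axis=0).div(sd, axis=0)


def pattern_correlation(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of each metabolite with the age pattern 1-2-3.

    ``values`` is metabolites x samples (typically PQN + autoscaled);
    significance defaults to raw p < ``alpha`` (pattern-matching
    convention), with optional BH adjustment.  Constant metabolites are
    skipped with a warning.
    """
    md = metadata.loc[values.columns]
    if md["age_days"].nunique() < 2:
        raise ValueError("need at least 2 distinct ages")
    codes = md["age_days"].map(AGE_PATTERN).to_numpy(float)
    rows = []
    skipped = []
    for met, row in values.iterrows():
        x = row.to_numpy(float)
        if np.all(x == x[0]):
            skipped.append(met)
            continue
        rho, p = stats.spearmanr(x, codes)
        rows.append(dict(metabolite=met, rho=float(rho), p=float(p)))
    if skipped:
        warnings.warn(f"skipped constant metabolites: {skipped[:5]}")
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    crit = out["q"] if adjust else out["p"]
    out["significant"] = crit < alpha
    out["direction"] = np.where(out["rho"] >= 0, "increasing", "decreasing")
    return out


def _two_way_f(y: np.ndarray, d1: np.ndarray, d2: np.ndarray):
    """F statistics (diet, agp, interaction) of a two-way layout.

    Projection-based sums of squares; in the balanced designs simulated
    here, sequential and marginal decompositions coincide.
    """
    n = y.size
    ones = np.ones((n, 1))

    def proj_ss(X):
        Q, _ = np.linalg.qr(X)
        fitted = Q @ (Q.T @ y)
        return fitted @ fitted

    X1 = np.column_stack([ones, d1])
    X12 = np.column_stack([ones, d1, d2])
    Xfull = np.column_stack([ones, d1, d2, d1 * d2])
    ss0 = proj_ss(ones)
    ss_d1 = proj_ss(X1) - ss0
    ss_d2 = proj_ss(X12) - proj_ss(X1)
    ss_int = proj_ss(Xfull) - proj_ss(X12)
    ss_res = y @ y - proj_ss(Xfull)
    df_res = n - 4
    if ss_res <= 1e-300 or df_res <= 0:
        return np.array([np.nan, np.nan, np.nan])
    ms_res = ss_res / df_res
    return np.array([ss_d1, ss_d2, ss_int]) / ms_res


def perm_factorial_anova(
    table,
    metadata: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation two-way ANOVA (diet, AGP, interaction) per metabolite.

    The observed F of each term is compared with its distribution under
    random permutation of the response across samples (one shared set of
    permutations for all metabolites); p = (b + 1) / (m + 1), BH adjusted
    across metabolites within each term.  Constant metabolites get p = 1.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    md = metadata.loc[data.columns]
    d1 = (md["diet"] == "wheat").to_numpy(float)
    d2 = md["agp"].to_numpy(float)
    for name, v in (("diet", d1), ("agp", d2)):
        if len(np.unique(v)) < 2:
            raise ValueError(f"factor {name} has a single level")
    cells = pd.crosstab(md["diet"], md["agp"])
    if (cells == 0).any().any():
        raise ValueError("empty cell in the 2x2 diet x AGP design")

    n = data.shape[1]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    terms = ("diet", "agp", "interaction")
    rows = []
    for met, row in data.iterrows():
        y = row.to_numpy(float)
        y = y - y.mean()
        if np.allclose(y, 0):
            rows.append(dict(metabolite=met, **{f"p_{t}": 1.0 for t in terms}))
            continue
        f_obs = _two_way_f(y, d1, d2)
        exceed = np.zeros(3)
        valid = 0
        for perm in perms:
            f_p = _two_way_f(y[perm], d1, d2)
            if np.isnan(f_p).any():
                continue
            valid += 1
            exceed += f_p >= f_obs - 1e-12
        p = (exceed + 1) / (valid + 1)
        rows.append(dict(metabolite=met, **dict(zip([f"p_{t}" for t in terms], p))))
    out = pd.DataFrame(rows)
    for t in terms:
        out[f"q_{t}"] = bh_adjust(out[f"p_{t}"].to_numpy())
        out[f"significant_{t}"] = out[f"q_{t}"] <= 0.05
    return out


def age_pattern_analysis(
    table: FeatureTable,
    metadata: pd.DataFrame,
    reference_by_arm: dict | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> dict:
    """PQN + autoscale + age-pattern correlation, run per treatment arm.

    ``reference_by_arm`` maps an arm label (``"control"`` / ``"agp"``) to
    the reference sample id for PQN in that arm; by default the first sample
    of each arm is used.  Returns per-arm pattern-correlation tables, the
    study's route to counting age-correlated metabolites separately in
    control and AGP birds.
    """
    md = metadata.loc[table.samples]
    out = {}
    for arm, mask in (("control", ~md["agp"]), ("agp", md["agp"])):
        sids = md.index[mask].tolist()
        if not sids:
            continue
        sub = table.filter_samples(sids)
        ref = (reference_by_arm or {}).get(arm, sids[0])
        normalized = pqn_normalize(sub, ref)
        scaled = autoscale(normalized)
        out[arm] = pattern_correlation(scaled, md, alpha=alpha, adjust=adjust)
    return out
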