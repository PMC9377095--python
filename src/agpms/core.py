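"""Shared domain types, table I/O and cross-cutting statistical utilities.

The central container is :class:`FeatureTable`, a features-by-samples matrix
of nonnegative counts or expression values, stored with features as rows and
samples as columns (the common OTU-table orientation).  Sample metadata is a
:class:`pandas.DataFrame` indexed by sample id with the study design columns
``diet`` (corn/wheat), ``agp`` (bool), ``age_days`` (10/24/40), ``site`` and
``bird_id``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "DIETS",
    "SITES",
    "AGES",
    "Lineage",
    "FeatureTable",
    "AnnotatedTranscriptTable",
    "DifferentialResult",
    "validate_metadata",
    "read_metadata",
    "read_feature_table",
    "write_feature_table",
    "collapse_to_rank",
    "bh_adjust",
    "pca_scores",
]

#: Taxonomic ranks, highest to lowest, used by :class:`Lineage`.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

DIETS = ("corn", "wheat")
SITES = ("gizzard", "duodenum", "jejunum", "ileum", "ceca", "colon")
AGES = (10, 24, 40)


@dataclass(frozen=True)
class Lineage:
    """A taxonomic assignment from domain down to genus.

    ``ranks`` maps rank name to taxon name; assignments must form a
    contiguous prefix of :data:`RANKS` (a taxon cannot be assigned at genus
    while unassigned at family).  ``confidence`` is the classifier's
    confidence for the deepest assigned rank.
    """

    ranks: dict = field(default_factory=dict)
    confidence: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        unknown = set(self.ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown rank names: {sorted(unknown)}")
        seen_gap = False
        for r in RANKS:
            if r in self.ranks:
                if seen_gap:
                    raise ValueError(
                        "lineage has a gap: rank assigned below an unassigned rank"
                    )
            else:
                seen_gap = True

    def at(self, rank: str) -> str | None:
        """Name at ``rank``, or None when unassigned there."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.ranks.get(rank)

    def nearest_classified_ancestor(self, rank: str) -> str | None:
        """Deepest assigned name strictly above ``rank``; None if fully unassigned."""
        idx = RANKS.index(rank)
        for r in reversed(RANKS[:idx]):
            if r in self.ranks:
                return self.ranks[r]
        return None


class FeatureTable:
    """Features x samples matrix of nonnegative values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.
    kind : str
        One of ``otu_counts``, ``transcript_counts``, ``expression``.
        Count kinds must hold integral values.
    """

    KINDS = ("otu_counts", "transcript_counts", "expression")

    def __init__(self, data: pd.DataFrame, kind: str = "otu_counts"):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if any(str(i) == "" for i in data.index) or any(
            str(c) == "" for c in data.columns
        ):
            raise ValueError("feature and sample ids must be nonempty")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("table contains missing values")
        if (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative entries in features: {bad[:10]}")
        if kind.endswith("counts") and not np.allclose(values, np.round(values)):
            raise ValueError(f"kind={kind!r} requires integral values")
        self.data = data.astype(float)
        self.kind = kind

    # -- basic introspection -------------------------------------------------
    @property
    def features(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; errors on all-zero samples."""
        totals = self.sample_totals()
        zero = totals[totals == 0].index.tolist()
        if zero:
            raise ValueError(f"samples with zero total: {zero}")
        return self.data / totals

    def filter_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)], kind=self.kind)

    def filter_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids), :], kind=self.kind)

    def __eq__(self, other):
        return (
            isinstance(other, FeatureTable)
            and self.kind == other.kind
            and self.data.equals(other.data)
        )

    def __repr__(self):
        nf, ns = self.data.shape
        return f"<FeatureTable kind={self.kind} {nf} features x {ns} samples>"


_EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


class AnnotatedTranscriptTable:
    """Transcript expression with taxon lineage, EC and ortholog annotation.

    Parameters
    ----------
    annotations : pandas.DataFrame
        Indexed by transcript id, with columns ``lineage`` (:class:`Lineage`),
        ``ec_numbers`` (frozenset of EC strings, possibly empty) and
        ``ortholog_id`` (string or None).
    expression : pandas.DataFrame
        Transcripts x samples, nonnegative; index must match ``annotations``.
    """

    def __init__(self, annotations: pd.DataFrame, expression: pd.DataFrame):
        if not annotations.index.equals(expression.index):
            raise ValueError("annotation and expression indices differ")
        if annotations.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        vals = expression.to_numpy(dtype=float)
        if (vals < 0).any() or np.isnan(vals).any():
            raise ValueError("expression must be nonnegative and complete")
        for tid, ecs in annotations["ec_numbers"].items():
            for ec in ecs:
                if not _EC_PATTERN.match(ec):
                    raise ValueError(f"malformed EC {ec!r} on transcript {tid}")
        self.annotations = annotations
        self.expression = expression.astype(float)

    @property
    def transcripts(self) -> list:
        return list(self.annotations.index)

    @property
    def samples(self) -> list:
        return list(self.expression.columns)

    def taxon_labels(self, rank: str = "genus") -> pd.Series:
        """Per-transcript taxon name at ``rank`` with unclassified bucketing."""
        out = {}
        for tid, lin in self.annotations["lineage"].items():
            name = lin.at(rank)
            if name is None:
                anc = lin.nearest_classified_ancestor(rank)
                name = f"unclassified_{anc}" if anc is not None else "unclassified"
            out[tid] = name
        return pd.Series(out, name=rank).reindex(self.annotations.index)

    def ec_map(self) -> dict:
        """EC -> list of transcript ids mapped to it."""
        mapping: dict = {}
        for tid, ecs in self.annotations["ec_numbers"].items():
            for ec in ecs:
                mapping.setdefault(ec, []).append(tid)
        return mapping

    def __repr__(self):
        nt, ns = self.expression.shape
        return f"<AnnotatedTranscriptTable {nt} transcripts x {ns} samples>"


@dataclass
class DifferentialResult:
    """Per-feature effect estimate with raw and BH-adjusted p-values."""

    feature_id: str
    log2fc: float
    base_mean: float
    p: float
    q: float
    significant: bool

    @staticmethod
    def frame(results: list) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    feature_id=r.feature_id,
                    log2fc=r.log2fc,
                    base_mean=r.base_mean,
                    p=r.p,
                    q=r.q,
                    significant=r.significant,
                )
                for r in results
            ]
        )


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return a typed copy.

    The index is the sample id (unique).  Expected columns: ``diet``,
    ``agp`` (boolean), ``age_days``, ``site``, ``bird_id``; extra columns
    pass through untouched.
    """
    md = metadata.copy()
    if md.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if "diet" in md:
        bad = set(md["diet"].unique()) - set(DIETS)
        if bad:
            raise ValueError(f"unknown diet values: {sorted(bad)}")
    if "agp" in md:
        md["agp"] = md["agp"].astype(bool)
    if "age_days" in md:
        md["age_days"] = md["age_days"].astype(int)
        bad = set(md["age_days"].unique()) - set(AGES)
        if bad:
            raise ValueError(f"unexpected ages: {sorted(bad)}")
    if "site" in md:
        bad = set(md["site"].unique()) - set(SITES)
        if bad:
            raise ValueError(f"unknown GI sites: {sorted(bad)}")
    return md


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(md)


# ---------------------------------------------------------------------------
# Feature-table I/O: TSV (features x samples) and BIOM JSON (format 1.0)
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv", kind: str = "otu_counts") -> FeatureTable:
    """Read a feature table from ``tsv`` or ``biom-json``.

    TSV layout: first column feature ids, header row sample ids.  BIOM JSON
    follows the format-1.0 specification (dense or sparse), with rows as
    features and columns as samples; row/column order is preserved.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # surface the offending location
            raise ValueError(f"could not parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return FeatureTable(df, kind=kind)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(rows), len(cols)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        return FeatureTable(pd.DataFrame(mat, index=rows, columns=cols), kind=kind)
    raise ValueError(f"unknown format {format!r}")


def write_feature_table(table: FeatureTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.data.to_csv(path, sep="\t")
        return
    if format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "agpms",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": list(table.shape),
            "rows": [{"id": f, "metadata": None} for f in table.features],
            "columns": [{"id": s, "metadata": None} for s in table.samples],
            "data": table.values().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Rank collapsing
# ---------------------------------------------------------------------------

def collapse_to_rank(table: FeatureTable, taxonomy: dict, rank: str) -> FeatureTable:
    """Sum features into taxa at ``rank``; per-sample totals are conserved.

    Features unassigned at ``rank`` are bucketed as
    ``unclassified_<nearest classified ancestor>`` (or plain ``unclassified``
    when the lineage is empty), one bucket per distinct ancestor, so that
    "other Clostridiales"-style groups are reproducible.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    missing = [f for f in table.features if f not in taxonomy]
    if missing:
        raise ValueError(f"features with no lineage: {missing[:10]}")

    labels = []
    for f in table.features:
        lin = taxonomy[f]
        name = lin.at(rank)
        if name is None:
            anc = lin.nearest_classified_ancestor(rank)
            name = f"unclassified_{anc}" if anc is not None else "unclassified"
        labels.append(name)
    grouped = table.data.groupby(pd.Index(labels, name=rank), sort=False).sum()
    return FeatureTable(grouped, kind=table.kind)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving.

    Families are the caller's responsibility: pass exactly the p-values of
    one test family (one contrast or model term) per call.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward (step-up)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# PCA sample scores
# ---------------------------------------------------------------------------

def pca_scores(table: FeatureTable, center: bool = True, scale: bool = False):
    """Principal-component scores of samples over features.

    Samples are the observations (rows of the internal data matrix after
    transposition).  Returns ``(scores, explained)`` where ``scores`` is a
    samples x components DataFrame and ``explained`` the fraction of total
    variance per component (sums to 1 when all components are kept).
    Constant matrices yield all-zero scores with a warning.
    """
    X = table.values().T  # samples x features
    n, pdim = X.shape
    if n < 2 or pdim < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if np.allclose(X, 0):
        warnings.warn("constant matrix: all principal-component scores are zero")
        k = min(n - 1, pdim)
        scores = pd.DataFrame(
            np.zeros((n, k)),
            index=table.samples,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        return scores, np.zeros(k)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = min(n - 1, pdim)
    var = s[:keep] ** 2 / (n - 1)
    explained = var / (s**2 / (n - 1)).sum()
    scores = pd.DataFrame(
        U[:, :keep] * s[:keep],
        index=table.samples,
        columns=[f"PC{i+1}" for i in range(keep)],
    )
    return scores, explained
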