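"""Projection of transcript expression onto a reference interaction network.

Transcripts are mapped to ortholog groups (nodes of a published E. coli
functional-interaction network) through tabular homology hits filtered by
the dual-branch rule: (alignment length > 100 and bit score > 60) OR
(identity > 85% and overlap > 65%), all comparisons strict.  Node mass is
the summed expression of mapped transcripts; taxon shares and per-taxon
subnetworks support "who expresses what" displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core import AnnotatedTranscriptTable

__all__ = [
    "HIT_COLUMNS",
    "NetworkProjection",
    "read_hits",
    "filter_hits",
    "project_expression",
    "species_subnetwork",
]

#: BLAST outfmt-6 columns plus the two extras the filter needs.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "overlap_pct",
    "subject_length",
]


def read_hits(path) -> pd.DataFrame:
    """Read a tab-separated homology hit table (outfmt 6 + overlap, slen)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    for col in ("pident", "overlap_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    if (df["length"] < 0).any():
        raise ValueError("negative alignment length")
    return df


def filter_hits(
    hits: pd.DataFrame,
    min_length: float = 100.0,
    min_bitscore: float = 60.0,
    min_identity: float = 85.0,
    min_overlap: float = 65.0,
) -> pd.DataFrame:
    """Keep hits passing either acceptance branch, one best hit per query.

    Branch 1: length > ``min_length`` AND bitscore > ``min_bitscore``.
    Branch 2: identity > ``min_identity`` AND overlap > ``min_overlap``.
    All comparisons are strict, so boundary values fail.  Among surviving
    hits of a query, the best is kept (highest bitscore, ties broken by
    identity, then lexicographic subject id) to prevent double counting.
    """
    branch1 = (hits["length"] > min_length) & (hits["bitscore"] > min_bitscore)
    branch2 = (hits["pident"] > min_identity) & (hits["overlap_pct"] > min_overlap)
    surv = hits[branch1 | branch2]
    if surv.empty:
        return surv.copy()
    surv = surv.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
    )
    return surv.groupby("qseqid", as_index=False, sort=False).head(1).reset_index(drop=True)


@dataclass
class NetworkProjection:
    """Expression mass projected onto a reference network.

    ``node_mass`` maps ortholog group -> total expression; ``taxon_shares``
    maps node -> {taxon: fraction}; ``calls`` optionally maps node ->
    up/down/both/ns per contrast.
    """

    graph: nx.Graph
    node_mass: dict
    taxon_shares: dict = field(default_factory=dict)
    calls: dict = field(default_factory=dict)

    def to_frames(self):
        nodes = pd.DataFrame(
            [
                dict(node=n, mass=self.node_mass.get(n, 0.0), call=self.calls.get(n, "ns"))
                for n in self.graph.nodes
            ]
        )
        edges = pd.DataFrame(list(self.graph.edges), columns=["node_a", "node_b"])
        return nodes, edges


def project_expression(
    table: AnnotatedTranscriptTable,
    mapping: dict,
    network: nx.Graph,
    sample_ids,
    taxon_rank: str = "family",
    de: pd.DataFrame | None = None,
) -> NetworkProjection:
    """Sum mapped transcript expression onto network nodes.

    ``mapping`` is transcript id -> ortholog group (from
    :func:`filter_hits`); mappings to groups absent from the network are
    dropped with a log entry implied by their absence.  Nodes without mapped
    transcripts are retained at zero mass.  When transcript-level
    differential results ``de`` are given, each node is called up/down/both/
    ns by the same propagation rule as enzymes.
    """
    sample_ids = list(sample_ids)
    taxa = table.taxon_labels(taxon_rank)
    mass = {n: 0.0 for n in network.nodes}
    shares: dict = {n: {} for n in network.nodes}
    node_tx: dict = {n: [] for n in network.nodes}
    for tid, node in mapping.items():
        if node not in mass or tid not in table.expression.index:
            continue
        expr = float(table.expression.loc[tid, sample_ids].sum())
        mass[node] += expr
        shares[node][taxa.loc[tid]] = shares[node].get(taxa.loc[tid], 0.0) + expr
        node_tx[node].append(tid)
    for node, contrib in shares.items():
        total = sum(contrib.values())
        if total > 0:
            shares[node] = {t: v / total for t, v in contrib.items()}

    calls = {}
    if de is not None:
        det = de.set_index("feature_id")
        for node, tids in node_tx.items():
            present = [t for t in tids if t in det.index]
            sig = det.loc[present]
            sig = sig[sig["significant"]]
            n_up = int((sig["log2fc"] > 0).sum())
            n_down = int((sig["log2fc"] < 0).sum())
            calls[node] = (
                "both" if n_up and n_down else "up" if n_up else "down" if n_down else "ns"
            )
    return NetworkProjection(graph=network, node_mass=mass, taxon_shares=shares, calls=calls)


def species_subnetwork(projection: NetworkProjection, taxon: str) -> NetworkProjection:
    """Restrict node masses to one taxon's contribution.

    Nodes where the taxon contributes nothing keep mass 0 (the organism
    lacked detectable homologs for that ortholog group).  Unknown taxa —
    never seen in any node's shares — are an error.
    """
    seen = set()
    for contrib in projection.taxon_shares.values():
        seen.update(contrib)
    if taxon not in seen:
        raise ValueError(f"taxon {taxon!r} contributes to no node")
    mass = {
        n: projection.node_mass[n] * projection.taxon_shares.get(n, {}).get(taxon, 0.0)
        for n in projection.graph.nodes
    }
    shares = {n: ({taxon: 1.0} if mass[n] > 0 else {}) for n in projection.graph.nodes}
    return NetworkProjection(
        graph=projection.graph, node_mass=mass, taxon_shares=shares, calls=projection.calls
    )
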