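"""Synthetic data with planted effects for every pipeline input.

Emulates a 2 diets (corn/wheat) x 2 AGP (+/-) x 3 ages (10/24/40 days)
broiler-chicken factorial, with distinct birds sacrificed at each age.
Generators produce:

* an OTU count table (negative-binomial counts with planted diet, AGP and
  interaction fold changes), a taxonomy and a random bifurcating tree;
* an annotated transcript table in which selected (taxon, pathway) pairs
  carry pathway-specific expression shifts decoupled from taxon abundance;
* a serum metabolite table in which a subset of metabolites trends
  monotonically with age in untreated birds only, under per-sample dilution;
* a homology-hit table with known true homologs and decoys around the
  hit-filter thresholds.

Every generator is a pure function of its design and seed: the same seed
yields byte-identical outputs.  Ground truth for all planted structure is
returned alongside each table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .core import AnnotatedTranscriptTable, FeatureTable, Lineage

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "make_metadata",
    "simulate_community",
    "simulate_metatranscriptome",
    "simulate_metabolome",
    "simulate_homology_hits",
]

TERMS = ("diet", "agp", "interaction")


@dataclass
class SimulationDesign:
    """Parameters of the simulated factorial study.

    Defaults give the toy scale used throughout the test suite: 2 birds per
    diet x AGP x age cell (24 samples per gut site), 200 taxa with NB
    dispersion 0.1, planted twofold-squared (log2fc = 2) effects in 10% of
    taxa per main effect and 5% for the interaction.
    """

    n_birds_per_arm: int = 2
    n_taxa: int = 200
    n_transcripts_per_taxon: int = 5
    effect_log2fc: float = 2.0
    frac_diet_affected: float = 0.1
    frac_agp_affected: float = 0.1
    frac_interaction: float = 0.05
    dispersion: float = 0.1
    library_size_range: tuple = (5000, 20000)
    seed: int = 0

    def __post_init__(self):
        fracs = (
            self.frac_diet_affected + self.frac_agp_affected + self.frac_interaction
        )
        for name in ("frac_diet_affected", "frac_agp_affected", "frac_interaction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if fracs > 1.0 + 1e-12:
            raise ValueError("affected fractions must sum to at most 1")
        if self.n_birds_per_arm < 1 or self.n_taxa < 2:
            raise ValueError("need at least 1 bird per arm and 2 taxa")
        if self.n_transcripts_per_taxon < 1:
            raise ValueError("need at least 1 transcript per taxon")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library size range")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")

    def rng_streams(self) -> dict:
        """Named, independent random substreams derived from the seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("taxonomy", "community", "transcriptome", "metabolome", "homology")
        return dict(zip(names, (np.random.default_rng(c) for c in ss.spawn(len(names)))))


@dataclass
class GroundTruth:
    """Planted truth records for one simulated dataset."""

    taxon_log2fc: pd.DataFrame | None = None  # taxa x (diet, agp, interaction)
    transcript_log2fc: pd.DataFrame | None = None
    pathway_flags: pd.DataFrame | None = None  # columns: taxon, pathway, log2fc
    metabolite_slopes: pd.DataFrame | None = None  # per metabolite, per arm
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Study layout
# ---------------------------------------------------------------------------

def make_metadata(design: SimulationDesign, site: str = "ceca") -> pd.DataFrame:
    """Sample sheet for the full 2x2x3 factorial at one gut site."""
    rows = []
    bird = 0
    for diet in ("corn", "wheat"):
        for agp in (False, True):
            for age in (10, 24, 40):
                for _ in range(design.n_birds_per_arm):
                    bird += 1
                    arm = f"{diet}{'+agp' if agp else ''}"
                    sid = f"{arm}_d{age}_b{bird:03d}"
                    rows.append(
                        dict(
                            sample_id=sid,
                            diet=diet,
                            agp=agp,
                            age_days=age,
                            site=site,
                            bird_id=f"bird{bird:03d}",
                        )
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _make_taxonomy(design: SimulationDesign, rng: np.random.Generator):
    """Hierarchical lineages with multi-OTU genera and ~10% genus-unassigned."""
    n = design.n_taxa
    otu_ids = [f"OTU{i:04d}" for i in range(n)]
    n_genera = max(2, n // 3)
    taxonomy = {}
    genus_of = {}
    for i, otu in enumerate(otu_ids):
        g = int(rng.integers(n_genera))
        fam, order = g // 3, g // 9
        ranks = {
            "domain": "Bacteria",
            "phylum": f"p{order // 3:02d}",
            "class": f"c{order // 2:02d}",
            "order": f"o{order:02d}",
            "family": f"f{fam:02d}",
            "genus": f"g{g:03d}",
        }
        if rng.random() < 0.1:  # 16S resolution gap: family-level only
            ranks.pop("genus")
        taxonomy[otu] = Lineage(ranks=ranks, confidence=float(rng.uniform(0.9, 1.0)))
        genus_of[otu] = ranks.get("genus", f"unclassified_{ranks['family']}")
    return otu_ids, taxonomy, genus_of


def _random_tree(otu_ids, rng: np.random.Generator) -> skbio.TreeNode:
    """Random bifurcating tree with uniform(0.1, 1) branch lengths."""
    ids = list(otu_ids)
    rng.shuffle(ids)

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        split = int(rng.integers(1, len(leaves)))
        left = build(leaves[:split])
        right = build(leaves[split:])
        bl, br = rng.uniform(0.1, 1.0, size=2)
        return f"({left}:{bl:.6f},{right}:{br:.6f})"

    newick = build(ids) + ";"
    return skbio.TreeNode.read(io.StringIO(newick))


def _planted_effects(design: SimulationDesign, otu_ids, rng) -> pd.DataFrame:
    """Disjoint per-term affected taxa with log2fc of random sign."""
    n = len(otu_ids)
    counts = {
        "diet": int(round(design.frac_diet_affected * n)),
        "agp": int(round(design.frac_agp_affected * n)),
        "interaction": int(round(design.frac_interaction * n)),
    }
    order = rng.permutation(n)
    fc = pd.DataFrame(0.0, index=otu_ids, columns=list(TERMS))
    pos = 0
    for term in TERMS:
        chosen = order[pos : pos + counts[term]]
        pos += counts[term]
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        fc.iloc[chosen, fc.columns.get_loc(term)] = signs * design.effect_log2fc
    return fc


def _nb_draw(rng, mu, alpha):
    """NB(mu, variance mu + alpha*mu^2) draws; Poisson in the alpha->0 limit."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_community(design: SimulationDesign, site: str = "ceca"):
    """OTU counts, taxonomy, tree and truth for the 16S arm of the study.

    Counts follow NB(mu_ij, alpha) with
    ``mu_ij = baseline_i * L_j * 2**(x_j . beta_i)`` where ``x_j`` codes
    wheat diet, AGP and their product and ``L_j`` is a per-sample library
    size drawn uniformly from ``library_size_range``.
    """
    if design.n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    streams = design.rng_streams()
    rng_tax, rng = streams["taxonomy"], streams["community"]
    otu_ids, taxonomy, _ = _make_taxonomy(design, rng_tax)
    tree = _random_tree(otu_ids, rng_tax)
    metadata = make_metadata(design, site=site)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=design.n_taxa)
    base = base / base.sum()
    effects = _planted_effects(design, otu_ids, rng)
    lo, hi = design.library_size_range
    lib = rng.integers(lo, hi + 1, size=len(metadata))

    diet = (metadata["diet"] == "wheat").to_numpy(float)
    agp = metadata["agp"].to_numpy(float)
    design_x = np.stack([diet, agp, diet * agp])  # 3 x samples
    logfc = effects.to_numpy() @ design_x  # taxa x samples, in log2 units
    mu = base[:, None] * lib[None, :] * np.exp2(logfc)
    counts = _nb_draw(rng, mu, design.dispersion)

    table = FeatureTable(
        pd.DataFrame(counts, index=otu_ids, columns=metadata.index),
        kind="otu_counts",
    )
    truth = GroundTruth(taxon_log2fc=effects, extras={"metadata": metadata})
    return table, taxonomy, tree, truth


# ---------------------------------------------------------------------------
# Metatranscriptome
# ---------------------------------------------------------------------------

def simulate_metatranscriptome(
    design: SimulationDesign,
    pathways: dict,
    n_flagged_pairs: int = 3,
    noise_sigma: float = 0.3,
    couple_to_abundance: bool = True,
):
    """Annotated transcript expression with pathway-specific regulation.

    Each simulated taxon contributes ``n_transcripts_per_taxon`` transcripts
    carrying its lineage, 0-2 EC numbers drawn from the pathway definitions
    plus a background pool, and (with probability 0.3) an ortholog id.
    Baseline expression is lognormal.  Taxon-level (global) fold changes are
    the community truth when ``couple_to_abundance``; on top of that,
    ``n_flagged_pairs`` randomly chosen (taxon, pathway) pairs receive an
    AGP-conditional shift of ``effect_log2fc`` applied only to transcripts
    mapped to that pathway, while the taxon's abundance and other transcripts
    stay at baseline — regulation decoupled from abundance.
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    streams = design.rng_streams()
    rng_tax, rng = streams["taxonomy"], streams["transcriptome"]
    otu_ids, taxonomy, genus_of = _make_taxonomy(design, rng_tax)
    _random_tree(otu_ids, rng_tax)  # keep the taxonomy stream aligned with 16S
    metadata = make_metadata(design)

    all_ecs = sorted(set().union(*pathways.values()))
    background_ecs = [f"9.9.{i}.{j}" for i in range(1, 6) for j in range(1, 6)]
    ec_pool = all_ecs + background_ecs

    # taxon-level global effects (shared planting scheme with the community)
    effects = _planted_effects(design, otu_ids, rng) if couple_to_abundance else (
        pd.DataFrame(0.0, index=otu_ids, columns=list(TERMS))
    )

    records, expr_rows, tx_logfc = [], [], []
    diet = (metadata["diet"] == "wheat").to_numpy(float)
    agp = metadata["agp"].to_numpy(float)
    design_x = np.stack([diet, agp, diet * agp])

    # decoupled (genus, pathway) flags: exclude taxa with planted global effects
    genera = sorted({genus_of[o] for o in otu_ids if not genus_of[o].startswith("unclassified")})
    unaffected = [
        g
        for g in genera
        if all(
            effects.loc[o].eq(0).all() for o in otu_ids if genus_of[o] == g
        )
    ]
    pathway_names = sorted(pathways)
    n_flags = min(n_flagged_pairs, len(unaffected))
    flag_taxa = rng.choice(unaffected, size=n_flags, replace=False) if n_flags else []
    flags = pd.DataFrame(
        [
            dict(
                taxon=t,
                pathway=pathway_names[int(rng.integers(len(pathway_names)))],
                log2fc=design.effect_log2fc,
            )
            for t in flag_taxa
        ],
        columns=["taxon", "pathway", "log2fc"],
    )
    flag_lookup = {(r.taxon, r.pathway): r.log2fc for r in flags.itertuples()}

    flagged_pathway_of = dict(zip(flags["taxon"], flags["pathway"]))

    k = 0
    for otu in otu_ids:
        genus = genus_of[otu]
        taxon_fc = effects.loc[otu].to_numpy()
        for j in range(design.n_transcripts_per_taxon):
            tid = f"TX{k:05d}"
            k += 1
            n_ec = int(rng.choice([0, 1, 1, 2]))
            ecs = frozenset(
                rng.choice(ec_pool, size=n_ec, replace=False).tolist()
            )
            if j == 0 and genus in flagged_pathway_of:
                # guarantee the flagged pair has pathway-mapped transcripts
                members = sorted(pathways[flagged_pathway_of[genus]])
                ecs = ecs | {members[int(rng.integers(len(members)))]}
            ortho = f"OG_{int(rng.integers(40)):03d}" if rng.random() < 0.3 else None
            base = rng.lognormal(mean=3.0, sigma=1.0)
            fc = taxon_fc.copy()
            for pw, members in pathways.items():
                if ecs & set(members) and (genus, pw) in flag_lookup:
                    fc[1] += flag_lookup[(genus, pw)]  # AGP-conditional shift
            log2_shift = fc @ design_x
            noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=len(metadata))
            expr_rows.append(base * np.exp2(log2_shift) * noise)
            records.append(
                dict(
                    transcript_id=tid,
                    lineage=taxonomy[otu],
                    ec_numbers=ecs,
                    ortholog_id=ortho,
                )
            )
            tx_logfc.append(dict(transcript_id=tid, diet=fc[0], agp=fc[1], interaction=fc[2]))

    annotations = pd.DataFrame(records).set_index("transcript_id")
    expression = pd.DataFrame(
        np.asarray(expr_rows), index=annotations.index, columns=metadata.index
    )
    table = AnnotatedTranscriptTable(annotations, expression)
    truth = GroundTruth(
        transcript_log2fc=pd.DataFrame(tx_logfc).set_index("transcript_id"),
        pathway_flags=flags,
        extras={"metadata": metadata, "genus_of": genus_of},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------

def simulate_metabolome(
    design: SimulationDesign,
    n_metabolites: int = 139,
    frac_age_trending: float = 0.3,
    slope_log2: float = 1.0,
    noise_sigma: float = 0.25,
    dilution_sigma: float = 0.2,
):
    """Serum metabolite concentrations with age trends in control birds only.

    Trending metabolites shift their mean by ``slope_log2`` log2 units per
    age step (10 -> 24 -> 40) in untreated arms; AGP arms stay flat,
    emulating growth-promotant disruption of normal metabolic maturation.
    Every sample is multiplied by a lognormal dilution factor.
    """
    if n_metabolites <= 0:
        raise ValueError("n_metabolites must be positive")
    if not 0.0 <= frac_age_trending <= 1.0:
        raise ValueError("frac_age_trending must be in [0, 1]")
    rng = design.rng_streams()["metabolome"]
    metadata = make_metadata(design)
    mets = [f"M{i:03d}" for i in range(n_metabolites)]

    n_trend = int(round(frac_age_trending * n_metabolites))
    trending = rng.choice(n_metabolites, size=n_trend, replace=False)
    slopes = np.zeros(n_metabolites)
    slopes[trending] = rng.choice([-1.0, 1.0], size=n_trend) * slope_log2

    base = rng.lognormal(mean=2.0, sigma=0.8, size=n_metabolites)
    age_code = metadata["age_days"].map({10: 0.0, 24: 1.0, 40: 2.0}).to_numpy()
    control = (~metadata["agp"]).to_numpy(float)
    shift = slopes[:, None] * age_code[None, :] * control[None, :]
    dilution = rng.lognormal(mean=0.0, sigma=dilution_sigma, size=len(metadata))
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=(n_metabolites, len(metadata)))
    conc = base[:, None] * np.exp2(shift) * noise * dilution[None, :]

    table = FeatureTable(
        pd.DataFrame(conc, index=mets, columns=metadata.index), kind="expression"
    )
    slope_frame = pd.DataFrame(
        {"control_slope_log2": slopes, "agp_slope_log2": np.zeros(n_metabolites)},
        index=mets,
    )
    truth = GroundTruth(
        metabolite_slopes=slope_frame,
        extras={"metadata": metadata, "dilution": pd.Series(dilution, index=metadata.index)},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Homology hits
# ---------------------------------------------------------------------------

def simulate_homology_hits(
    transcripts: AnnotatedTranscriptTable,
    network,
    frac_true: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """BLAST-outfmt-6-like hit table with truth labels around filter bounds.

    True homologs receive a hit passing one of the two acceptance branches
    (long strong alignment, or high-identity high-overlap); decoys fail both
    branches.  Columns follow outfmt 6 plus ``overlap_pct``, ``subject_length``
    and ``is_true``.
    """
    nodes = list(network.nodes) if hasattr(network, "nodes") else list(network)
    if not nodes:
        raise ValueError("reference network is empty")
    if not 0.0 <= frac_true <= 1.0:
        raise ValueError("frac_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for tid in transcripts.transcripts:
        subject = nodes[int(rng.integers(len(nodes)))]
        is_true = bool(rng.random() < frac_true)
        if is_true:
            if rng.random() < 0.5:  # branch 1: length > 100 and bitscore > 60
                length = int(rng.integers(110, 500))
                bitscore = float(rng.uniform(65, 300))
                ident = float(rng.uniform(30, 80))
                overlap = float(rng.uniform(10, 60))
            else:  # branch 2: identity > 85 and overlap > 65
                length = int(rng.integers(30, 95))
                bitscore = float(rng.uniform(25, 55))
                ident = float(rng.uniform(86, 100))
                overlap = float(rng.uniform(67, 100))
        else:  # fail both branches
            length = int(rng.integers(20, 95))  # <= 100 kills branch 1
            bitscore = float(rng.uniform(25, 300))
            ident = float(rng.uniform(30, 84))  # <= 85 kills branch 2
            overlap = float(rng.uniform(10, 100))
        rows.append(
            dict(
                qseqid=tid,
                sseqid=subject,
                pident=round(ident, 2),
                length=length,
                mismatch=int(length * (100 - ident) / 100),
                gapopen=0,
                qstart=1,
                qend=length,
                sstart=1,
                send=length,
                evalue=10 ** -float(rng.uniform(5, 50)),
                bitscore=round(bitscore, 1),
                overlap_pct=round(overlap, 2),
                subject_length=int(length / max(overlap, 1.0) * 100),
                is_true=is_true,
            )
        )
    return pd.DataFrame(rows)
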