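import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agpms.core import FeatureTable, Lineage
from agpms.synthetic import (
    SimulationDesign,
    simulate_community,
    simulate_metatranscriptome,
)

PATHWAYS = {
    "glycolysis": {"1.1.1.1", "2.7.1.1", "2.7.1.11", "4.1.2.13"},
    "purine": {"2.4.2.14", "6.3.4.13", "2.4.2.7"},
    "cell_wall": {"6.3.2.8", "6.3.2.9", "2.4.1.129"},
}


@pytest.fixture(scope="session")
def design():
    return SimulationDesign(n_taxa=40, seed=12345)


@pytest.fixture(scope="session")
def community(design):
    """(otu_table, taxonomy, tree, truth) at toy scale, fixed seed."""
    return simulate_community(design)


@pytest.fixture(scope="session")
def metadata(community):
    return community[3].extras["metadata"]


@pytest.fixture(scope="session")
def pathways():
    return dict(PATHWAYS)


@pytest.fixture(scope="session")
def transcriptome(design, pathways):
    """(AnnotatedTranscriptTable, truth) with planted decoupled regulation."""
    return simulate_metatranscriptome(design, pathways)


@pytest.fixture(scope="session")
def reference_network():
    g = nx.random_regular_graph(3, 40, seed=4)
    return nx.relabel_nodes(g, {i: f"OG_{i:03d}" for i in g.nodes})


@pytest.fixture
def toy_table():
    """Tiny deterministic OTU table used across unit tests."""
    return FeatureTable(
        pd.DataFrame(
            [[10, 0, 3], [5, 2, 3], [0, 8, 4]],
            index=["otu1", "otu2", "otu3"],
            columns=["s1", "s2", "s3"],
        ),
        kind="otu_counts",
    )


@pytest.fixture
def toy_taxonomy():
    base = {"domain": "Bacteria", "phylum": "p1", "class": "c1", "order": "o1"}
    return {
        "otu1": Lineage(ranks={**base, "family": "F", "genus": "G1"}),
        "otu2": Lineage(ranks={**base, "family": "F", "genus": "G1"}),
        "otu3": Lineage(ranks={**base, "family": "F"}),
    }
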