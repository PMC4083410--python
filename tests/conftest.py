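import networkx as nx
import numpy as np
import pandas as pd
import pytest

from repurposenet.types import VariantRecord, VariantTable


@pytest.fixture
def toy_graph():
    """8-node graph with hand-checkable neighbor structure.

    Edges: hub H touches a,b,c; a-b; b-c; c-d; d-e; isolated node Z.
    """
    g = nx.Graph()
    g.add_edges_from([("H", "a"), ("H", "b"), ("H", "c"),
                      ("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    g.add_node("Z")
    return g


@pytest.fixture
def variant_table():
    """Gene g1: 3 common + 1 rare site; gene g2: no variants (absent)."""
    recs = [
        VariantRecord("g1", "1:100:A:G", 30, 200),   # AF 0.15  common
        VariantRecord("g1", "1:200:C:T", 40, 200),   # AF 0.20  common
        VariantRecord("g1", "1:300:G:A", 12, 200),   # AF 0.06  common
        VariantRecord("g1", "1:400:T:C", 4, 200),    # AF 0.02  rare
    ]
    return VariantTable(recs)


@pytest.fixture
def annotation_small():
    return pd.DataFrame(
        {
            "protein_length": [600.0, 250.0, 400.0],
            "longest_transcript_length": [110_000.0, 60_000.0, 70_000.0],
            "dnds_mouse": [0.2, 0.3, np.nan],
            "dnds_chimp": [0.4, 0.35, 0.5],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )


def random_simple_graph(rng: np.random.Generator, max_nodes: int) -> nx.Graph:
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.5))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
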