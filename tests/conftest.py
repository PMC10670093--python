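import networkx as nx
import pandas as pd
import pytest


@pytest.fixture
def tri_path_graph():
    """Minimal ER - cytosol - mitochondria relay: a 3-node path."""
    g = nx.Graph()
    g.add_edges_from([("E1", "C1"), ("C1", "M1")])
    nx.set_node_attributes(
        g, {"E1": "ER", "C1": "cytosol", "M1": "mitochondria"}, "compartment"
    )
    return g


@pytest.fixture
def motif_graph():
    """The four-node relay motif: DDO-(IDE, UBA52)-SEC61A1."""
    g = nx.Graph()
    g.add_edges_from(
        [("DDO", "IDE"), ("DDO", "UBA52"), ("IDE", "SEC61A1"),
         ("UBA52", "SEC61A1"), ("IDE", "UBA52")]
    )
    nx.set_node_attributes(
        g,
        {"DDO": "cytosol", "IDE": "mitochondria", "UBA52": "mitochondria",
         "SEC61A1": "ER"},
        "compartment",
    )
    return g


@pytest.fixture
def raw_catalog_rows():
    def make(rows):
        return pd.DataFrame(rows, columns=["symbol", "compartment", "source"])

    return make


@pytest.fixture(scope="session")
def screen_bundle():
    """One shared end-to-end fixture bundle (expensive to regenerate)."""
    from xtalk.fixtures import reference_screen_fixture

    return reference_screen_fixture(seed=7)
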