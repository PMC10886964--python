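import networkx as nx
import pytest

from dismodnet.de import collapse_probes, filter_microarray, union_and_partition
from dismodnet.ppi import build_disease_network
from dismodnet.synthetic import generate_de_tables, generate_ppi


@pytest.fixture(scope="session")
def synthetic_scenario():
    """One seeded synthetic study: planted PPI, DE tables, disease network."""
    graph, truth = generate_ppi(seed=11)
    tables = generate_de_tables(graph, truth, seed=12)
    filtered = [collapse_probes(filter_microarray(t)) for t in tables]
    union = union_and_partition(filtered, truth.disease_genes)
    network = build_disease_network({frozenset(e) for e in graph.edges}, union)
    return {"graph": graph, "truth": truth, "tables": tables,
            "filtered": filtered, "union": union, "network": network}


@pytest.fixture
def labelled_toy_graph():
    """10-node universe, 5 HDEGs, a few edges — for enrichment tests."""
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(10))
    for i in range(4):
        g.add_edge(f"n{i}", f"n{i + 1}")
    for i in range(10):
        g.nodes[f"n{i}"]["label"] = "HDEG" if i < 5 else "ODEG"
    return g
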