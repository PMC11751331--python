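import networkx as nx
import pytest

from phimpact import make_polyhedron, shortest_path_matrix


@pytest.fixture(scope="session")
def dodecahedron():
    return make_polyhedron("dodecahedron")


@pytest.fixture(scope="session")
def octahedron():
    return make_polyhedron("octahedron")


@pytest.fixture(scope="session")
def dodecahedron_dm(dodecahedron):
    return shortest_path_matrix(dodecahedron)


@pytest.fixture(scope="session")
def octahedron_dm(octahedron):
    return shortest_path_matrix(octahedron)


def labeled(g: nx.Graph, prefix: str = "N") -> nx.Graph:
    """Relabel integer nodes to normalized gene-symbol-like strings."""
    return nx.relabel_nodes(g, {n: f"{prefix}{int(n):02d}" for n in g.nodes})


@pytest.fixture()
def labeler():
    return labeled
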