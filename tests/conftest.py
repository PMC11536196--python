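import networkx as nx
import numpy as np
import pytest

from symptomnet.criteria import CriterionDefinition
from symptomnet.pcor import SymptomNetwork


def make_network(edges, n_nodes=9, weight=1.0, alpha=0.05, group=""):
    """Build a SymptomNetwork directly from an (i, j[, w]) edge list."""
    criteria = [CriterionDefinition(f"A{i + 1}") for i in range(n_nodes)]
    codes = [c.code for c in criteria]
    g = nx.Graph()
    g.add_nodes_from(codes)
    for e in edges:
        i, j = e[0], e[1]
        w = e[2] if len(e) > 2 else weight
        g.add_edge(codes[i], codes[j], weight=float(w))
    return SymptomNetwork(criteria=criteria, graph=g, alpha=alpha,
                          group_label=group, n=100)


@pytest.fixture
def net_factory():
    return make_network


def random_pd_correlation(rng, p):
    """Random positive-definite correlation matrix."""
    a = rng.standard_normal((p, p + 3))
    s = a @ a.T + 0.5 * np.eye(p)
    d = 1 / np.sqrt(np.diag(s))
    return s * d[:, None] * d[None, :]


@pytest.fixture
def toy_csv(tmp_path):
    """3-person criteria CSV with a sex column, 0/1 coded."""
    path = tmp_path / "toy.csv"
    rows = ["A1,A2,A3,A4,A5,A6,A7,A8,A9,sex",
            "1,1,1,1,0,0,1,0,0,men",
            "0,1,1,1,1,1,1,1,1,women",
            "1,0,1,0,1,0,1,0,1,men"]
    path.write_text("\n".join(rows) + "\n")
    return path
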