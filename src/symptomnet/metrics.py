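"""Node centralities and graph-level topology of a symptom network.

Conventions are chosen so reported values are directly comparable with the
usual network-visualization software output on this kind of graph:

* eigenvector centrality uses the (absolute) edge weights and is
  max-normalized, so the most central node scores exactly 1;
* closeness centrality and all path-based indices (average path length,
  diameter) are computed on the *unweighted* skeleton — hop counts — with
  closeness normalized as ``(n - 1) / sum of distances`` so values lie in
  (0, 1]; weighted distances (length = 1/|weight|) are available behind a
  flag but are not the default;
* density is ``edges / (n (n - 1) / 2)``.

Disconnected graphs raise by default so path metrics cannot silently be
nonsense; ``on_disconnected="largest"`` computes on the largest component
and annotates the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DisconnectedGraphError, ParameterError
from .pcor import SymptomNetwork

__all__ = [
    "NetworkSummary",
    "eigenvector_centrality",
    "closeness_centrality",
    "centrality_table",
    "rank_criteria",
    "network_summary",
]

logger = logging.getLogger(__name__)

#: Power-iteration convergence tolerance and iteration cap.
POWER_TOL = 1e-10
POWER_MAXITER = 100_000


@dataclass
class NetworkSummary:
    """Graph-level indices of a symptom network."""

    n_nodes: int
    n_edges: int
    density: float
    connected: bool
    average_path_length: float | None
    diameter: int | None
    component_note: str = ""

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "connected": self.connected,
            "average_path_length": self.average_path_length,
            "diameter": self.diameter,
            "component_note": self.component_note,
        }


def _working_graph(net: SymptomNetwork, on_disconnected: str) -> tuple[nx.Graph, str]:
    g = net.graph
    if g.number_of_nodes() == 0:
        raise DisconnectedGraphError("empty graph")
    if nx.is_connected(g):
        return g, ""
    if on_disconnected == "largest":
        comp = max(nx.connected_components(g), key=len)
        note = (f"computed on the largest connected component "
                f"({len(comp)} of {g.number_of_nodes()} nodes)")
        logger.warning("disconnected network: %s", note)
        return g.subgraph(comp).copy(), note
    raise DisconnectedGraphError(
        "network is disconnected; pass on_disconnected='largest' to compute "
        "on the largest component"
    )


def eigenvector_centrality(
    net: SymptomNetwork,
    use_weights: bool = True,
    on_disconnected: str = "error",
) -> pd.Series:
    """Max-normalized eigenvector centrality of the (weighted) adjacency.

    The leading eigenvector of the absolute-weighted adjacency matrix is found
    by power iteration (tolerance 1e-10); by Perron-Frobenius it is entrywise
    positive on a connected graph. The vector is divided by its maximum, so
    the most central node scores exactly 1.
    """
    g, _ = _working_graph(net, on_disconnected)
    order = [c for c in net.codes if c in g]
    a = nx.to_numpy_array(g, nodelist=order, weight="weight" if use_weights else None)
    if use_weights and (a < 0).any():
        logger.warning("negative edge weights entered eigenvector centrality "
                       "by absolute value")
        a = np.abs(a)
    if a.max() <= 0:
        raise DisconnectedGraphError("graph has no edges")
    # shift by the identity: same eigenvectors, but the spectrum becomes
    # strictly dominant so power iteration converges on bipartite graphs too
    m = a + a.max() * np.eye(a.shape[0])
    v = np.ones(a.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(POWER_MAXITER):
        w = m @ v
        w /= np.linalg.norm(w)
        if np.abs(w - v).max() < POWER_TOL:
            v = w
            break
        v = w
    v = np.abs(v)
    return pd.Series(v / v.max(), index=order, name="eigenvector")


def closeness_centrality(
    net: SymptomNetwork,
    weighted: bool = False,
    on_disconnected: str = "error",
) -> pd.Series:
    """Normalized closeness: ``(n - 1) / sum of shortest-path distances``.

    Distances are hop counts on the unweighted skeleton by default; with
    ``weighted=True`` each edge has length ``1/|weight|`` so strong partial
    correlations are short.
    """
    g, _ = _working_graph(net, on_disconnected)
    if weighted:
        h = g.copy()
        for u, v, d in h.edges(data=True):
            d["length"] = 1.0 / abs(d["weight"])
        vals = nx.closeness_centrality(h, distance="length")
    else:
        vals = nx.closeness_centrality(g)
    order = [c for c in net.codes if c in g]
    return pd.Series({c: vals[c] for c in order}, name="closeness")


def centrality_table(
    net: SymptomNetwork,
    use_weights: bool = True,
    weighted_paths: bool = False,
    on_disconnected: str = "error",
) -> pd.DataFrame:
    """Per-node eigenvector and closeness centralities with rank columns.

    Ranks are dense and descending (1 = most central); ties share a rank.
    """
    ev = eigenvector_centrality(net, use_weights, on_disconnected)
    cl = closeness_centrality(net, weighted_paths, on_disconnected)
    df = pd.DataFrame({"eigenvector": ev, "closeness": cl})
    df["rank_eigenvector"] = df["eigenvector"].rank(
        ascending=False, method="dense").astype(int)
    df["rank_closeness"] = df["closeness"].rank(
        ascending=False, method="dense").astype(int)
    return df


def rank_criteria(ct: pd.DataFrame) -> dict:
    """Criterion codes ordered by descending centrality, per index.

    Ties are broken by criterion code order and reported in ``ties``.
    """
    out: dict = {"ties": {}}
    for index in ("eigenvector", "closeness"):
        if index not in ct.columns:
            raise ParameterError(f"centrality table lacks column {index!r}")
        ordered = sorted(ct.index, key=lambda c: (-ct.loc[c, index], c))
        out[index] = ordered
        dup = ct[index].round(12).duplicated(keep=False)
        out["ties"][index] = sorted(ct.index[dup])
    return out


def network_summary(
    net: SymptomNetwork,
    weighted_paths: bool = False,
    on_disconnected: str = "error",
) -> NetworkSummary:
    """Density, average path length and diameter of the network.

    Density always refers to the full node set. Path metrics require a
    connected graph; on a disconnected one the default is a hard error,
    ``on_disconnected="flag"`` returns density with path metrics missing,
    and ``"largest"`` computes them on the largest component (annotated).
    """
    n = net.n_nodes
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    e = net.n_edges
    density = e / (n * (n - 1) / 2)
    g = net.graph
    connected = nx.is_connected(g)
    note = ""
    if not connected:
        if on_disconnected == "flag":
            return NetworkSummary(n, e, density, False, None, None,
                                  "disconnected: path metrics undefined")
        g, note = _working_graph(net, on_disconnected)  # raises on "error"
    if weighted_paths:
        h = g.copy()
        for u, v, d in h.edges(data=True):
            d["length"] = 1.0 / abs(d["weight"])
        apl = nx.average_shortest_path_length(h, weight="length")
        diam = nx.diameter(h, weight="length")
    else:
        apl = nx.average_shortest_path_length(g)
        diam = nx.diameter(g)
    return NetworkSummary(n, e, density, connected, float(apl), diam, note)
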