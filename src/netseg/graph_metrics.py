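"""Network properties and the two inter-network distance measures.

Properties come in three flavours: local (degree), local-global
(betweenness, closeness) and global (relative density). A local(-global)
property describes a graph by a vector of per-node values; two graphs on
the same node set are compared by an lp-norm of the difference of their
vectors. A global property compares two graphs through the symmetric
difference and the union of their edge sets: the distance is the property
of the symmetric-difference graph divided by the property of the union
graph, so a greater value implies a sparser network intersection.

Conventions (fixed so tests are exact): betweenness is unnormalized and
counts each unordered node pair once; closeness is the
reachability-scaled (Wasserman-Faust) form, zero for isolated nodes;
shortest paths are unweighted.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np


def _vector(G: nx.Graph, per_node: dict) -> np.ndarray:
    return np.array([per_node[v] for v in G.nodes], dtype=float)


def degree_vector(G: nx.Graph) -> np.ndarray:
    """Number of incident edges per node, in node order."""
    return np.array([d for _, d in G.degree()], dtype=float)


def betweenness_vector(G: nx.Graph) -> np.ndarray:
    """Unnormalized betweenness: summed fractions of shortest paths through a node.

    Each unordered pair (u, w), u != v != w, contributes the fraction of
    shortest u-w paths containing v.
    """
    return _vector(G, nx.betweenness_centrality(G, normalized=False))


def closeness_vector(G: nx.Graph) -> np.ndarray:
    """Reachability-scaled closeness: (r_v/(n-1)) * (r_v / sum of distances).

    r_v is the number of nodes reachable from v (excluding v); an isolated
    node scores 0.
    """
    return _vector(G, nx.closeness_centrality(G))


def relative_density(G: nx.Graph) -> float:
    """Edges per node, |E| / |V|."""
    n = G.number_of_nodes()
    if n < 1:
        raise ValueError("relative density needs at least one node")
    return G.number_of_edges() / n


#: Local(-global) properties available for vector distances.
PROPERTY_VECTORS: dict[str, Callable[[nx.Graph], np.ndarray]] = {
    "degree": degree_vector,
    "betweenness": betweenness_vector,
    "closeness": closeness_vector,
}

#: Global properties available for symmetric-difference distances.
GLOBAL_PROPERTIES: dict[str, Callable[[nx.Graph], float]] = {
    "relative_density": relative_density,
}


def lp_property_distance(a: np.ndarray, b: np.ndarray, p: float = 2) -> float:
    """lp-norm distance between two property vectors on the same node order.

    ``(sum_v |a(v) - b(v)|^p)^(1/p)``; p = 2 is the Euclidean distance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched vector lengths {a.shape} vs {b.shape}")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(np.linalg.norm(a - b, ord=p))


def symmetric_difference_graph(G1: nx.Graph, G2: nx.Graph) -> nx.Graph:
    """Graph of edges present in exactly one of two graphs (same node set)."""
    _check_same_nodes(G1, G2)
    out = nx.Graph()
    out.add_nodes_from(G1.nodes)
    e1 = {frozenset(e) for e in G1.edges}
    e2 = {frozenset(e) for e in G2.edges}
    out.add_edges_from(tuple(e) for e in e1 ^ e2)
    return out


def union_graph(G1: nx.Graph, G2: nx.Graph) -> nx.Graph:
    """Graph of edges present in either of two graphs (same node set)."""
    _check_same_nodes(G1, G2)
    out = nx.Graph()
    out.add_nodes_from(G1.nodes)
    out.add_edges_from(G1.edges)
    out.add_edges_from(G2.edges)
    return out


def _check_same_nodes(G1: nx.Graph, G2: nx.Graph) -> None:
    if set(G1.nodes) != set(G2.nodes):
        raise ValueError("graphs must share the same node set")


def global_sd_distance(
    G1: nx.Graph, G2: nx.Graph, prop: str = "relative_density"
) -> float:
    """Global-property distance P(G delta G') / P(G union G').

    Zero for identical graphs (empty symmetric difference) and symmetric in
    its arguments. For relative density the node counts cancel, leaving the
    ratio of symmetric-difference edges to union edges (a Jaccard distance
    on edge sets), hence a value in [0, 1]. Both graphs empty => 0.
    """
    try:
        fn = GLOBAL_PROPERTIES[prop]
    except KeyError:
        raise ValueError(f"unknown global property {prop!r}") from None
    union = union_graph(G1, G2)
    denom = fn(union)
    if denom == 0:
        return 0.0
    return fn(symmetric_difference_graph(G1, G2)) / denom


def export_edgelist(G: nx.Graph, path) -> None:
    """Write the edge set as a two-column TSV for inspection."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in G.edges:
            fh.write(f"{u}\t{v}\n")


def export_graphml(G: nx.Graph, path) -> None:
    """Write the graph as GraphML (drops non-serializable attributes)."""
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from(G.edges)
    nx.write_graphml(H, path)
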