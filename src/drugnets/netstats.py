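"""Network parameters and node centralities.

Summary metrics: average degree <d> = (1/|V|) sum_i d(v_i) (with in/out and
per-partition variants for directed/bipartite networks), average clustering
<c>, density r = 2|E| / (|V|(|V|-1)), average shortest-path length <s> and
diameter phi.  Path-based quantities are computed by BFS on the undirected
view, over node pairs of the largest connected component: averaging over
disconnected pairs is undefined, and for a bipartite drug→target network a
directed path metric would be trivially degenerate.

Centralities: degree, betweenness (Brandes fractional by default, with a
literal pair-indicator variant in which any shortest path through a node
counts once per pair), closeness (inverse distance sum, scaled by
(|C|-1)/(|V|-1) so components of different sizes are comparable),
eccentricity, eigenvector (power iteration on the adjacency matrix) and
PageRank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

from .build import DRUG, InteractionNetwork


@dataclass
class MetricsSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_clustering: float
    n_components: int
    largest_component_size: int
    avg_path_length: float | None
    diameter: int | None
    avg_in_degree: float | None = None
    avg_out_degree: float | None = None
    avg_degree_drugs: float | None = None
    avg_degree_targets: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class CentralityTable:
    """Per-node values for one centrality."""

    centrality_name: str
    values: dict[str, float]
    params: dict = field(default_factory=dict)

    def aligned(self, nodes) -> np.ndarray:
        return np.array([self.values[n] for n in nodes], dtype=float)

    def positive_values(self) -> np.ndarray:
        """Finite, strictly positive values (the Benford-testable subset)."""
        arr = np.array(list(self.values.values()), dtype=float)
        return arr[np.isfinite(arr) & (arr > 0)]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, iterations: int):
        super().__init__(message)
        self.iterations = iterations


def summarize(net: InteractionNetwork) -> MetricsSummary:
    """Compute the summary metrics for one network snapshot."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.undirected_view()
    n = net.n_nodes
    avg_degree = 2 * net.n_edges / n
    density = 2 * net.n_edges / (n * (n - 1)) if n > 1 else 0.0
    avg_clustering = nx.average_clustering(g) if n > 0 else 0.0

    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    if len(largest) >= 2:
        sub = g.subgraph(sorted(largest))
        adj = nx.to_scipy_sparse_array(sub, dtype=np.int8)
        dist = csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)
        iu = np.triu_indices(dist.shape[0], k=1)
        pair_dists = dist[iu]
        avg_path: float | None = float(pair_dists.mean())
        diameter: int | None = int(pair_dists.max())
    else:
        avg_path = None
        diameter = None

    summary = MetricsSummary(
        n_nodes=n,
        n_edges=net.n_edges,
        avg_degree=avg_degree,
        density=density,
        avg_clustering=avg_clustering,
        n_components=len(components),
        largest_component_size=len(largest),
        avg_path_length=avg_path,
        diameter=diameter,
    )
    if net.directed:
        dg = net.to_networkx()
        summary.avg_in_degree = sum(d for _, d in dg.in_degree()) / n
        summary.avg_out_degree = sum(d for _, d in dg.out_degree()) / n
    if net.bipartite:
        drugs, targets = net.drugs, net.targets
        if drugs:
            summary.avg_degree_drugs = sum(g.degree(d) for d in drugs) / len(drugs)
        if targets:
            summary.avg_degree_targets = sum(g.degree(t) for t in targets) / len(targets)
    return summary


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def degree(net: InteractionNetwork, which: str = "total") -> CentralityTable:
    """Per-node degree; ``which`` in {total, in, out} (in/out for DTI)."""
    if which == "total":
        g = net.undirected_view()
        values = {n: float(d) for n, d in g.degree()}
    elif which in ("in", "out"):
        if not net.directed:
            raise ValueError("in/out degree requires a directed network")
        dg = net.to_networkx()
        deg_view = dg.in_degree() if which == "in" else dg.out_degree()
        values = {n: float(d) for n, d in deg_view}
    else:
        raise ValueError(f"unknown degree variant {which!r}")
    return CentralityTable("degree" if which == "total" else f"{which}_degree", values)


def betweenness(net: InteractionNetwork, variant: str = "brandes") -> CentralityTable:
    """Betweenness on the undirected view, normalised by 2/(|V|(|V|-1)).

    ``brandes``: standard fractional shortest-path betweenness.
    ``pair_indicator``: for each node pair (j,k), every interior node lying on
    at least one shortest j–k path contributes 1 (a 0/1 indicator rather than
    a fractional share).
    """
    g = net.undirected_view()
    n = g.number_of_nodes()
    scale = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    if variant == "brandes":
        raw = nx.betweenness_centrality(g, normalized=False)
        values = {v: raw[v] * scale for v in g}
    elif variant == "pair_indicator":
        acc = {v: 0.0 for v in g}
        dist = dict(nx.all_pairs_shortest_path_length(g))
        nodes = list(g)
        for ji, j in enumerate(nodes):
            dj = dist[j]
            for k in nodes[ji + 1:]:
                if k not in dj:
                    continue
                djk = dj[k]
                if djk < 2:
                    continue
                dk = dist[k]
                for v in nodes:
                    if v is j or v is k or v not in dj or v not in dk:
                        continue
                    if 0 < dj[v] < djk and dj[v] + dk[v] == djk:
                        acc[v] += 1.0
        values = {v: acc[v] * scale for v in g}
    else:
        raise ValueError(f"unknown betweenness variant {variant!r}")
    return CentralityTable("betweenness", values, {"variant": variant})


def closeness(net: InteractionNetwork) -> CentralityTable:
    """Inverse distance-sum closeness with component-size scaling.

    For node v in component C: gamma(v) = (sum_{u in C\\{v}} s(v,u))^-1
    multiplied by (|C|-1)/(|V|-1).  Singleton components get 0.
    """
    g = net.undirected_view()
    n = g.number_of_nodes()
    values: dict[str, float] = {}
    for comp in nx.connected_components(g):
        size = len(comp)
        if size == 1:
            values[next(iter(comp))] = 0.0
            continue
        scale = (size - 1) / (n - 1) if n > 1 else 0.0
        sub = g.subgraph(comp)
        for v in comp:
            total = sum(nx.single_source_shortest_path_length(sub, v).values())
            values[v] = scale / total
    return CentralityTable("closeness", values, {"component_scaled": True})


def eccentricity(net: InteractionNetwork) -> CentralityTable:
    """Max shortest-path distance within each node's component."""
    g = net.undirected_view()
    values: dict[str, float] = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            values[next(iter(comp))] = 0.0
            continue
        ecc = nx.eccentricity(g.subgraph(comp))
        values.update({v: float(e) for v, e in ecc.items()})
    return CentralityTable("eccentricity", values)


def eigenvector(
    net: InteractionNetwork, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityTable:
    """Principal adjacency eigenvector by power iteration, per component.

    Each component's vector is L2-normalised and nonnegative.  Iteration uses
    the shifted operator A + I, which shares A's eigenvectors while breaking
    the +/-lambda oscillation of bipartite components.
    """
    g = net.undirected_view()
    values: dict[str, float] = {}
    for comp in nx.connected_components(g):
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            values[comp_nodes[0]] = 1.0
            continue
        sub = g.subgraph(comp_nodes)
        a = nx.to_scipy_sparse_array(sub, nodelist=comp_nodes, dtype=float)
        x = np.full(len(comp_nodes), 1.0 / np.sqrt(len(comp_nodes)))
        for it in range(max_iter):
            y = a @ x + x
            y /= np.linalg.norm(y)
            if np.max(np.abs(y - x)) < tol:
                x = y
                break
            x = y
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations",
                iterations=max_iter,
            )
        x = np.abs(x)
        values.update({v: float(val) for v, val in zip(comp_nodes, x)})
    return CentralityTable("eigenvector", values, {"tol": tol})


def pagerank(
    net: InteractionNetwork, damping: float = 0.85, tol: float = 1e-8
) -> CentralityTable:
    """PageRank on the undirected view (each edge as two directed links)."""
    g = net.undirected_view()
    pr = nx.pagerank(g, alpha=damping, tol=tol)
    return CentralityTable("pagerank", {v: float(x) for v, x in pr.items()},
                           {"damping": damping, "tol": tol})


CENTRALITY_FUNCTIONS = {
    "degree": degree,
    "betweenness": betweenness,
    "closeness": closeness,
    "eccentricity": eccentricity,
    "eigenvector": eigenvector,
    "pagerank": pagerank,
}


def compute_centrality(net: InteractionNetwork, name: str, **kwargs) -> CentralityTable:
    try:
        fn = CENTRALITY_FUNCTIONS[name]
    except KeyError:
        raise ValueError(f"unknown centrality {name!r}") from None
    return fn(net, **kwargs)
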