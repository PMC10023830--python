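"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — hand-rolled BFS, exhaustive
shortest-path enumeration, dense eigendecomposition — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Plain queue BFS distances from ``source`` over an adjacency dict."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency_dict(g: nx.Graph) -> dict:
    return {v: sorted(g.neighbors(v)) for v in g}


def path_metrics_bruteforce(g: nx.Graph):
    """(avg path length, diameter, eccentricity per node) on the largest
    component, by repeated BFS."""
    adj = adjacency_dict(g)
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    dists = []
    for u, v in combinations(sorted(largest), 2):
        d = bfs_distances(adj, u)
        dists.append(d[v])
    ecc = {}
    for comp in comps:
        for v in comp:
            d = bfs_distances(adj, v)
            ecc[v] = max(d.values()) if len(comp) > 1 else 0
    avg = sum(dists) / len(dists) if dists else None
    dia = max(dists) if dists else None
    return avg, dia, ecc


def betweenness_bruteforce(g: nx.Graph, fractional: bool = True) -> dict:
    """Exhaustive shortest-path enumeration betweenness, 2/(n(n-1)) scale.

    fractional=True sums sigma_st(v)/sigma_st (Brandes' quantity);
    fractional=False scores 1 whenever any shortest path crosses v.
    """
    n = g.number_of_nodes()
    acc = {v: 0.0 for v in g}
    for s, t in combinations(sorted(g), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        counts = {v: 0 for v in g}
        for p in paths:
            for v in p[1:-1]:
                counts[v] += 1
        for v, c in counts.items():
            if c == 0:
                continue
            acc[v] += (c / len(paths)) if fractional else 1.0
    scale = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    return {v: x * scale for v, x in acc.items()}


def eigenvector_dense(g: nx.Graph) -> dict:
    """Per-component principal eigenvector via numpy.linalg.eigh."""
    values = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            values[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
        w, v = np.linalg.eigh(a)
        vec = np.abs(v[:, np.argmax(w)])
        vec /= np.linalg.norm(vec)
        values.update(dict(zip(nodes, vec)))
    return values


def pagerank_dense(g: nx.Graph, damping: float = 0.85) -> dict:
    """Stationary vector of the dense Google matrix (dangling mass spread
    uniformly), found by eigendecomposition."""
    nodes = sorted(g)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    out = a.sum(axis=1)
    p = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            p[i] = a[i] / out[i]
        else:
            p[i] = 1.0 / n
    google = damping * p + (1 - damping) / n
    w, v = np.linalg.eig(google.T)
    vec = np.real(v[:, np.argmax(np.real(w))])
    vec = np.abs(vec)
    vec /= vec.sum()
    return dict(zip(nodes, vec))


def kendall_tau_b_bruteforce(x, y) -> float | None:
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i, j in combinations(range(n), 2):
        dx = np.sign(x[i] - x[j])
        dy = np.sign(y[i] - y[j])
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return None
    return (conc - disc) / denom
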