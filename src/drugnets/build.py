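"""Construction of DDI and DTI networks from filtered drug records.

A drug–drug interaction (DDI) network is monopartite, undirected and
unweighted: nodes are drugs, an edge joins two drugs if either record lists
the other as an interaction partner (symmetric closure).  A drug–target
interaction (DTI) network is bipartite, directed drug→target and unweighted.
Entities with no surviving interaction are omitted, so every node has
degree >= 1.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from .ingest import DrugRecord

DRUG = "drug"
TARGET = "target"


@dataclass(frozen=True)
class InteractionNetwork:
    """An unweighted interaction network snapshot.

    ``edges`` holds canonical pairs: sorted ``(a, b)`` tuples when undirected,
    ``(drug, target)`` tuples when directed.  ``nodes`` is lexicographically
    sorted for stable, diffable outputs.  ``node_groups`` optionally carries
    drug group labels so synthetic networks can be serialised to fixture XML.
    """

    nodes: tuple[str, ...]
    node_kind: dict[str, str]
    edges: frozenset[tuple[str, str]]
    bipartite: bool
    directed: bool
    version_label: str = ""
    node_groups: dict[str, frozenset[str]] | None = None

    # -- basic views --------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.node_kind[n] == DRUG)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.node_kind[n] == TARGET)

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.directed else nx.Graph()
        for n in self.nodes:
            g.add_node(n, kind=self.node_kind[n])
        g.add_edges_from(self.edges)
        return g

    def undirected_view(self) -> nx.Graph:
        """The undirected simple graph on the same node set."""
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, kind=self.node_kind[n])
        g.add_edges_from(self.edges)
        return g

    def with_edges(self, extra: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        """A copy with additional edges on the SAME node set."""
        new_edges = set(self.edges)
        for a, b in extra:
            new_edges.add(canonical_edge(a, b, directed=self.directed))
        return InteractionNetwork(
            nodes=self.nodes,
            node_kind=self.node_kind,
            edges=frozenset(new_edges),
            bipartite=self.bipartite,
            directed=self.directed,
            version_label=self.version_label,
            node_groups=self.node_groups,
        )

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        node_set = set(self.nodes)
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at {a}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a},{b}) leaves the node set")
            if self.bipartite:
                if self.node_kind[a] != DRUG or self.node_kind[b] != TARGET:
                    raise ValueError(f"edge ({a},{b}) is not drug->target")
            elif not self.directed and a > b:
                raise ValueError(f"non-canonical undirected edge ({a},{b})")
            deg[a] += 1
            deg[b] += 1
        isolated = [n for n, d in deg.items() if d == 0]
        if isolated:
            raise ValueError(f"isolated nodes present: {isolated[:5]}")


def canonical_edge(a: str, b: str, *, directed: bool) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-loop at {a}")
    if directed:
        return (a, b)
    return (a, b) if a < b else (b, a)


def build_ddi(records: Sequence[DrugRecord], *, version_label: str = "") -> InteractionNetwork:
    """Build the undirected DDI network with symmetric closure.

    An undirected edge {a, b} exists iff b is in a's interaction list or a is
    in b's, with both drugs present in ``records``; drugs left with no edge
    are omitted.
    """
    ids = {r.drug_id for r in records}
    groups = {r.drug_id: r.groups for r in records}
    edges: set[tuple[str, str]] = set()
    for rec in records:
        for partner in rec.interactions:
            if partner in ids and partner != rec.drug_id:
                edges.add(canonical_edge(rec.drug_id, partner, directed=False))
    nodes = sorted({n for e in edges for n in e})
    return InteractionNetwork(
        nodes=tuple(nodes),
        node_kind={n: DRUG for n in nodes},
        edges=frozenset(edges),
        bipartite=False,
        directed=False,
        version_label=version_label,
        node_groups={n: groups[n] for n in nodes} if groups else None,
    )


def build_dti(records: Sequence[DrugRecord], *, version_label: str = "") -> InteractionNetwork:
    """Build the bipartite directed drug→target network.

    Targets are deduplicated by target id across drugs; drugs without targets
    (after the organism filter applied upstream) and untouched targets are
    omitted.
    """
    groups = {r.drug_id: r.groups for r in records}
    edges: set[tuple[str, str]] = set()
    for rec in records:
        for t in rec.targets:
            if t.target_id != rec.drug_id:
                edges.add((rec.drug_id, t.target_id))
    drug_nodes = sorted({d for d, _ in edges})
    target_nodes = sorted({t for _, t in edges})
    kind = {d: DRUG for d in drug_nodes}
    kind.update({t: TARGET for t in target_nodes})
    nodes = tuple(sorted(kind))
    return InteractionNetwork(
        nodes=nodes,
        node_kind=kind,
        edges=frozenset(edges),
        bipartite=True,
        directed=True,
        version_label=version_label,
        node_groups={d: groups[d] for d in drug_nodes if d in groups} or None,
    )


# ---------------------------------------------------------------------------
# non-edge universe
# ---------------------------------------------------------------------------

class NonEdgeUniverse:
    """Implicit descriptor of all absent edges on the network's node set.

    For a DDI network the total universe E_t is every unordered drug pair; for
    a DTI network it is every drug×target pair.  The set E_t \\ E is never
    materialised: membership, exact size, uniform sampling without replacement
    and lazy enumeration are provided instead.
    """

    def __init__(self, net: InteractionNetwork):
        self.net = net
        if net.bipartite:
            self._drugs = net.drugs
            self._targets = net.targets
            self.total = len(self._drugs) * len(self._targets)
        else:
            n = net.n_nodes
            self.total = n * (n - 1) // 2
        self.size = self.total - net.n_edges

    def __len__(self) -> int:
        return self.size

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        net = self.net
        if net.bipartite:
            if net.node_kind.get(a) != DRUG or net.node_kind.get(b) != TARGET:
                return False
            return (a, b) not in net.edges
        if a == b or a not in net.node_kind or b not in net.node_kind:
            return False
        return canonical_edge(a, b, directed=False) not in net.edges

    # pair <-> integer index over the lexicographic enumeration of E_t
    def _decode(self, idx: int) -> tuple[str, str]:
        net = self.net
        if net.bipartite:
            nt = len(self._targets)
            return (self._drugs[idx // nt], self._targets[idx % nt])
        # unordered pair (i, j), i < j, row-major over i
        n = net.n_nodes
        i = int(n - 2 - math.floor(
            math.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2 - 0.5))
        j = int(idx + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
        return (net.nodes[i], net.nodes[j])

    def iterate(self) -> Iterator[tuple[str, str]]:
        """Lazily enumerate all non-edges in lexicographic order."""
        for idx in range(self.total):
            pair = self._decode(idx)
            edge = pair if self.net.directed else canonical_edge(*pair, directed=False)
            if edge not in self.net.edges:
                yield edge

    def sample(self, m: int, rng: np.random.Generator) -> list[tuple[str, str]]:
        """Draw ``m`` distinct non-edges uniformly without replacement.

        Rejection sampling over integer pair indices; memory is O(m) so dense
        universes are safe.  Falls back to full enumeration when the universe
        is almost exhausted.
        """
        if m > self.size:
            raise ValueError(f"requested {m} non-edges from a universe of {self.size}")
        if m == 0:
            return []
        if self.size < 2 * m or self.total < 1024:
            pool = list(self.iterate())
            idx = rng.choice(len(pool), size=m, replace=False)
            return [pool[i] for i in sorted(idx.tolist())]
        chosen: set[int] = set()
        out: list[tuple[str, str]] = []
        while len(out) < m:
            batch = rng.integers(0, self.total, size=max(16, 2 * (m - len(out))))
            for idx in batch.tolist():
                if idx in chosen:
                    continue
                pair = self._decode(idx)
                edge = pair if self.net.directed else canonical_edge(*pair, directed=False)
                if edge in self.net.edges:
                    continue
                chosen.add(idx)
                out.append(edge)
                if len(out) == m:
                    break
        return out


def nonedge_universe(net: InteractionNetwork) -> NonEdgeUniverse:
    """The sampler/enumerator over absent edges on the current node set."""
    return NonEdgeUniverse(net)


# ---------------------------------------------------------------------------
# serialisation (edge-list TSV, GraphML)
# ---------------------------------------------------------------------------

def write_edgelist_tsv(net: InteractionNetwork, path: str | Path) -> None:
    """Two-column TSV with a header comment carrying kind and directedness."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(
            f"# bipartite={int(net.bipartite)} directed={int(net.directed)} "
            f"version={net.version_label}\n"
        )
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target"])
        for a, b in sorted(net.edges):
            writer.writerow([a, b])


def read_edgelist_tsv(path: str | Path) -> InteractionNetwork:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
        )
        bipartite = bool(int(meta.get("bipartite", "0")))
        directed = bool(int(meta.get("directed", "0")))
        version = meta.get("version", "")
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # column header
        raw = [(a, b) for a, b in reader]
    edges = {canonical_edge(a, b, directed=directed) for a, b in raw}
    if bipartite:
        kind = {a: DRUG for a, _ in edges}
        kind.update({b: TARGET for _, b in edges})
    else:
        kind = {n: DRUG for e in edges for n in e}
    return InteractionNetwork(
        nodes=tuple(sorted(kind)),
        node_kind=kind,
        edges=frozenset(edges),
        bipartite=bipartite,
        directed=directed,
        version_label=version,
    )


def write_graphml(net: InteractionNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))
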