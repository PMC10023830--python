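"""Shared fixtures: tiny hand-built networks, record factories, XML snippets."""

from __future__ import annotations

import pytest

from drugnets.build import DRUG, InteractionNetwork, canonical_edge
from drugnets.ingest import DrugRecord, TargetRecord


def make_net(edge_pairs, *, directed=False, bipartite=False, kinds=None,
             version_label="") -> InteractionNetwork:
    """Build an InteractionNetwork from a bare edge list (test helper)."""
    edges = {canonical_edge(a, b, directed=directed) for a, b in edge_pairs}
    nodes = sorted({n for e in edges for n in e})
    if kinds is None:
        kinds = {n: DRUG for n in nodes}
    return InteractionNetwork(
        nodes=tuple(nodes),
        node_kind=kinds,
        edges=frozenset(edges),
        bipartite=bipartite,
        directed=directed,
        version_label=version_label,
    )


def make_record(drug_id, groups=("approved",), interactions=(), targets=()):
    return DrugRecord(
        drug_id=drug_id,
        name=f"Drug {drug_id}",
        groups=frozenset(groups),
        interactions=frozenset(interactions),
        targets=tuple(
            TargetRecord(t, "Humans") if isinstance(t, str) else t for t in targets
        ),
    )


@pytest.fixture
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return make_net([("A", "B"), ("B", "C")])


@pytest.fixture
def ring5():
    return make_net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")])


@pytest.fixture
def star4():
    # hub H with 3 leaves
    return make_net([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def k4():
    nodes = "ABCD"
    return make_net([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]])
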