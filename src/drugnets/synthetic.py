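"""Synthetic versioned DDI/DTI networks and DrugBank-dialect XML fixtures.

The generator emulates the statistical regime of versioned drug databases:

* a DDI series whose density grows across versions from sparse (~0.02) to
  dense (~0.13), starting from a power-law degree sequence and densifying by
  degree-proportional (preferential) edge addition, with edge supersets
  across versions (monotone knowledge accretion, optionally with a small
  removal fraction emulating curation);
* a sparse bipartite drug→target network with heavy-tailed degree on both
  partitions (drug out-degrees drawn from a discrete power law, targets
  attached preferentially) and density near 7e-4;
* serialisation of either as DrugBank-dialect XML so the parser and every
  downstream stage are testable end to end without any external download.

All randomness flows from one root seed through fixed-offset substreams, so
identical configurations give byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

from .build import DRUG, TARGET, InteractionNetwork, canonical_edge
from .powerlaw import sample_discrete_powerlaw

GROUP_LABELS = ("approved", "investigational", "experimental", "withdrawn", "vet_approved")

#: default per-label probabilities: most drugs approved, a minority carrying
#: co-labels or excluded statuses, mirroring the composition of a curated
#: drug database release
DEFAULT_GROUP_PROBS = {
    "approved": 0.88,
    "investigational": 0.15,
    "experimental": 0.06,
    "withdrawn": 0.02,
    "vet_approved": 0.02,
}


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for fixture generation.

    The DDI density schedule default spans the sparse-to-dense trajectory
    observed across a decade of database versions (~0.019 to ~0.128); the DTI
    mean drug out-degree default of 3.6 and degree exponent defaults match
    the scale-free regime of real drug–target data.
    """

    n_drugs: int = 1000
    n_targets: int = 800
    n_versions: int = 3
    ddi_density_schedule: tuple[float, ...] = (0.019, 0.06, 0.128)
    dti_mean_degree: float = 3.6
    degree_exponent: float = 2.5
    seed: int = 0
    removal_fraction: float = 0.0
    group_label_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROBS)
    )

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_targets < 1 or self.n_versions < 1:
            raise ConfigError("n_drugs/n_targets/n_versions must be positive")
        if len(self.ddi_density_schedule) != self.n_versions:
            raise ConfigError("density schedule length must equal n_versions")
        if not all(0 < r < 1 for r in self.ddi_density_schedule):
            raise ConfigError("densities must lie strictly inside (0, 1)")
        if any(b < a for a, b in zip(self.ddi_density_schedule,
                                     self.ddi_density_schedule[1:])):
            raise ConfigError("density schedule must be non-decreasing")
        if not 1 < self.degree_exponent <= 4:
            raise ConfigError("degree_exponent must lie in (1, 4]")
        if self.dti_mean_degree <= 0 or self.dti_mean_degree >= min(
            self.n_drugs, self.n_targets
        ):
            raise ConfigError("dti_mean_degree out of range for the node counts")
        if not 0 <= self.removal_fraction < 1:
            raise ConfigError("removal_fraction must lie in [0, 1)")
        for label, p in self.group_label_probabilities.items():
            if label not in GROUP_LABELS:
                raise ConfigError(f"unknown group label {label!r}")
            if not 0 <= p <= 1:
                raise ConfigError("group probabilities must lie in [0, 1]")


# substream offsets off the root seed
_SUB_GROUPS, _SUB_DDI, _SUB_DTI = 1, 2, 3


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, offset]))


def drug_id(i: int) -> str:
    return f"SD{i:05d}"


def target_id(j: int) -> str:
    return f"ST{j:05d}"


def _assign_groups(config: SyntheticConfig) -> dict[str, frozenset[str]]:
    rng = _rng(config, _SUB_GROUPS)
    probs = config.group_label_probabilities
    out: dict[str, frozenset[str]] = {}
    for i in range(config.n_drugs):
        labels = {g for g in GROUP_LABELS if rng.random() < probs.get(g, 0.0)}
        if not labels:
            labels = {"experimental"}
        out[drug_id(i)] = frozenset(labels)
    return out


def _weighted_endpoint(degrees: np.ndarray, rng: np.random.Generator) -> int:
    """Pick a node index with probability proportional to degree + 1."""
    w = degrees + 1.0
    return int(rng.choice(degrees.size, p=w / w.sum()))


def _densify(
    edges: set[tuple[int, int]],
    degrees: np.ndarray,
    m_target: int,
    rng: np.random.Generator,
) -> None:
    """Add degree-proportional edges in place until |E| = m_target."""
    n = degrees.size
    max_edges = n * (n - 1) // 2
    if m_target > max_edges:
        raise ConfigError(f"scheduled density needs {m_target} edges but only "
                          f"{max_edges} pairs exist")
    # stub list with +1 attractiveness per node: O(1) degree-proportional draws
    stubs = np.repeat(np.arange(n), degrees.astype(int) + 1).tolist()
    while len(edges) < m_target:
        u = stubs[int(rng.integers(len(stubs)))]
        v = stubs[int(rng.integers(len(stubs)))]
        if u == v:
            continue
        e = (u, v) if u < v else (v, u)
        if e in edges:
            continue
        edges.add(e)
        degrees[u] += 1
        degrees[v] += 1
        stubs.append(u)
        stubs.append(v)


def _initial_powerlaw_graph(
    n: int, alpha: float, m_target: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Configuration-model graph from a truncated power-law degree sequence,
    adjusted to exactly m_target edges."""
    deg_seq = sample_discrete_powerlaw(alpha, n, rng, xmin=1, xmax=max(2, n - 1))
    if deg_seq.sum() % 2:
        deg_seq[int(rng.integers(n))] += 1
    stubs = np.repeat(np.arange(n), deg_seq)
    edges: set[tuple[int, int]] = set()
    degrees = np.zeros(n, dtype=float)
    for _ in range(3):  # pair stubs; re-shuffle rejects a few times
        rng.shuffle(stubs)
        leftovers: list[int] = []
        for a, b in zip(stubs[0::2], stubs[1::2]):
            u, v = int(a), int(b)
            e = (u, v) if u < v else (v, u)
            if u == v or e in edges:
                leftovers.extend((u, v))
                continue
            edges.add(e)
            degrees[u] += 1
            degrees[v] += 1
        if len(stubs) % 2:
            leftovers.append(int(stubs[-1]))
        stubs = np.array(leftovers, dtype=int)
        if stubs.size < 2:
            break
    # guarantee degree >= 1 everywhere
    for u in np.flatnonzero(degrees == 0):
        while True:
            v = _weighted_endpoint(degrees, rng)
            if v != u:
                e = (int(u), v) if u < v else (v, int(u))
                if e not in edges:
                    edges.add(e)
                    degrees[int(u)] += 1
                    degrees[v] += 1
                    break
    # trim or grow to the scheduled edge count
    if len(edges) > m_target:
        pool = sorted(edges)
        for idx in rng.permutation(len(pool)):
            if len(edges) == m_target:
                break
            u, v = pool[int(idx)]
            if degrees[u] > 1 and degrees[v] > 1:
                edges.discard((u, v))
                degrees[u] -= 1
                degrees[v] -= 1
    _densify(edges, degrees, m_target, rng)
    return edges


def _as_network(
    int_edges: set[tuple[int, int]],
    groups: dict[str, frozenset[str]],
    version_label: str,
) -> InteractionNetwork:
    edges = {
        canonical_edge(drug_id(u), drug_id(v), directed=False) for u, v in int_edges
    }
    nodes = sorted({n for e in edges for n in e})
    return InteractionNetwork(
        nodes=tuple(nodes),
        node_kind={n: DRUG for n in nodes},
        edges=frozenset(edges),
        bipartite=False,
        directed=False,
        version_label=version_label,
        node_groups={n: groups[n] for n in nodes},
    )


def generate_ddi_series(config: SyntheticConfig) -> list[InteractionNetwork]:
    """One undirected DDI network per version, edge-superset accretion.

    Version 1 realises a discrete power-law degree sequence; each later
    version optionally removes ``removal_fraction`` of the previous edges
    (curation) and then adds degree-proportional edges until the scheduled
    density is met.  Densities land within rounding of the schedule.
    """
    rng = _rng(config, _SUB_DDI)
    groups = _assign_groups(config)
    n = config.n_drugs
    pair_count = n * (n - 1) // 2
    targets_m = [int(round(r * pair_count)) for r in config.ddi_density_schedule]

    nets: list[InteractionNetwork] = []
    edges = _initial_powerlaw_graph(n, config.degree_exponent, targets_m[0], rng)
    degrees = np.zeros(n, dtype=float)
    for u, v in edges:
        degrees[u] += 1
        degrees[v] += 1
    nets.append(_as_network(edges, groups, "synth-1"))
    for k in range(1, config.n_versions):
        edges = set(edges)
        if config.removal_fraction > 0:
            n_remove = int(round(config.removal_fraction * len(edges)))
            if n_remove:
                pool = sorted(edges)
                for idx in rng.choice(len(pool), size=n_remove, replace=False):
                    u, v = pool[int(idx)]
                    edges.discard((u, v))
                    degrees[u] -= 1
                    degrees[v] -= 1
        _densify(edges, degrees, targets_m[k], rng)
        nets.append(_as_network(edges, groups, f"synth-{k + 1}"))
    return nets


def generate_dti(config: SyntheticConfig, *, version_label: str = "synth-1") -> InteractionNetwork:
    """Bipartite directed drug→target network with heavy tails on both sides.

    Out-degrees (drugs) and in-degrees (targets) are both drawn from the
    discrete power law with exponent ``degree_exponent``, each rescaled so
    the two sides sum to the same total round(dti_mean_degree * n_drugs),
    and then joined by bipartite configuration-model stub pairing with
    duplicate-edge rejection.  Both partitions therefore carry a power-law
    degree distribution whose fitted exponent recovers the configured one.
    """
    rng = _rng(config, _SUB_DTI)
    groups = _assign_groups(config)
    nd, nt = config.n_drugs, config.n_targets
    m_total = int(round(config.dti_mean_degree * nd))

    deg = sample_discrete_powerlaw(
        config.degree_exponent, nd, rng, xmin=1, xmax=max(2, nt)
    ).astype(float)
    # proportional rescale to the scheduled edge total, keeping degree >= 1
    deg = np.maximum(1, np.round(deg * m_total / deg.sum())).astype(int)
    deg = np.minimum(deg, nt)
    while deg.sum() > m_total:
        i = int(rng.integers(nd))
        if deg[i] > 1:
            deg[i] -= 1
    while deg.sum() < m_total:
        i = int(rng.integers(nd))
        if deg[i] < nt:
            deg[i] += 1

    tdeg = sample_discrete_powerlaw(
        config.degree_exponent, nt, rng, xmin=1, xmax=max(2, nd)
    ).astype(float)
    tdeg = np.maximum(1, np.round(tdeg * m_total / tdeg.sum())).astype(int)
    tdeg = np.minimum(tdeg, nd)
    # nudge the largest entries so both stub totals match exactly
    while tdeg.sum() > m_total:
        j = int(np.argmax(tdeg))
        tdeg[j] -= 1
    while tdeg.sum() < m_total:
        j = int(rng.integers(nt))
        if tdeg[j] < nd:
            tdeg[j] += 1

    drug_stubs = np.repeat(np.arange(nd), deg)
    tgt_stubs = np.repeat(np.arange(nt), tdeg)
    edges_int: set[tuple[int, int]] = set()
    for _ in range(20):  # pair stubs, re-shuffling duplicate rejects
        rng.shuffle(tgt_stubs)
        left_d: list[int] = []
        left_t: list[int] = []
        for i, j in zip(drug_stubs, tgt_stubs):
            e = (int(i), int(j))
            if e in edges_int:
                left_d.append(e[0])
                left_t.append(e[1])
            else:
                edges_int.add(e)
        if not left_d:
            break
        drug_stubs = np.array(left_d, dtype=int)
        tgt_stubs = np.array(left_t, dtype=int)
    else:
        # place stragglers on any free target (negligible shape distortion)
        for i in left_d:
            for j in rng.permutation(nt):
                if (int(i), int(j)) not in edges_int:
                    edges_int.add((int(i), int(j)))
                    break
    edges = {(drug_id(i), target_id(j)) for i, j in edges_int}

    drug_nodes = sorted({d for d, _ in edges})
    tgt_nodes = sorted({t for _, t in edges})
    kind = {d: DRUG for d in drug_nodes}
    kind.update({t: TARGET for t in tgt_nodes})
    return InteractionNetwork(
        nodes=tuple(sorted(kind)),
        node_kind=kind,
        edges=frozenset(edges),
        bipartite=True,
        directed=True,
        version_label=version_label,
        node_groups={d: groups[d] for d in drug_nodes},
    )


# ---------------------------------------------------------------------------
# XML fixture serialisation
# ---------------------------------------------------------------------------

def _drug_element(
    parent: etree._Element,
    did: str,
    groups: frozenset[str],
    partners: Sequence[str],
    targets: Sequence[str],
) -> None:
    drug = etree.SubElement(parent, "drug")
    etree.SubElement(drug, "drugbank-id", primary="true").text = did
    etree.SubElement(drug, "name").text = f"Synthetic compound {did}"
    groups_el = etree.SubElement(drug, "groups")
    for g in sorted(groups):
        etree.SubElement(groups_el, "group").text = g.replace("_", " ")
    di_el = etree.SubElement(drug, "drug-interactions")
    for p in sorted(partners):
        di = etree.SubElement(di_el, "drug-interaction")
        etree.SubElement(di, "drugbank-id").text = p
        etree.SubElement(di, "name").text = f"Synthetic compound {p}"
    t_el = etree.SubElement(drug, "targets")
    for t in sorted(targets):
        tgt = etree.SubElement(t_el, "target")
        etree.SubElement(tgt, "id").text = t
        etree.SubElement(tgt, "name").text = f"Synthetic protein {t}"
        etree.SubElement(tgt, "organism").text = "Humans"
        etree.SubElement(tgt, "known-action").text = "yes"


def write_release_xml(
    path: str | Path,
    *,
    version: str,
    ddi: InteractionNetwork | None = None,
    dti: InteractionNetwork | None = None,
) -> Path:
    """Serialise one release (DDI and/or DTI content) as dialect XML.

    DDI interactions are written one-sided (from the lexicographically
    smaller partner), exercising the parser's symmetric closure downstream.
    Output is deterministic: nodes and children are written in sorted order.
    """
    path = Path(path)
    partners: dict[str, list[str]] = {}
    targets: dict[str, list[str]] = {}
    groups: dict[str, frozenset[str]] = {}
    if ddi is not None:
        for n in ddi.nodes:
            groups[n] = (ddi.node_groups or {}).get(n, frozenset({"approved"}))
        for a, b in ddi.edges:
            partners.setdefault(a, []).append(b)
            partners.setdefault(b, [])
    if dti is not None:
        for d in dti.drugs:
            groups.setdefault(d, (dti.node_groups or {}).get(d, frozenset({"approved"})))
            targets.setdefault(d, [])
        for d, t in dti.edges:
            targets[d].append(t)

    root = etree.Element("drugbank", version=version)
    for did in sorted(groups):
        _drug_element(root, did, groups[did], partners.get(did, ()), targets.get(did, ()))
    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
    except OSError as exc:
        raise OSError(f"could not write fixture XML to {path}: {exc}") from exc
    return path


def write_fixture_xml(
    networks: Sequence[InteractionNetwork],
    out_dir: str | Path,
    *,
    prefix: str = "drugbank",
    seed: int | None = None,
) -> list[Path]:
    """Write one XML file per version, grouping DDI/DTI that share a label.

    Returns the file paths (one per version, sorted by label) and writes a
    ``manifest.json`` alongside listing version labels, paths and the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_version: dict[str, dict[str, InteractionNetwork]] = {}
    for net in networks:
        slot = by_version.setdefault(net.version_label or "v1", {})
        kind = "dti" if net.bipartite else "ddi"
        if kind in slot:
            raise ValueError(f"two {kind} networks share version label {net.version_label!r}")
        slot[kind] = net

    paths: list[Path] = []
    manifest = {"versions": [], "seed": seed}
    for label in sorted(by_version):
        nets = by_version[label]
        path = out_dir / f"{prefix}_{label}.xml"
        write_release_xml(path, version=label, ddi=nets.get("ddi"), dti=nets.get("dti"))
        paths.append(path)
        manifest["versions"].append({"label": label, "path": path.name})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
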