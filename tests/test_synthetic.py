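"""Synthetic versioned networks and XML fixture round trips."""

from __future__ import annotations

import numpy as np
import pytest

from drugnets.build import build_ddi, build_dti
from drugnets.ingest import filter_approved, parse_release
from drugnets.netstats import degree, summarize
from drugnets.powerlaw import fit_power_law
from drugnets.synthetic import (
    ConfigError,
    SyntheticConfig,
    generate_ddi_series,
    generate_dti,
    write_fixture_xml,
    write_release_xml,
)

from .conftest import make_net


def small_cfg(**kw):
    base = dict(n_drugs=100, n_targets=80, n_versions=2,
                ddi_density_schedule=(0.02, 0.13), seed=1)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_schedule_length_mismatch(self):
        with pytest.raises(ConfigError):
            small_cfg(n_versions=3)

    def test_density_outside_unit_interval(self):
        with pytest.raises(ConfigError):
            small_cfg(ddi_density_schedule=(0.02, 1.0))

    def test_decreasing_schedule_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(ddi_density_schedule=(0.13, 0.02))

    def test_mean_degree_exceeding_partition_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(dti_mean_degree=90)

    def test_bad_group_probability(self):
        with pytest.raises(ConfigError):
            small_cfg(group_label_probabilities={"approved": 1.5})


class TestDDISeries:
    def test_densities_track_schedule(self):
        nets = generate_ddi_series(small_cfg())
        assert len(nets) == 2
        for net, target in zip(nets, (0.02, 0.13)):
            net.validate()
            assert summarize(net).density == pytest.approx(target, abs=0.005)

    def test_versions_are_edge_supersets(self):
        v1, v2 = generate_ddi_series(small_cfg())
        assert v1.edges <= v2.edges

    def test_constant_schedule_gives_identical_versions(self):
        v1, v2 = generate_ddi_series(small_cfg(ddi_density_schedule=(0.05, 0.05)))
        assert v1.edges == v2.edges

    def test_removal_fraction_breaks_strict_superset(self):
        v1, v2 = generate_ddi_series(
            small_cfg(removal_fraction=0.1,
                      ddi_density_schedule=(0.05, 0.08))
        )
        assert len(v1.edges - v2.edges) > 0
        assert summarize(v2).density == pytest.approx(0.08, abs=0.005)

    def test_deterministic_given_seed(self):
        a = generate_ddi_series(small_cfg())
        b = generate_ddi_series(small_cfg())
        assert [n.edges for n in a] == [n.edges for n in b]

    def test_initial_version_heavy_tailed_degrees(self):
        cfg = SyntheticConfig(n_drugs=500, n_targets=10, n_versions=1,
                              ddi_density_schedule=(0.004,), seed=9)
        (net,) = generate_ddi_series(cfg)
        degs = list(degree(net).values.values())
        fit = fit_power_law(degs)
        assert 1.5 < fit.alpha < 4.5


class TestDTI:
    def test_bipartite_no_same_side_edges(self):
        net = generate_dti(SyntheticConfig(
            n_drugs=500, n_targets=400, n_versions=1,
            ddi_density_schedule=(0.02,), dti_mean_degree=3.6, seed=7))
        net.validate()  # checks every edge is drug->target
        assert net.bipartite and net.directed

    def test_mean_degree_within_ten_percent(self):
        net = generate_dti(SyntheticConfig(
            n_drugs=500, n_targets=400, n_versions=1,
            ddi_density_schedule=(0.02,), dti_mean_degree=3.6, seed=7))
        mean_out = net.n_edges / len(net.drugs)
        assert abs(mean_out - 3.6) / 3.6 < 0.1

    def test_target_indegree_exponent_in_range(self):
        net = generate_dti(SyntheticConfig(
            n_drugs=500, n_targets=400, n_versions=1,
            ddi_density_schedule=(0.02,), dti_mean_degree=3.6, seed=7))
        indeg = [v for v in degree(net, "in").values.values() if v > 0]
        fit = fit_power_law(indeg)
        assert 2 <= fit.alpha <= 4

    def test_deterministic_given_seed(self):
        kw = dict(n_drugs=120, n_targets=90, n_versions=1,
                  ddi_density_schedule=(0.02,), seed=3)
        a = generate_dti(SyntheticConfig(**kw))
        b = generate_dti(SyntheticConfig(**kw))
        assert a.edges == b.edges


class TestFixtureXML:
    def test_ddi_round_trip(self, tmp_path):
        nets = generate_ddi_series(small_cfg())
        paths = write_fixture_xml(nets, tmp_path, seed=1)
        assert len(paths) == 2
        for net, path in zip(nets, paths):
            records = parse_release(path)
            rebuilt = build_ddi(records, version_label=net.version_label)
            assert rebuilt.nodes == net.nodes
            assert rebuilt.edges == net.edges

    def test_dti_round_trip(self, tmp_path):
        net = generate_dti(SyntheticConfig(
            n_drugs=60, n_targets=50, n_versions=1,
            ddi_density_schedule=(0.02,), dti_mean_degree=2.5, seed=4))
        path = write_release_xml(tmp_path / "dti.xml", version="v1", dti=net)
        rebuilt = build_dti(parse_release(path), version_label=net.version_label)
        assert rebuilt.edges == net.edges
        assert set(rebuilt.nodes) == set(net.nodes)

    def test_byte_identical_for_identical_seeds(self, tmp_path):
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            write_fixture_xml(generate_ddi_series(small_cfg()), tmp_path / d, seed=1)
        a = (tmp_path / "a" / "drugbank_synth-1.xml").read_bytes()
        b = (tmp_path / "b" / "drugbank_synth-1.xml").read_bytes()
        assert a == b

    def test_experimental_only_drug_absent_from_approved_set(self, tmp_path):
        net = make_net([("SD1", "SD2"), ("SD2", "SD3")])
        net = net.__class__(
            nodes=net.nodes, node_kind=net.node_kind, edges=net.edges,
            bipartite=False, directed=False, version_label="v1",
            node_groups={"SD1": frozenset({"experimental"}),
                         "SD2": frozenset({"approved"}),
                         "SD3": frozenset({"approved"})},
        )
        path = write_release_xml(tmp_path / "r.xml", version="v1", ddi=net)
        kept = filter_approved(parse_release(path))
        assert {r.drug_id for r in kept} == {"SD2", "SD3"}

    def test_empty_network_valid_xml(self, tmp_path):
        path = write_release_xml(tmp_path / "empty.xml", version="v0")
        records = parse_release(path)
        assert records == []

    def test_manifest_written(self, tmp_path):
        import json
        write_fixture_xml(generate_ddi_series(small_cfg()), tmp_path, seed=1)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert [v["label"] for v in manifest["versions"]] == ["synth-1", "synth-2"]
        assert manifest["seed"] == 1

    def test_unwritable_path_reports_path(self, tmp_path):
        net = generate_ddi_series(small_cfg())[0]
        with pytest.raises(OSError, match="no/such/dir"):
            write_release_xml(tmp_path / "no" / "such" / "dir" / "x.xml",
                              version="v1", ddi=net)
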