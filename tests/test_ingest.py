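"""Parsing of release XML and the approved-human-drug filter."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugnets.ingest import (
    DrugRecord,
    ReleaseParseError,
    TargetRecord,
    filter_approved,
    parse_release,
)

from .conftest import make_record

XML_THREE_DRUGS = """<?xml version="1.0" encoding="UTF-8"?>
<drugbank version="test">
  <drug><drugbank-id primary="true">DB001</drugbank-id><name>Alpha</name>
    <groups><group>approved</group></groups>
    <drug-interactions>
      <drug-interaction><drugbank-id>DB002</drugbank-id><name>Beta</name></drug-interaction>
    </drug-interactions>
    <targets>
      <target><id>P12345</id><organism>Humans</organism><known-action>yes</known-action></target>
      <target><id>Q99999</id><organism>Mouse</organism></target>
    </targets>
  </drug>
  <drug><drugbank-id>DB002</drugbank-id><name>Beta</name>
    <groups><group>approved</group><group>investigational</group></groups>
    <drug-interactions>
      <drug-interaction><drugbank-id>DB003</drugbank-id></drug-interaction>
    </drug-interactions>
  </drug>
  <drug><drugbank-id>DB003</drugbank-id><name>Gamma</name>
    <groups><group>experimental</group></groups>
  </drug>
</drugbank>
"""


@pytest.fixture
def release_path(tmp_path):
    p = tmp_path / "release.xml"
    p.write_text(XML_THREE_DRUGS)
    return p


def test_parse_three_drug_release(release_path):
    records = parse_release(release_path)
    assert [r.drug_id for r in records] == ["DB001", "DB002", "DB003"]
    by_id = {r.drug_id: r for r in records}
    assert by_id["DB001"].interactions == {"DB002"}
    assert by_id["DB002"].interactions == {"DB003"}
    assert by_id["DB001"].groups == {"approved"}
    assert by_id["DB002"].groups == {"approved", "investigational"}
    # targets parsed verbatim, organism retained for later filtering
    assert [t.target_id for t in by_id["DB001"].targets] == ["P12345", "Q99999"]
    assert by_id["DB001"].targets[0].known_action is True


def test_namespaced_release_parses(tmp_path):
    """Real releases carry a default namespace and extra elements; only the
    supported paths are read and the namespace is transparent."""
    xml = """<?xml version="1.0" encoding="UTF-8"?>
    <drugbank xmlns="http://www.drugbank.ca" version="5.1">
      <drug type="small molecule">
        <drugbank-id primary="true">DB01050</drugbank-id>
        <name>Ibuprofen</name>
        <groups><group>approved</group></groups>
        <drug-interactions>
          <drug-interaction><drugbank-id>DB00001</drugbank-id></drug-interaction>
        </drug-interactions>
        <targets>
          <target><id>BE0000017</id><organism>Humans</organism>
            <known-action>yes</known-action>
            <polypeptide id="P23219" source="Swiss-Prot"><name>PGHS-1</name></polypeptide>
          </target>
        </targets>
      </drug>
    </drugbank>"""
    p = tmp_path / "ns.xml"
    p.write_text(xml)
    (rec,) = parse_release(p)
    assert rec.drug_id == "DB01050"
    assert rec.interactions == {"DB00001"}
    assert rec.targets[0].target_id == "BE0000017"
    assert rec.targets[0].known_action is True


def test_duplicate_id_keeps_first_and_counts(tmp_path):
    xml = """<drugbank>
      <drug><drugbank-id>DB001</drugbank-id><name>First</name></drug>
      <drug><drugbank-id>DB001</drugbank-id><name>Second</name></drug>
    </drugbank>"""
    p = tmp_path / "dup.xml"
    p.write_text(xml)
    records, stats = parse_release(p, return_stats=True)
    assert len(records) == 1
    assert records[0].name == "First"
    assert stats.n_duplicate_ids == 1


def test_missing_id_skipped_with_count(tmp_path):
    xml = """<drugbank>
      <drug><name>Anonymous</name></drug>
      <drug><drugbank-id>DB001</drugbank-id></drug>
    </drugbank>"""
    p = tmp_path / "noid.xml"
    p.write_text(xml)
    records, stats = parse_release(p, return_stats=True)
    assert [r.drug_id for r in records] == ["DB001"]
    assert stats.n_skipped_missing_id == 1


def test_malformed_xml_raises_with_location(tmp_path):
    p = tmp_path / "broken.xml"
    p.write_text("<drugbank><drug><drugbank-id>DB001</drugbank-id></drugbank>")
    with pytest.raises(ReleaseParseError, match="line"):
        parse_release(p)


def test_self_interaction_dropped(tmp_path):
    xml = """<drugbank><drug><drugbank-id>DB001</drugbank-id>
      <drug-interactions>
        <drug-interaction><drugbank-id>DB001</drugbank-id></drug-interaction>
        <drug-interaction><drugbank-id>DB002</drugbank-id></drug-interaction>
      </drug-interactions></drug></drugbank>"""
    p = tmp_path / "self.xml"
    p.write_text(xml)
    (rec,) = parse_release(p)
    assert rec.interactions == {"DB002"}


def test_parse_order_independent(tmp_path, release_path):
    """Permuting <drug> elements yields the same record set."""
    reordered = XML_THREE_DRUGS
    # move the DB003 block before DB001 by crude text surgery
    blocks = reordered.split("<drug>")
    header, drugs = blocks[0], ["<drug>" + b for b in blocks[1:]]
    tail = drugs[-1].rsplit("</drugbank>", 1)
    drugs[-1] = tail[0]
    permuted = header + "".join(reversed(drugs)) + "</drugbank>"
    p = tmp_path / "permuted.xml"
    p.write_text(permuted)
    assert set(parse_release(p)) == set(parse_release(release_path))


class TestFilterApproved:
    def test_plain_approved_kept(self):
        assert filter_approved([make_record("A", groups=("approved",))])

    @pytest.mark.parametrize("groups", [
        ("approved", "withdrawn"),
        ("approved", "vet_approved"),
        ("experimental",),
        ("investigational",),
    ])
    def test_excluded_groups_dropped(self, groups):
        assert filter_approved([make_record("A", groups=groups)]) == []

    def test_approved_investigational_kept_permissive_dropped_strict(self):
        rec = make_record("A", groups=("approved", "investigational"))
        assert len(filter_approved([rec])) == 1
        assert filter_approved([rec], policy="strict") == []

    def test_non_human_targets_removed(self):
        rec = make_record(
            "A",
            targets=(TargetRecord("P1", "Humans"), TargetRecord("P2", "Mouse"),
                     TargetRecord("P3", "  humans ")),
        )
        (kept,) = filter_approved([rec])
        assert [t.target_id for t in kept.targets] == ["P1", "P3"]

    def test_interaction_ids_untouched(self):
        rec = make_record("A", interactions=("GONE", "B"))
        (kept,) = filter_approved([rec])
        assert kept.interactions == {"GONE", "B"}

    @given(
        st.lists(
            st.builds(
                DrugRecord,
                drug_id=st.text(min_size=1, max_size=4),
                groups=st.frozensets(
                    st.sampled_from(
                        ["approved", "investigational", "experimental",
                         "withdrawn", "vet_approved"]
                    )
                ),
            ),
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_idempotent(self, records):
        once = filter_approved(records)
        assert filter_approved(once) == once
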