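"""Parsing of DrugBank-style XML releases into drug records.

A release is an XML document with a ``<drugbank>`` root holding repeated
``<drug>`` elements.  Only a small dialect of the schema is read: the primary
``<drugbank-id>``, ``<name>``, ``<groups>``, ``<drug-interactions>`` and
``<targets>`` (id / organism / known-action).  Real releases are a superset of
this dialect; unknown elements are ignored, and parsing is streaming so
multi-gigabyte files are feasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

logger = logging.getLogger(__name__)

#: drug group labels recognised in ``<groups>``; anything else is kept verbatim.
KNOWN_GROUPS = frozenset(
    {
        "approved",
        "investigational",
        "experimental",
        "withdrawn",
        "vet_approved",
        "illicit",
        "nutraceutical",
    }
)


@dataclass(frozen=True)
class TargetRecord:
    """A biological target attached to a drug entry."""

    target_id: str
    organism: str = ""
    known_action: bool | None = None


@dataclass(frozen=True)
class DrugRecord:
    """One parsed drug: identity, group labels, interaction partners, targets.

    ``interactions`` holds partner drug ids exactly as written in the release;
    resolution against the filtered drug set happens at network-build time.
    Self-interactions are dropped at parse time.
    """

    drug_id: str
    name: str = ""
    groups: frozenset[str] = frozenset()
    interactions: frozenset[str] = frozenset()
    targets: tuple[TargetRecord, ...] = ()


@dataclass
class ParseStats:
    """Bookkeeping emitted by :func:`parse_release`."""

    n_records: int = 0
    n_skipped_missing_id: int = 0
    n_duplicate_ids: int = 0
    duplicate_ids: list[str] = field(default_factory=list)


class ReleaseParseError(ValueError):
    """Malformed XML; carries the underlying parser message (with line info)."""


def _localname(tag: object) -> str:
    if not isinstance(tag, str):  # comments / PIs
        return ""
    return tag.rsplit("}", 1)[-1]


def _norm_group(text: str) -> str:
    return text.strip().lower().replace(" ", "_").replace("-", "_")


def _parse_drug_element(el: etree._Element) -> DrugRecord | None:
    drug_id = ""
    name = ""
    groups: set[str] = set()
    interactions: set[str] = set()
    targets: list[TargetRecord] = []

    for child in el:
        tag = _localname(child.tag)
        if tag == "drugbank-id" and not (
            drug_id and child.get("primary") is None
        ):
            # keep the first id, but let a primary="true" id override a
            # non-primary one seen earlier
            if not drug_id or child.get("primary") == "true":
                drug_id = (child.text or "").strip()
        elif tag == "name" and not name:
            name = (child.text or "").strip()
        elif tag == "groups":
            for g in child:
                if _localname(g.tag) == "group" and g.text:
                    groups.add(_norm_group(g.text))
        elif tag == "drug-interactions":
            for di in child:
                if _localname(di.tag) != "drug-interaction":
                    continue
                for sub in di:
                    if _localname(sub.tag) == "drugbank-id" and sub.text:
                        interactions.add(sub.text.strip())
        elif tag == "targets":
            for t in child:
                if _localname(t.tag) != "target":
                    continue
                tid = ""
                organism = ""
                known_action: bool | None = None
                for sub in t:
                    stag = _localname(sub.tag)
                    if stag == "id" and sub.text:
                        tid = sub.text.strip()
                    elif stag == "organism":
                        organism = (sub.text or "").strip()
                    elif stag == "known-action" and sub.text:
                        val = sub.text.strip().lower()
                        if val in ("yes", "no"):
                            known_action = val == "yes"
                if tid:
                    targets.append(TargetRecord(tid, organism, known_action))

    if not drug_id:
        return None
    interactions.discard(drug_id)  # no self-interaction
    return DrugRecord(
        drug_id=drug_id,
        name=name,
        groups=frozenset(groups),
        interactions=frozenset(interactions),
        targets=tuple(targets),
    )


def parse_release(
    xml_path: str | Path, *, return_stats: bool = False
) -> list[DrugRecord] | tuple[list[DrugRecord], ParseStats]:
    """Stream-parse one release into a list of :class:`DrugRecord`.

    One record per top-level ``<drug>`` element.  A ``<drug>`` without an id is
    skipped with a logged warning; a duplicate id keeps the first occurrence.
    Malformed XML raises :class:`ReleaseParseError` with the parser's line
    information.
    """
    xml_path = Path(xml_path)
    stats = ParseStats()
    records: list[DrugRecord] = []
    seen: set[str] = set()

    try:
        context = etree.iterparse(str(xml_path), events=("end",), recover=False)
        for _, el in context:
            if _localname(el.tag) != "drug":
                continue
            parent = el.getparent()
            if parent is None or _localname(parent.tag) != "drugbank":
                continue  # e.g. nested structures in richer schemas
            rec = _parse_drug_element(el)
            if rec is None:
                stats.n_skipped_missing_id += 1
                logger.warning("drug element without drugbank-id skipped")
            elif rec.drug_id in seen:
                stats.n_duplicate_ids += 1
                stats.duplicate_ids.append(rec.drug_id)
                logger.warning("duplicate drug id %s: second occurrence rejected", rec.drug_id)
            else:
                seen.add(rec.drug_id)
                records.append(rec)
                stats.n_records += 1
            # free the processed subtree (streaming memory bound)
            el.clear()
            while el.getprevious() is not None:
                del parent[0]
    except etree.XMLSyntaxError as exc:
        raise ReleaseParseError(f"{xml_path}: {exc}") from exc

    if return_stats:
        return records, stats
    return records


def filter_approved(
    records: Iterable[DrugRecord],
    *,
    policy: str = "permissive",
    organism: str = "Humans",
) -> list[DrugRecord]:
    """Restrict to approved human drugs.

    A record is kept iff ``approved`` is among its groups and neither
    ``withdrawn`` nor ``vet_approved`` is.  Under ``policy="strict"`` any
    ``investigational`` or ``experimental`` label also excludes the drug; the
    default ``"permissive"`` policy keeps approved drugs that carry those
    co-labels, since an approved drug under further investigation is still an
    approved drug.  Target lists are restricted to the given organism
    (case-insensitive, trimmed).  Interaction partner ids are left untouched:
    pruning against the kept set happens at network-build time.

    The filter is idempotent.
    """
    if policy not in ("permissive", "strict"):
        raise ValueError(f"unknown filter policy: {policy!r}")
    org_key = organism.strip().lower()
    kept: list[DrugRecord] = []
    for rec in records:
        if "approved" not in rec.groups:
            continue
        if "withdrawn" in rec.groups or "vet_approved" in rec.groups:
            continue
        if policy == "strict" and (
            "investigational" in rec.groups or "experimental" in rec.groups
        ):
            continue
        human_targets = tuple(
            t for t in rec.targets if t.organism.strip().lower() == org_key
        )
        if human_targets == rec.targets:
            kept.append(rec)
        else:
            kept.append(
                DrugRecord(
                    drug_id=rec.drug_id,
                    name=rec.name,
                    groups=rec.groups,
                    interactions=rec.interactions,
                    targets=human_targets,
                )
            )
    return kept
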