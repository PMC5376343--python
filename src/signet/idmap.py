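"""Canonical protein identifiers across Uniprot, KEGG and HGNC namespaces.

Proteins are referred to by Uniprot accessions without the isoform postfix.
When several Uniprot accessions share the same KEGG or HGNC identifier they
are grouped under one representative accession, preferring a reviewed
(Swiss-Prot) entry, so that unreviewed entries resolve to the associated
reviewed entry whenever one exists.  Groupings induced by different
namespaces are union-merged into a single partition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["IdMap", "IdMapError", "build_id_map", "canonicalize", "strip_isoform"]

# Uniprot-shaped accession, e.g. P43405, Q9Y281, A0A024R1R8; optional -<n> isoform
_ISOFORM_RE = re.compile(r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})-\d+$")


class IdMapError(ValueError):
    """Raised on irreconcilable identifier-mapping input."""


def strip_isoform(raw_id: str) -> str:
    """Drop a trailing ``-<digits>`` isoform suffix from a Uniprot-shaped accession.

    Suffixes are removed only when the stem looks like a Uniprot accession,
    so foreign identifiers containing dashes are left untouched.
    """
    m = _ISOFORM_RE.match(raw_id)
    return raw_id.split("-", 1)[0] if m else raw_id


@dataclass
class IdMap:
    """A partition of protein identifiers into canonical classes.

    Attributes
    ----------
    entries:
        ``(namespace, foreign_id) -> canonical_id`` for every foreign key,
        plus ``("uniprot", accession) -> canonical_id`` for every member.
    canonical_meta:
        per canonical id: ``{"reviewed": bool, "members": [accessions]}``;
        the canonical id is always one of its members.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    canonical_meta: dict[str, dict] = field(default_factory=dict)

    def lookup(self, namespace: str, foreign_id: str) -> str | None:
        return self.entries.get((namespace, foreign_id))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_id_map(
    uniprot_mapping_rows: pd.DataFrame,
    hgnc_rows: pd.DataFrame | None = None,
    reviewed: set[str] | None = None,
) -> IdMap:
    """Build an :class:`IdMap` from Uniprot id-mapping rows.

    Parameters
    ----------
    uniprot_mapping_rows:
        columns ``uniprot_id``, ``namespace``, ``foreign_id`` (the 3-column
        Uniprot idmapping layout).  Isoform suffixes on accessions are
        stripped before grouping.
    hgnc_rows:
        optional table with ``symbol`` and ``uniprot_id`` columns; adds
        ``("HGNC", symbol)`` keys.
    reviewed:
        set of reviewed (Swiss-Prot) accessions.  Unlisted accessions are
        treated as unreviewed.

    Accessions sharing a KEGG or HGNC key are grouped; one representative is
    chosen per group, preferring reviewed entries and breaking ties by
    lexicographic order.  Classes that overlap through different foreign
    keys are union-merged.
    """
    reviewed = reviewed or set()
    required = {"uniprot_id", "namespace", "foreign_id"}
    if not required.issubset(uniprot_mapping_rows.columns):
        raise IdMapError(f"mapping table must have columns {sorted(required)}")

    rows = uniprot_mapping_rows[["uniprot_id", "namespace", "foreign_id"]].astype(str)
    if hgnc_rows is not None and len(hgnc_rows):
        extra = pd.DataFrame(
            {
                "uniprot_id": hgnc_rows["uniprot_id"].astype(str),
                "namespace": "HGNC",
                "foreign_id": hgnc_rows["symbol"].astype(str),
            }
        )
        rows = pd.concat([rows, extra], ignore_index=True)

    rows = rows.assign(uniprot_id=rows["uniprot_id"].map(strip_isoform)).drop_duplicates()

    uf = _UnionFind()
    foreign_members: dict[tuple[str, str], set[str]] = {}
    for rec in rows.itertuples(index=False):
        key = (rec.namespace, rec.foreign_id)
        foreign_members.setdefault(key, set()).add(rec.uniprot_id)
    for members in foreign_members.values():
        members = sorted(members)
        for other in members[1:]:
            uf.union(members[0], other)
    for acc in rows["uniprot_id"]:
        uf.find(acc)

    classes: dict[str, set[str]] = {}
    for acc in uf.parent:
        classes.setdefault(uf.find(acc), set()).add(acc)

    idmap = IdMap()
    rep_of: dict[str, str] = {}
    for members in classes.values():
        rev = sorted(m for m in members if m in reviewed)
        rep = rev[0] if rev else min(members)
        for m in members:
            rep_of[m] = rep
            idmap.entries[("uniprot", m)] = rep
        idmap.canonical_meta[rep] = {
            "reviewed": rep in reviewed,
            "members": sorted(members),
        }

    for (namespace, foreign_id), members in foreign_members.items():
        reps = {rep_of[m] for m in members}
        if len(reps) != 1:  # cannot happen after union-merge; guard anyway
            raise IdMapError(
                f"foreign key {namespace}:{foreign_id} maps to conflicting "
                f"canonical ids {sorted(reps)}"
            )
        idmap.entries[(namespace, foreign_id)] = reps.pop()

    return idmap


def canonicalize(raw_id: str, idmap: IdMap, namespace: str = "uniprot") -> tuple[str, bool]:
    """Resolve *raw_id* to its canonical id.

    The isoform suffix is stripped before lookup.  Returns
    ``(canonical_id, known)``; unknown ids are returned stripped with
    ``known=False`` rather than dropped, so coverage can be reported.
    """
    stripped = strip_isoform(raw_id)
    hit = idmap.entries.get((namespace, stripped))
    if hit is None and namespace != "uniprot":
        hit = idmap.entries.get(("uniprot", stripped))
    if hit is None:
        return stripped, False
    return hit, True
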