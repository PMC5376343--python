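"""Curation of kinase-target sets from quantitative (phospho-)proteomic tables.

Three evidence classes are produced and kept distinct, because the edge
distance scheme treats them differently downstream:

* ``complex-level`` — proteins whose SILAC ratio between conditions varies
  by at least a configurable fraction (default 10%), i.e. differential
  enrichment of phospho-tyrosine-dependent protein complexes;
* ``site-level`` — proteins carrying a phospho-peptide observed exclusively
  in one experimental condition (differential phosphorylation);
* ``direct-substrate`` — proteins whose in-vitro-phosphorylated peptide is
  also found exclusively in the positive cellular condition.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
import pandas as pd

__all__ = [
    "TargetEvidence",
    "TargetSet",
    "PeptideKey",
    "select_ratio_targets",
    "select_exclusive_peptides",
    "map_peptides_to_proteins",
    "select_direct_substrates",
    "merge_target_sets",
]

COMPLEX_LEVEL = "complex-level"
SITE_LEVEL = "site-level"
DIRECT_SUBSTRATE = "direct-substrate"

_SITE_RE = re.compile(r"^[STY]\d+$")

#: peptide identity used throughout: (sequence, phosphosite), with the
#: methionine-oxidation state deliberately left out so that peptide pairs
#: differing only by Met oxidation collapse onto one key.
PeptideKey = tuple[str, str]


@dataclass
class TargetEvidence:
    tags: set[str] = field(default_factory=set)
    direction: str | None = None  # up | down | mixed | None


@dataclass
class TargetSet:
    """Curated targets with per-protein evidence tags and direction."""

    members: dict[str, TargetEvidence] = field(default_factory=dict)
    peptide_records: pd.DataFrame | None = None

    def ids(self) -> set[str]:
        return set(self.members)

    def with_tag(self, tag: str) -> set[str]:
        return {i for i, ev in self.members.items() if tag in ev.tags}

    def __len__(self) -> int:
        return len(self.members)

    def add(self, protein_id: str, tag: str, direction: str | None) -> None:
        ev = self.members.setdefault(protein_id, TargetEvidence())
        ev.tags.add(tag)
        ev.direction = _merge_direction(ev.direction, direction)


def _merge_direction(a: str | None, b: str | None) -> str | None:
    if a is None:
        return b
    if b is None or a == b:
        return a
    return "mixed"


def select_ratio_targets(protein_ratios: pd.DataFrame, threshold: float = 0.10) -> TargetSet:
    """Select proteins whose SILAC ratio varies from 1 by at least *threshold*.

    The bound is inclusive (a ratio of 1.10 or 0.90 at threshold 0.10 is
    retained); a small absolute guard absorbs binary rounding of printed
    ratios.  Direction is ``up`` for ratios above 1 and ``down`` below.
    Non-positive ratios are rejected with a warning.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    out = TargetSet()
    for rec in protein_ratios.itertuples(index=False):
        pid, ratio = str(rec.id), float(rec.silac_ratio)
        if ratio <= 0:
            warnings.warn(f"non-positive SILAC ratio {ratio} for {pid}: row rejected")
            continue
        delta = abs(ratio - 1.0)
        if delta > 0 and delta >= threshold - 1e-12:
            out.add(pid, COMPLEX_LEVEL, "up" if ratio > 1 else "down")
    return out


def select_exclusive_peptides(
    peptides: pd.DataFrame,
) -> tuple[set[PeptideKey], set[PeptideKey], set[PeptideKey]]:
    """Partition phospho-peptides into condition-exclusive and shared sets.

    A peptide is keyed by (sequence, phosphosite); the oxidation state is
    ignored when building the key, so a pair of observations differing only
    by methionine oxidation counts as the same peptide and is excluded as
    shared.  Returns ``(pos_exclusive, neg_exclusive, excluded_shared)``.
    Rows with malformed phosphosite notation (not e.g. ``Y123``) are
    rejected with a warning.
    """
    by_key: dict[PeptideKey, set[str]] = {}
    for rec in peptides.itertuples(index=False):
        site = str(rec.phosphosite)
        cond = str(rec.condition)
        if not _SITE_RE.match(site):
            warnings.warn(f"malformed phosphosite {site!r}: row rejected")
            continue
        if cond not in ("pos", "neg"):
            warnings.warn(f"unknown condition label {cond!r}: row rejected")
            continue
        by_key.setdefault((str(rec.sequence), site), set()).add(cond)

    pos = {k for k, conds in by_key.items() if conds == {"pos"}}
    neg = {k for k, conds in by_key.items() if conds == {"neg"}}
    shared = {k for k, conds in by_key.items() if len(conds) == 2}
    return pos, neg, shared


def map_peptides_to_proteins(
    pos_peptides: set[PeptideKey],
    neg_peptides: set[PeptideKey],
    protein_index: dict[PeptideKey, list[str]],
) -> TargetSet:
    """Lift condition-exclusive peptides to site-level protein targets.

    Sequence redundancy is handled by inclusion: a peptide matching several
    proteins contributes all of them.  A protein with exclusive peptides in
    both conditions gets direction ``mixed``.  Peptides missing from the
    index are reported with a warning, not fatal.
    """
    out = TargetSet()
    records = []
    for key_set, direction in ((pos_peptides, "up"), (neg_peptides, "down")):
        for key in sorted(key_set):
            proteins = protein_index.get(key)
            if not proteins:
                warnings.warn(f"orphan peptide {key}: no protein match")
                continue
            for pid in proteins:
                out.add(pid, SITE_LEVEL, direction)
                records.append(
                    {"sequence": key[0], "phosphosite": key[1], "protein": pid,
                     "condition": "pos" if direction == "up" else "neg"}
                )
    out.peptide_records = pd.DataFrame(
        records, columns=["sequence", "phosphosite", "protein", "condition"]
    )
    return out


def select_direct_substrates(
    invitro_peptides: dict[PeptideKey, list[str]],
    cellular_pos_peptides: set[PeptideKey],
    forced_includes: list[str] | None = None,
    forced_excludes: list[tuple[str, str | None]] | None = None,
) -> TargetSet:
    """Select direct substrates: in-vitro peptides retrieved in cells.

    A protein qualifies when at least one of its in-vitro phosphorylated
    peptides is in the cellular positive-exclusive set.  ``forced_excludes``
    entries are ``(protein_id, peptide_sequence_or_None)``: with ``None``
    the whole protein is excluded, otherwise only that one peptide — a
    protein with another matching peptide survives a per-peptide
    exclusion.  ``forced_includes`` adds proteins unconditionally.  Both
    lists ship as configuration, not code.
    """
    forced_includes = forced_includes or []
    forced_excludes = forced_excludes or []
    excluded_proteins = {pid for pid, seq in forced_excludes if seq is None}
    excluded_peptides = {(pid, seq) for pid, seq in forced_excludes if seq is not None}

    seen_proteins = {p for plist in invitro_peptides.values() for p in plist}
    for pid in excluded_proteins | {pid for pid, _ in excluded_peptides}:
        if pid not in seen_proteins and pid not in forced_includes:
            warnings.warn(f"exclusion of {pid} which never occurs in the in-vitro set")

    out = TargetSet()
    for key, proteins in sorted(invitro_peptides.items()):
        if key not in cellular_pos_peptides:
            continue
        for pid in proteins:
            if pid in excluded_proteins or (pid, key[0]) in excluded_peptides:
                continue
            out.add(pid, DIRECT_SUBSTRATE, "up")
    for pid in forced_includes:
        out.add(pid, DIRECT_SUBSTRATE, "up")
    return out


def merge_target_sets(sets: list[TargetSet]) -> tuple[TargetSet, pd.DataFrame]:
    """Union target sets, accumulating tags; returns (merged, overlap report).

    The report counts proteins per combination of evidence tags, e.g. how
    many carry both complex-level and site-level evidence.
    """
    merged = TargetSet()
    frames = []
    for ts in sets:
        for pid, ev in ts.members.items():
            for tag in ev.tags:
                merged.add(pid, tag, ev.direction)
        if ts.peptide_records is not None:
            frames.append(ts.peptide_records)
    if frames:
        merged.peptide_records = pd.concat(frames, ignore_index=True).drop_duplicates()

    combo_counts: dict[str, int] = {}
    for ev in merged.members.values():
        combo = "+".join(sorted(ev.tags))
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    report = pd.DataFrame(
        sorted(combo_counts.items()), columns=["tag_combination", "n_proteins"]
    )
    return merged, report
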