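"""Readers for the standard input formats.

KGML (KEGG pathway XML) is parsed with lxml; OBO ontologies through
obonet; GAF annotation files through biopython's GOA iterator; GMT gene
sets through gseapy; extended-SIF and the tabular inputs (SILAC ratio
tables, phosphopeptide tables, Uniprot id-mapping) with pandas.  All
readers emit plain containers (:class:`~signet.enrichment.Pathway`,
DataFrames, dicts) — identifier canonicalization happens at merge time,
not here.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from Bio.UniProt import GOA
from gseapy import read_gmt as _gseapy_read_gmt
from lxml import etree

from .curation import PeptideKey
from .enrichment import Pathway

__all__ = [
    "DEFAULT_KGML_TYPE_MAP",
    "DEFAULT_SIF_TYPE_MAP",
    "read_kgml",
    "read_sif",
    "read_gmt",
    "read_obo",
    "read_gaf",
    "read_ratio_table",
    "read_peptide_table",
    "read_idmapping",
    "peptide_protein_index",
]

#: KGML relation subtype -> (interaction type, sign); configuration, not code
DEFAULT_KGML_TYPE_MAP: dict[str, tuple[str, str]] = {
    "phosphorylation": ("phosphorylation", "unknown"),
    "dephosphorylation": ("phosphorylation", "negative"),
    "activation": ("regulation", "positive"),
    "inhibition": ("regulation", "negative"),
    "expression": ("regulation", "positive"),
    "repression": ("regulation", "negative"),
    "ubiquitination": ("modification", "unknown"),
    "glycosylation": ("modification", "unknown"),
    "methylation": ("modification", "unknown"),
    "binding/association": ("other", "unknown"),
    "indirect effect": ("other", "unknown"),
    "compound": ("other", "unknown"),
}

#: extended-SIF relation -> (interaction type, sign, directed)
DEFAULT_SIF_TYPE_MAP: dict[str, tuple[str, str, bool]] = {
    "controls-phosphorylation-of": ("phosphorylation", "unknown", True),
    "controls-dephosphorylation-of": ("phosphorylation", "negative", True),
    "controls-state-change-of": ("modification", "unknown", True),
    "controls-expression-of": ("regulation", "unknown", True),
    "controls-transport-of": ("modification", "unknown", True),
    "catalysis-precedes": ("other", "unknown", True),
    "in-complex-with": ("other", "unknown", False),
    "interacts-with": ("other", "unknown", False),
    "activates": ("regulation", "positive", True),
    "inhibits": ("regulation", "negative", True),
    "phosphorylates": ("phosphorylation", "unknown", True),
}


def read_kgml(
    path: str | Path,
    type_map: dict[str, tuple[str, str]] | None = None,
    source_db: str = "KEGG",
) -> Pathway:
    """Parse one KGML file into a :class:`Pathway`.

    Gene entries listing several identifiers, and explicit ``group``
    entries, both become group constructs (interchangeable proteins behind
    one pathway node).  Relation subtypes are mapped to interaction types
    and signs by *type_map*; relations with no mapped subtype become
    ``other``/``unknown`` edges.
    """
    type_map = type_map if type_map is not None else DEFAULT_KGML_TYPE_MAP
    tree = etree.parse(str(path))
    root = tree.getroot()
    pathway_id = root.get("name", str(path)).removeprefix("path:")

    entry_ids: dict[str, list[str]] = {}  # KGML entry id -> protein ids
    groups: dict[str, list[str]] = {}
    components: dict[str, list[str]] = {}
    members: set[str] = set()

    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "group":
            components[eid] = [c.get("id") for c in entry.findall("component")]
            continue
        if etype not in ("gene", "enzyme", "protein"):
            continue  # compounds, maps, orthologs: not protein nodes
        names = entry.get("name", "").split()
        if not names:
            continue
        entry_ids[eid] = names
        members.update(names)
        if len(names) > 1:  # paralog set shown as one KGML node
            groups[f"entry:{eid}"] = names

    def local_ref(eid: str) -> str | None:
        if eid in components:
            return f"group:{eid}"
        if eid in entry_ids:
            names = entry_ids[eid]
            return names[0] if len(names) == 1 else f"entry:{eid}"
        return None

    for gid, comp_ids in components.items():
        mem: list[str] = []
        for cid in comp_ids:
            ref = local_ref(cid)
            if ref is not None:
                mem.append(ref)
        if mem:
            groups[f"group:{gid}"] = mem

    interactions: list[tuple] = []
    for rel in root.findall("relation"):
        u = local_ref(rel.get("entry1"))
        v = local_ref(rel.get("entry2"))
        if u is None or v is None:
            continue
        types: set[str] = set()
        signs: list[str] = []
        for st in rel.findall("subtype"):
            mapped = type_map.get(st.get("name"))
            if mapped:
                types.add(mapped[0])
                signs.append(mapped[1])
        if not types:
            types, signs = {"other"}, ["unknown"]
        sign = "unknown"
        for s in signs:
            if s != "unknown":
                sign = s if sign in ("unknown", s) else "unclear"
        interactions.append((u, v, types, sign))

    return Pathway(
        id=pathway_id, source_db=source_db, members=members,
        interactions=interactions, groups=groups,
        name=root.get("title", pathway_id),
    )


def read_sif(
    path: str | Path,
    pathway_id: str | None = None,
    type_map: dict[str, tuple[str, str, bool]] | None = None,
    source_db: str = "PathwayCommons",
    pathway_col: str | None = None,
) -> list[Pathway]:
    """Read a (possibly extended) SIF file into pathways.

    The three leading columns are participant A, interaction type and
    participant B; a header row is detected and skipped.  By default the
    whole file is one pathway (*pathway_id* defaults to the file stem);
    with *pathway_col* naming a column (e.g. ``PATHWAY_NAMES``) rows are
    split into one pathway per value, on ``;``-separated lists.
    """
    type_map = type_map if type_map is not None else DEFAULT_SIF_TYPE_MAP
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment=None)
    first = [str(x).upper() for x in df.iloc[0].tolist()[:3]]
    if first and first[0].startswith("PARTICIPANT"):
        df.columns = [str(x) for x in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
    else:
        cols = ["PARTICIPANT_A", "INTERACTION_TYPE", "PARTICIPANT_B"]
        df.columns = cols + [f"col{i}" for i in range(3, df.shape[1])]

    def rows_to_pathway(pid: str, rows: pd.DataFrame) -> Pathway:
        members: set[str] = set()
        interactions: list[tuple] = []
        for rec in rows.itertuples(index=False):
            a, rel, b = rec[0], rec[1], rec[2]
            itype, sign, directed = type_map.get(rel, ("other", "unknown", True))
            members.update((a, b))
            interactions.append((a, b, {itype}, sign))
            if not directed:
                interactions.append((b, a, {itype}, sign))
        return Pathway(id=pid, source_db=source_db, members=members, interactions=interactions)

    if pathway_col is None:
        pid = pathway_id or Path(path).stem
        return [rows_to_pathway(pid, df)]

    buckets: dict[str, list[int]] = {}
    for i, val in enumerate(df[pathway_col].fillna("")):
        for name in str(val).split(";"):
            name = name.strip()
            if name:
                buckets.setdefault(name, []).append(i)
    return [rows_to_pathway(name, df.iloc[idx]) for name, idx in sorted(buckets.items())]


def read_gmt(path: str | Path, source_db: str = "GMT") -> list[Pathway]:
    """Read a GMT gene-set file as membership-only pathways."""
    sets = _gseapy_read_gmt(str(path))
    return [
        Pathway(id=name, source_db=source_db, members=set(genes))
        for name, genes in sorted(sets.items())
    ]


def read_obo(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO ontology (edges child -> parent, keyed by relation)."""
    return obonet.read_obo(str(path))


def read_gaf(path: str | Path, exclude_evidence: set[str] | None = None) -> pd.DataFrame:
    """Read a GAF annotation file into (db_object_id, go_id, evidence, aspect).

    Evidence codes in *exclude_evidence* (e.g. ``{"IEA"}``) are dropped;
    by default no filtering is applied.
    """
    rows = []
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if exclude_evidence and rec["Evidence"] in exclude_evidence:
                continue
            rows.append(
                {
                    "db_object_id": rec["DB_Object_ID"],
                    "go_id": rec["GO_ID"],
                    "evidence": rec["Evidence"],
                    "aspect": rec["Aspect"],
                }
            )
    return pd.DataFrame(rows, columns=["db_object_id", "go_id", "evidence", "aspect"])


def read_ratio_table(path: str | Path) -> pd.DataFrame:
    """Read a per-protein SILAC ratio table (columns ``id``, ``silac_ratio``)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "silac_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"ratio table lacks columns {sorted(missing)}")
    return df


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a phosphopeptide table.

    Expected columns: ``sequence``, ``phosphosite``, ``oxidation_state``,
    ``condition`` and optionally ``proteins`` (``;``-separated matches).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sequence", "phosphosite", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"peptide table lacks columns {sorted(missing)}")
    if "oxidation_state" not in df.columns:
        df["oxidation_state"] = "none"
    return df


def peptide_protein_index(peptides: pd.DataFrame) -> dict[PeptideKey, list[str]]:
    """Build the peptide -> protein-ids index from a table's ``proteins`` column."""
    index: dict[PeptideKey, list[str]] = {}
    for rec in peptides.itertuples(index=False):
        key = (str(rec.sequence), str(rec.phosphosite))
        prots = [p for p in str(getattr(rec, "proteins", "")).split(";") if p]
        merged = set(index.get(key, [])) | set(prots)
        index[key] = sorted(merged)
    return index


def read_idmapping(path: str | Path, reviewed_path: str | Path | None = None) -> tuple[pd.DataFrame, set[str]]:
    """Read a 3-column Uniprot id-mapping TSV plus an optional reviewed-accession list."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["uniprot_id", "namespace", "foreign_id"], dtype=str
    )
    reviewed: set[str] = set()
    if reviewed_path is not None:
        reviewed = {
            line.strip() for line in Path(reviewed_path).read_text().splitlines() if line.strip()
        }
    return df, reviewed
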