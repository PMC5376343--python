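"""Synthetic fixture generation with planted ground truth.

Generates a complete, self-consistent input bundle — pathway files
(extended SIF plus one KGML with a group construct), a GMT gene-set file,
a GAF/OBO annotation pair, a Uniprot-style id-mapping table and the two
curation tables — in which one or more source->kinase->target paths are
planted.  The kinase carries the tyrosine-kinase GO term, the target
site-level evidence and the source complex-level evidence, so under the
distance scheme the planted path is strictly shorter than any noise
route.  The generator certifies its own ground truth: it runs the full
pipeline (curation, enrichment with rescue, merge, annotation, distance
assignment, random-walk refinement, extraction) and resamples the noise
edges until the planted paths are recovered exactly at epsilon = 0 and
with zero overflow after refinement at epsilon = 0.2.

Everything is deterministic given the seed: the same spec yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, curation, enrichment, pathsearch, walk, weights
from .enrichment import Pathway
from .formats import DEFAULT_SIF_TYPE_MAP
from .idmap import build_id_map

__all__ = ["FixtureSpec", "FixtureBundle", "TableBundle", "generate_fixture", "generate_two_dataset_tables"]

_AA = list("ACDEFGHIKLMNPQRSTVWY")

#: synthetic child terms used by the ontology stub (marked synthetic: these
#: GO ids do not exist in the real ontology)
SYNTH_ADHESION_CHILD = "GO:0099901"
SYNTH_KINASE_CHILD = "GO:0099902"

_CATEGORY_ROOTS = {
    "GO:0007155": "cell adhesion",
    "GO:0048870": "cell motility",
    "GO:0034330": "cell junction organization",
    "GO:0022610": "biological adhesion",
    "GO:0060352": "cell adhesion molecule production",
    "GO:0030030": "cell projection organization",
    "GO:0008283": "cell population proliferation",
    "GO:0007049": "cell cycle",
    "GO:0008219": "cell death",
    "GO:0019835": "cytolysis",
    "GO:0000920": "septum digestion after cytokinesis",
    "GO:0007569": "cell aging",
    "GO:0051301": "cell division",
    "GO:0060242": "contact inhibition",
    "GO:0002376": "immune system process",
    "GO:0001906": "cell killing",
    "GO:0030154": "cell differentiation",
    "GO:0036166": "phenotypic switching",
    "GO:0004713": "protein tyrosine kinase activity",
    "GO:0004725": "protein tyrosine phosphatase activity",
}


@dataclass
class FixtureSpec:
    """Size and structure of a synthetic bundle (all tunables in one place)."""

    n_proteins: int = 60
    n_pathways: int = 6
    pathway_size_range: tuple[int, int] = (8, 15)
    n_planted_paths: int = 1
    noise_edges: int = 80
    seed: int = 0
    target_fraction: float = 0.25
    include_group_pathway: bool = True
    # curation-table structure (counts known by construction)
    n_ratio_proteins: int = 20
    n_ratio_hits: int = 8
    n_neg_exclusive: int = 5
    n_shared_peptides: int = 4
    n_oxidation_pairs: int = 2
    n_mixed_proteins: int = 2
    n_ambiguous_peptides: int = 2
    n_direct_substrates: int = 3
    max_resample: int = 50

    def validate(self) -> None:
        if self.pathway_size_range[1] < 3:
            raise ValueError("planted path (3 nodes) longer than maximum pathway size")
        if self.n_planted_paths * 2 + 1 > self.n_proteins:
            raise ValueError("not enough proteins for the planted paths")
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target_fraction must be in [0, 1]")


@dataclass
class TableBundle:
    """Curation tables plus their ground truth, known by construction."""

    ratio_table: pd.DataFrame
    peptide_table: pd.DataFrame
    invitro_table: pd.DataFrame
    expected: dict


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    proteins: list[str]
    source: str
    planted_paths: list[tuple[str, str, str]]
    planted_edges: set[tuple[str, str]]
    site_targets: list[str]
    complex_targets: list[str]
    kinases: list[str]
    pathways: list[Pathway]
    planted_pathway_ids: list[str]
    noise_edge_list: list[tuple[str, str]]
    tables: TableBundle
    idmapping: pd.DataFrame
    reviewed: set[str]
    gaf: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)


def _peptide(rng: np.random.Generator) -> tuple[str, str]:
    seq = "".join(rng.choice(_AA, size=10)) + "K"
    site = f"Y{int(rng.integers(2, 300))}"
    return seq, site


def generate_two_dataset_tables(
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    complex_ids: list[str] | None = None,
    pos_proteins: list[str] | None = None,
) -> TableBundle:
    """Generate the SILAC-ratio and phosphopeptide tables with known outcomes.

    The ratio table contains exactly ``n_ratio_hits`` proteins outside the
    10% band (the ids in *complex_ids* first, padded with generated ones);
    the peptide table contains one positive-exclusive peptide per protein
    of *pos_proteins*, plus the configured numbers of negative-exclusive
    peptides, shared peptides (including oxidation-only pairs),
    mixed-direction proteins and ambiguous (multi-protein) peptides.  The
    returned ``expected`` dict records every planted count and id set.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    complex_ids = list(complex_ids or [])
    pos_proteins = list(pos_proteins or [])

    while len(complex_ids) < spec.n_ratio_hits:
        complex_ids.append(f"P5{len(complex_ids):04d}")
    complex_ids = complex_ids[: spec.n_ratio_hits]
    n_null = max(spec.n_ratio_proteins - spec.n_ratio_hits, 0)
    null_ids = [f"P6{i:04d}" for i in range(n_null)]

    ratio_rows = []
    for pid in complex_ids:
        delta = float(rng.uniform(0.12, 0.5))
        up = bool(rng.integers(0, 2))
        ratio_rows.append({"id": pid, "silac_ratio": round(1 + delta if up else 1 / (1 + delta), 4)})
    for pid in null_ids:
        ratio_rows.append({"id": pid, "silac_ratio": round(float(rng.uniform(0.95, 1.05)), 4)})
    ratio_table = pd.DataFrame(ratio_rows, columns=["id", "silac_ratio"])

    if not pos_proteins:
        pos_proteins = [f"P7{i:04d}" for i in range(10)]
    neg_proteins = [f"P8{i:04d}" for i in range(spec.n_neg_exclusive)]
    mixed = pos_proteins[: spec.n_mixed_proteins]

    pep_rows = []
    pos_keys: dict[str, tuple[str, str]] = {}
    for i, pid in enumerate(pos_proteins):
        seq, site = _peptide(rng)
        prots = pid
        if i < spec.n_ambiguous_peptides and len(pos_proteins) > i + 1:
            prots = f"{pid};{pos_proteins[-(i + 1)]}"
        pep_rows.append({"sequence": seq, "phosphosite": site, "oxidation_state": "none",
                         "condition": "pos", "proteins": prots})
        pos_keys[pid] = (seq, site)
    for pid in neg_proteins:
        seq, site = _peptide(rng)
        pep_rows.append({"sequence": seq, "phosphosite": site, "oxidation_state": "none",
                         "condition": "neg", "proteins": pid})
    for pid in mixed:  # a second, neg-exclusive peptide on a pos protein
        seq, site = _peptide(rng)
        pep_rows.append({"sequence": seq, "phosphosite": site, "oxidation_state": "none",
                         "condition": "neg", "proteins": pid})
    shared_plain = spec.n_shared_peptides - spec.n_oxidation_pairs
    for i in range(spec.n_shared_peptides):
        seq, site = _peptide(rng)
        ox = "ox" if i >= shared_plain else "none"
        carrier = pos_proteins[i % len(pos_proteins)]
        pep_rows.append({"sequence": seq, "phosphosite": site, "oxidation_state": "none",
                         "condition": "pos", "proteins": carrier})
        pep_rows.append({"sequence": seq, "phosphosite": site, "oxidation_state": ox,
                         "condition": "neg", "proteins": carrier})
    peptide_table = pd.DataFrame(
        pep_rows, columns=["sequence", "phosphosite", "oxidation_state", "condition", "proteins"]
    )

    substrates = [p for p in pos_proteins if p not in mixed][: spec.n_direct_substrates]
    inv_rows = []
    for pid in substrates:
        seq, site = pos_keys[pid]
        inv_rows.append({"sequence": seq, "phosphosite": site, "proteins": pid})
    seq, site = _peptide(rng)  # in vitro only: must NOT become a substrate
    nonsub = neg_proteins[0] if neg_proteins else "P99999"
    inv_rows.append({"sequence": seq, "phosphosite": site, "proteins": nonsub})
    invitro_table = pd.DataFrame(inv_rows, columns=["sequence", "phosphosite", "proteins"])

    expected = {
        "ratio_hits": sorted(complex_ids),
        "n_ratio_hits": len(complex_ids),
        "pos_proteins": sorted(set(pos_proteins)),
        "neg_proteins": sorted(set(neg_proteins) | set(mixed)),
        "mixed_proteins": sorted(mixed),
        "n_pos_exclusive_peptides": len(pos_proteins),
        "n_neg_exclusive_peptides": spec.n_neg_exclusive + len(mixed),
        "n_shared_excluded": spec.n_shared_peptides,
        "n_oxidation_pairs": spec.n_oxidation_pairs,
        "ambiguous_extra_proteins": sorted(
            {pos_proteins[-(i + 1)] for i in range(min(spec.n_ambiguous_peptides, len(pos_proteins) - 1))}
        ),
        "direct_substrates": sorted(substrates),
        "non_substrate": nonsub,
    }
    return TableBundle(ratio_table, peptide_table, invitro_table, expected)


def _draw_noise(
    rng: np.random.Generator,
    pathway_members: list[list[str]],
    forbidden: set[tuple[str, str]],
    n_edges: int,
) -> list[list[tuple[str, str]]]:
    """Distribute directed noise edges across pathways (within-membership)."""
    per_pw: list[list[tuple[str, str]]] = [[] for _ in pathway_members]
    seen: set[tuple[str, str]] = set(forbidden)
    weights_ = np.array([max(len(m) - 1, 0) for m in pathway_members], dtype=float)
    if weights_.sum() == 0:
        return per_pw
    weights_ /= weights_.sum()
    attempts = 0
    while sum(len(e) for e in per_pw) < n_edges and attempts < n_edges * 50:
        attempts += 1
        pi = int(rng.choice(len(pathway_members), p=weights_))
        members = pathway_members[pi]
        if len(members) < 2:
            continue
        u, v = (members[int(i)] for i in rng.choice(len(members), size=2, replace=False))
        if (u, v) in seen:
            continue
        seen.add((u, v))
        per_pw[pi].append((u, v))
    return per_pw


def _build_pathways(
    bundle_members: list[tuple[str, list[str]]],
    planted_rows: dict[str, list[tuple[str, str, str]]],
    noise_rows: list[list[tuple[str, str]]],
) -> list[Pathway]:
    pathways = []
    for (pid, members), noise in zip(bundle_members, noise_rows):
        interactions = []
        for u, v, rel in planted_rows.get(pid, []):
            itype, sign, _ = DEFAULT_SIF_TYPE_MAP[rel]
            interactions.append((u, v, {itype}, sign))
        for u, v in noise:
            itype, sign, _ = DEFAULT_SIF_TYPE_MAP["controls-state-change-of"]
            interactions.append((u, v, {itype}, sign))
        pathways.append(
            Pathway(id=pid, source_db="synthetic", members=set(members), interactions=interactions)
        )
    return pathways


def _run_pipeline(bundle: "FixtureBundle", epsilon: float, refined: bool):
    """The full analysis chain on an in-memory bundle; returns per-target subnets."""
    tab = bundle.tables
    ratio_ts = curation.select_ratio_targets(tab.ratio_table, 0.10)
    pos, neg, _ = curation.select_exclusive_peptides(tab.peptide_table)
    from .formats import peptide_protein_index

    index = peptide_protein_index(tab.peptide_table)
    site_ts = curation.map_peptides_to_proteins(pos, neg, index)
    inv_index = peptide_protein_index(tab.invitro_table)
    direct_ts = curation.select_direct_substrates(inv_index, pos)
    merged_ts, _ = curation.merge_target_sets([ratio_ts, site_ts, direct_ts])

    targets = merged_ts.ids()
    results = enrichment.enrich_all(targets, bundle.pathways)
    selected = enrichment.select_pathways(results, alpha=0.1)
    rescued = enrichment.rescue_pathways(bundle.pathways, selected, targets, results)
    chosen = [p for p in bundle.pathways if p.id in selected | rescued]

    idmap = build_id_map(bundle.idmapping, reviewed=bundle.reviewed)
    net = assembly.merge_pathways(chosen, idmap, source_id=bundle.source)
    net = assembly.explode_groups(net)
    net = assembly.annotate_evidence(net, merged_ts)
    kin_gaf = bundle.gaf
    obo = _obo_graph()
    net = assembly.annotate_modifiers(net, kin_gaf, obo, ["GO:0004713", "GO:0004725"])

    dist = weights.assign_distances(net)
    if refined:
        scores = walk.score_nodes(net, dist, bundle.source)
        dist = weights.refine_distances(dist, scores.pi, scores.pi0)
    subnets = {}
    for _, _, t in bundle.planted_paths:
        if t in net:
            subnets[t] = pathsearch.near_shortest_subnetwork(net, dist, bundle.source, {t}, epsilon)
        else:
            subnets[t] = None
    return subnets, net


def _certify(bundle: "FixtureBundle") -> bool:
    """Planted paths must be the exact epsilon=0 extraction and keep zero
    overflow after random-walk refinement at epsilon=0.2."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        strict, _ = _run_pipeline(bundle, epsilon=0.0, refined=False)
        for (s, k, t) in bundle.planted_paths:
            sub = strict.get(t)
            if sub is None or sub.edges != {(s, k), (k, t)}:
                return False
        loose, _ = _run_pipeline(bundle, epsilon=0.2, refined=True)
        for (s, k, t) in bundle.planted_paths:
            sub = loose.get(t)
            if sub is None:
                return False
            for e in ((s, k), (k, t)):
                if sub.edge_overflow.get(e, 1.0) > 1e-9:
                    return False
    return True


def _obo_graph():
    import io

    import obonet

    return obonet.read_obo(io.StringIO(_obo_text()))


def _obo_text() -> str:
    lines = ["format-version: 1.2", "ontology: go", ""]
    for tid, name in _CATEGORY_ROOTS.items():
        lines += ["[Term]", f"id: {tid}", f"name: {name}", ""]
    lines += ["[Term]", f"id: {SYNTH_ADHESION_CHILD}",
              "name: synthetic child term of cell adhesion", "is_a: GO:0007155 ! cell adhesion", ""]
    lines += ["[Term]", f"id: {SYNTH_KINASE_CHILD}",
              "name: synthetic child term of tyrosine kinase activity",
              "is_a: GO:0004713 ! protein tyrosine kinase activity", ""]
    return "\n".join(lines)


def generate_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate (and optionally write) a certified synthetic input bundle."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    proteins = [f"P{10000 + i}" for i in range(spec.n_proteins)]
    source = proteins[0]
    planted_paths = []
    kinases, planted_targets = [], []
    for k in range(spec.n_planted_paths):
        kin, tgt = proteins[1 + 2 * k], proteins[2 + 2 * k]
        planted_paths.append((source, kin, tgt))
        kinases.append(kin)
        planted_targets.append(tgt)
    planted_edges = {(s, k) for s, k, _ in planted_paths} | {(k, t) for _, k, t in planted_paths}

    reserved = {source, *kinases, *planted_targets}
    pool = [p for p in proteins if p not in reserved]
    n_targets = max(int(round(spec.target_fraction * spec.n_proteins)), len(planted_targets))
    extra_targets = sorted(
        rng.choice(pool, size=min(n_targets - len(planted_targets), len(pool)), replace=False).tolist()
    )
    site_targets = planted_targets + extra_targets
    complex_ids = [source] + sorted(
        rng.choice([p for p in pool if p not in extra_targets],
                   size=min(spec.n_ratio_hits - 1, 5), replace=False).tolist()
    )

    tables = generate_two_dataset_tables(
        spec, rng, complex_ids=complex_ids, pos_proteins=site_targets
    )

    # pathway memberships: one pathway per planted path holding most extra
    # targets, the rest noise pathways with one target each
    lo, hi = spec.pathway_size_range
    members_list: list[tuple[str, list[str]]] = []
    planted_rows: dict[str, list[tuple[str, str, str]]] = {}
    n_extra_in_planted = min(len(extra_targets), max(hi - 5, 0))
    for i, (s, k, t) in enumerate(planted_paths):
        pid = f"planted_{i:02d}"
        share = extra_targets[i::spec.n_planted_paths][: n_extra_in_planted // spec.n_planted_paths + 1]
        fillers = [p for p in pool if p not in extra_targets][2 * i: 2 * i + 2]
        members = sorted({s, k, t, *share, *fillers})
        members_list.append((pid, members))
        planted_rows[pid] = [(s, k, "controls-state-change-of"), (k, t, "phosphorylates")]

    n_noise_pw = max(spec.n_pathways - spec.n_planted_paths - int(spec.include_group_pathway), 0)
    unplaced = [p for p in pool if p not in extra_targets]
    for j in range(n_noise_pw):
        pid = f"noise_{j:02d}"
        size = int(rng.integers(lo, hi + 1))
        base = rng.choice(unplaced, size=min(size - 1, len(unplaced)), replace=False).tolist()
        anchor = extra_targets[j % len(extra_targets)] if extra_targets else proteins[-1]
        members_list.append((pid, sorted(set(base) | {anchor})))

    group_members: list[str] = []
    if spec.include_group_pathway:
        pid = "group_00"
        cands = [p for p in unplaced if p != source][-4:]
        group_members = cands[:2]
        members = sorted(set(cands))
        members_list.append((pid, members))
        planted_rows[pid] = []

    forbidden = set(planted_edges) | {(v, u) for u, v in planted_edges}
    attempt = 0
    while True:
        attempt += 1
        noise_rows = _draw_noise(rng, [m for _, m in members_list], forbidden, spec.noise_edges)
        pathways = _build_pathways(members_list, planted_rows, noise_rows)
        if spec.include_group_pathway and group_members:
            gp = next(p for p in pathways if p.id == "group_00")
            gp.groups = {"g1": list(group_members)}
            others = [m for m in gp.members if m not in group_members]
            if others:
                gp.interactions.append((others[0], "g1", {"regulation"}, "positive"))

        gaf_rows = [
            {"db_object_id": k, "go_id": "GO:0004713", "evidence": "IDA", "aspect": "F"}
            for k in kinases
        ] + [
            {"db_object_id": t, "go_id": SYNTH_ADHESION_CHILD, "evidence": "IDA", "aspect": "P"}
            for t in planted_targets
        ]
        gaf = pd.DataFrame(gaf_rows, columns=["db_object_id", "go_id", "evidence", "aspect"])

        idmap_rows = []
        for i, p in enumerate(proteins):
            idmap_rows.append({"uniprot_id": p, "namespace": "KEGG", "foreign_id": f"hsa:{1000 + i}"})
            idmap_rows.append({"uniprot_id": p, "namespace": "HGNC", "foreign_id": f"GENE{i}"})
        # two unreviewed accessions sharing a KEGG id, to exercise grouping
        idmap_rows.append({"uniprot_id": "Q90000", "namespace": "KEGG", "foreign_id": "hsa:1001"})
        idmap_rows.append({"uniprot_id": "Q90001", "namespace": "KEGG", "foreign_id": "hsa:1002"})
        idmapping = pd.DataFrame(idmap_rows, columns=["uniprot_id", "namespace", "foreign_id"])
        reviewed = set(proteins)

        bundle = FixtureBundle(
            spec=spec, proteins=proteins, source=source, planted_paths=planted_paths,
            planted_edges=planted_edges, site_targets=site_targets,
            complex_targets=complex_ids, kinases=kinases, pathways=pathways,
            planted_pathway_ids=[pid for pid in planted_rows if pid.startswith("planted")],
            noise_edge_list=[e for rows in noise_rows for e in rows],
            tables=tables, idmapping=idmapping, reviewed=reviewed, gaf=gaf,
        )
        if _certify(bundle):
            break
        if attempt >= spec.max_resample:
            raise RuntimeError(
                f"could not certify planted ground truth after {spec.max_resample} noise resamples"
            )

    if outdir is not None:
        bundle.files = _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: FixtureBundle, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pathways").mkdir(exist_ok=True)
    files: dict[str, Path] = {}

    inv_type_map = {}
    for rel, (itype, sign, _) in DEFAULT_SIF_TYPE_MAP.items():
        inv_type_map.setdefault((itype, sign), rel)
    for pw in bundle.pathways:
        if pw.groups:  # the group pathway goes out as KGML
            path = outdir / "pathways" / f"{pw.id}.kgml"
            path.write_text(_kgml_text(pw))
            files[f"pathway:{pw.id}"] = path
            continue
        lines = ["PARTICIPANT_A\tINTERACTION_TYPE\tPARTICIPANT_B"]
        for u, v, types, sign in pw.interactions:
            rel = inv_type_map.get((sorted(types)[0], sign), "interacts-with")
            lines.append(f"{u}\t{rel}\t{v}")
        path = outdir / "pathways" / f"{pw.id}.sif"
        path.write_text("\n".join(lines) + "\n")
        files[f"pathway:{pw.id}"] = path

    gmt_lines = [
        "\t".join([pw.id, "synthetic"] + sorted(pw.members)) for pw in bundle.pathways
    ]
    files["gmt"] = outdir / "genesets.gmt"
    files["gmt"].write_text("\n".join(gmt_lines) + "\n")

    files["obo"] = outdir / "ontology.obo"
    files["obo"].write_text(_obo_text())

    gaf_lines = ["!gaf-version: 2.1"]
    for rec in bundle.gaf.itertuples(index=False):
        fields = ["SYN", rec.db_object_id, rec.db_object_id, "", rec.go_id, "SYN:0001",
                  rec.evidence, "", rec.aspect, "", "", "protein", "taxon:9606",
                  "20240101", "SYN", "", ""]
        gaf_lines.append("\t".join(fields))
    files["gaf"] = outdir / "annotations.gaf"
    files["gaf"].write_text("\n".join(gaf_lines) + "\n")

    files["idmapping"] = outdir / "idmapping.tsv"
    bundle.idmapping.to_csv(files["idmapping"], sep="\t", index=False, header=False)
    files["reviewed"] = outdir / "reviewed.txt"
    files["reviewed"].write_text("\n".join(sorted(bundle.reviewed)) + "\n")

    files["ratio_table"] = outdir / "mcf7_ratios.tsv"
    bundle.tables.ratio_table.to_csv(files["ratio_table"], sep="\t", index=False)
    files["peptide_table"] = outdir / "mda231_peptides.tsv"
    bundle.tables.peptide_table.to_csv(files["peptide_table"], sep="\t", index=False)
    files["invitro_table"] = outdir / "invitro_peptides.tsv"
    bundle.tables.invitro_table.to_csv(files["invitro_table"], sep="\t", index=False)
    return files


def _kgml_text(pw: Pathway) -> str:
    ids = {m: str(i + 1) for i, m in enumerate(sorted(pw.members))}
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:{pw.id}" org="syn" number="1" title="{pw.id}">',
    ]
    for m, eid in ids.items():
        lines.append(f'  <entry id="{eid}" name="{m}" type="protein"/>')
    next_id = len(ids) + 1
    group_ids = {}
    for gid, members in pw.groups.items():
        comp = "".join(f'<component id="{ids[m]}"/>' for m in members)
        lines.append(f'  <entry id="{next_id}" type="group">{comp}</entry>')
        group_ids[gid] = str(next_id)
        next_id += 1
    for u, v, types, sign in pw.interactions:
        e1 = group_ids.get(u, ids.get(u))
        e2 = group_ids.get(v, ids.get(v))
        if e1 is None or e2 is None:
            continue
        subtype = "activation" if sign == "positive" else ("inhibition" if sign == "negative" else "binding/association")
        lines.append(
            f'  <relation entry1="{e1}" entry2="{e2}" type="PPrel"><subtype name="{subtype}" value="--"/></relation>'
        )
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"
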