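# signet

Signaling-network reconstruction and signal-propagation analysis from
(phospho-)proteomic target lists.

Quantitative phosphoproteomics yields lists of proteins whose
phosphorylation or complex membership responds to perturbing a kinase —
but not the mechanisms connecting the kinase to those targets.  `signet`
rebuilds the candidate mechanisms from prior knowledge: starting from the
curated target lists it identifies over-represented pathways, merges them
into one annotated directed interaction network, and extracts the
near-shortest paths from the kinase to its targets, weighting edges by
biological plausibility and refining them with a random-walk
"reachability" score.  The reference use case is the spleen tyrosine
kinase Syk (Uniprot P43405) in breast cancer cell lines; the machinery is
generic over sources, species and pathway databases.  It is written for
computational biologists who have target tables and KGML / extended-SIF /
GMT pathway files and want ranked, inspectable mechanism hypotheses they
can open in Cytoscape.

## Method

1. **Curation.** Complex-level targets: SILAC ratio |r − 1| ≥ 0.10.
   Site-level targets: phosphopeptides observed in exactly one condition
   (pairs differing only by Met oxidation count as shared and are
   excluded); ambiguous peptides contribute all matching proteins.
   Direct substrates: in-vitro-phosphorylated peptides retrieved in the
   positive cellular condition, with configurable include/exclude lists.
2. **Enrichment.** Per pathway a Fisher exact test on the 2×2 table
   (pathway membership × target status); under-represented pathways are
   removed, over-represented ones kept at raw p < 0.1, and pathways
   containing otherwise-uncovered targets are rescued.
3. **Assembly.** Selected pathways merge into a directed network with
   provenance; interaction types union and signs join (+ and − conflict
   to *unclear*); GO term groups attach process categories and the
   phospho-tyrosine-modifier flag (GO:0004713/GO:0004725); paralog group
   nodes are exploded to protein-level edges.
4. **Edge distances.** d = 5 for unannotated edges; d = 3 out of an
   identified protein; d = 2 from a tyrosine kinase/phosphatase into an
   identified protein; d = 1 when both hold; d = 8 into a differentially
   phosphorylated target from a source that is neither identified nor a
   modifier, d = 6 if that source is identified.
5. **Random walk.** Transition probabilities
   p<sub>ij</sub> = (1 − p₀)·d<sub>ij</sub>⁻¹ / Σ<sub>k</sub> d<sub>ik</sub>⁻¹
   with return probability p₀ to the source; stationary scores π (πP = π)
   against the equal-weight baseline π⁰ refine the distances as
   d̃<sub>ij</sub> = d<sub>ij</sub>·π⁰<sub>i</sub>/π<sub>i</sub>.
6. **Extraction.** All nodes and edges on at least one source→target path
   of length ≤ (1 + ε)·shortest (ε = 0.2 by default), each annotated with
   its *overflow* — the extra distance of the best acceptable path using
   it; 0 marks strict shortest-path elements.

Details, defaults and design decisions are in `docs/methods.md`.

## Worked example

`examples/` holds one narrative script per capability.  The third one
runs the whole chain on a generated bundle with a planted
source→kinase→target path:

```sh
$ python examples/03_extract_paths.py
planted path: P10000 -> P10001 (tyrosine kinase) -> P10002

scheme distances on the planted edges: P10000->P10001: 3, P10001->P10002: 2
walk score ratio pi/pi0 of the kinase: 1.05 (>1: visited more than topology alone predicts)

subnetwork at epsilon=0.2 (refined weights): 3 nodes, 2 edges
  P10000 -> P10001   overflow 0.00
  P10001 -> P10002   overflow 0.00
```

The distances show the scheme at work (3: edge out of an identified
protein; 2: kinase into an identified target); the ratio π/π⁰ > 1 marks
the kinase as visited more than topology alone predicts, so refinement
promotes its outgoing edges; overflow 0.00 means both planted edges lie
on a strict shortest path — the planted mechanism is recovered exactly.

The same workflow is available from the shell:

```sh
signet simulate --seed 7 --out fixture/
signet targets --ratios fixture/mcf7_ratios.tsv --peptides fixture/mda231_peptides.tsv \
       --invitro fixture/invitro_peptides.tsv --out run/targets
signet build --pathways fixture/pathways --gmt fixture/genesets.gmt \
       --targets-dir run/targets --idmapping fixture/idmapping.tsv \
       --reviewed fixture/reviewed.txt --gaf fixture/annotations.gaf \
       --obo fixture/ontology.obo --source P10000 --out run/net
signet walk --network run/net/network.graphml --out run/scores.tsv
signet extract --network run/net/network.graphml --targets adhesion-motility \
       --epsilon 0.2 --weights refined --out run/adhesion
```

Outputs are GraphML (opens in Cytoscape 3), SIF with node/edge attribute
tables, JSON for web viewers, and TSV reports; every command writes a
run manifest with configuration hash and input checksums.

## Input formats

* ratio table: TSV with columns `id` (Uniprot accession), `silac_ratio`.
* peptide table: TSV with `sequence`, `phosphosite` (e.g. `Y424`),
  `oxidation_state`, `condition` (`pos`/`neg`), `proteins`
  (`;`-separated accessions).
* pathways: KGML files and/or extended-SIF; GMT for membership;
  Uniprot 3-column id-mapping TSV plus a reviewed-accession list;
  go-basic OBO and GAF for annotation.

The reference supplementary tables are distributed as ODS spreadsheets;
export the relevant sheets to TSV with the columns above (any spreadsheet
tool or `libreoffice --convert-to` works) and place them under
`data/reference/` as
`mcf7_ratios.tsv` / `mda231_peptides.tsv` to enable the reference-count
test; the package itself has no spreadsheet dependency.

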