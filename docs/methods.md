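# Methods

`signet` reconstructs a prior-knowledge signaling network around a source
protein (the reference use is the spleen tyrosine kinase Syk, Uniprot
P43405, in breast cancer cell lines) from lists of experimentally
identified targets, and extracts candidate signal-propagation mechanisms
by weighted near-shortest-path analysis refined with a random walk.  This
note records the model, its assumptions, the tunables and their defaults,
and the design decisions taken where the procedure was genuinely open.

## Target curation

Three evidence classes are curated and kept distinct, because the edge
weighting treats them differently:

* **complex-level** (MCF7-type evidence): proteins whose SILAC ratio
  between control and perturbed conditions satisfies |r − 1| ≥ 0.10.  The
  10% bound is inclusive — the threshold names the accepted variation —
  and is applied to the raw ratio, not its logarithm.  A guard of 1e-12
  absorbs the binary representation of printed ratios (0.90 is stored as
  0.0999…); without it a boundary ratio on the low side would be dropped.
  Direction is `up` for r > 1, `down` for r < 1.
* **site-level** (MDA231-type evidence): proteins carrying a
  phospho-peptide observed in exactly one experimental condition.  The
  peptide identity is (sequence, phosphosite); the methionine-oxidation
  state is deliberately excluded from the key, so observation pairs
  differing only by Met oxidation collapse onto one shared peptide and are
  excluded.  Sequence-ambiguous peptides contribute *all* matching
  proteins.  Proteins with exclusive peptides in both conditions are
  retained with direction `mixed`.
* **direct-substrate**: proteins with an in-vitro-phosphorylated peptide
  that is also found in the positive-exclusive cellular set.  The
  hand-curated corrections (six protein-level exclusions, one
  peptide-level exclusion, two forced inclusions) ship as configuration
  (`direct_substrate_excludes` / `_includes` in the default profile), so
  the mechanism is generic and the list editable.

## Identifier canonicalization

Proteins are keyed by Uniprot accession without the isoform suffix
(trailing `-<digits>` stripped only when the stem is Uniprot-shaped).
Accessions sharing a KEGG or HGNC identifier form one canonical class;
classes overlapping through different namespaces are union-merged (the
merge rule for disagreeing namespaces is not prescribed anywhere, so the
most conservative choice — union — is used).  The representative prefers
a reviewed entry, ties broken lexicographically, making unreviewed
accessions resolve to the associated reviewed entry.  Unknown identifiers
are kept, stripped and flagged, rather than dropped, so coverage
statistics stay honest.

## Pathway enrichment and selection

Each pathway containing at least one target is tested with a two-sided
Fisher exact test on the 2×2 table (in/out of pathway × target/non-target)
over a background set defaulting to the union of the database's pathway
members (the true background of the reference analysis is not recoverable;
a user-supplied background is supported).  Under-represented pathways
(k/m < n/N) are removed regardless of p; over-represented ones are kept at
raw p < α with α = 0.1.  No multiplicity correction is applied at
selection — the α is a deliberately permissive completeness filter, and a
Benjamini–Hochberg column is reported for transparency only.  A rescue
step then adds, per target not covered by the selection, the containing
pathway with the smallest p (ties: smallest pathway, then id;
`all-containing` is available as a policy), so that after selection ∪
rescue every target the database can cover is covered.

## Network assembly and annotation

Selected pathways merge into one directed graph: one node per canonical
id, one edge per ordered pair.  Interaction types
(phosphorylation / modification / regulation / other) union; signs join on
the lattice where `unknown` is neutral and {positive, negative} → unclear.
Nodes and edges retain their pathway provenance.  KGML relation subtypes
and extended-SIF relation names map to (type, sign) through shipped,
editable tables.

KEGG-style group constructs (interchangeable paralogs) are preserved as
marked group nodes with bidirectional member links so the merged network
remains exportable, and are exploded before any path search: each real
edge incident to a group is replaced by edges to/from every member,
inheriting type, sign and provenance; nested groups expand innermost
first, an enclosing group inheriting the members of an expanded inner one.

GO annotation attaches process categories (adhesion-motility,
growth-death, immunity-inflammation, differentiation — each a configured
group of GO terms) and the phospho-tyrosine-modifier flag (tyrosine kinase
GO:0004713 / phosphatase GO:0004725).  Term closure walks `is_a` edges of
the go-basic ontology only, with `part_of` available through
configuration; annotation evidence codes are unfiltered by default
(filtering, e.g. of IEA, is a reader option).  Manual allow/deny lists
override the GO-derived modifier flags.

## Edge distances

Distances encode the plausibility of an edge as a signal step
(lower = more plausible).  With S_id = source carries any dataset
evidence, S_mod = source is a phospho-tyrosine modifier, T_id = target
carries any dataset evidence, T_dp = target has site-level
(differentially phosphorylated) evidence, the first matching rule wins:

| d | condition |
|---|-----------|
| 1 | S_id ∧ S_mod ∧ T_id |
| 2 | S_mod ∧ T_id |
| 8 | T_dp ∧ ¬S_mod ∧ ¬S_id |
| 6 | T_dp ∧ ¬S_mod ∧ S_id |
| 3 | S_id |
| 5 | otherwise |

The promotion branch precedes the demotion branch because a
differentially phosphorylated target is demoted only when the edge does
*not* come from a tyrosine kinase or phosphatase.  "Identified" (T_id)
means evidence of any class; "differentially phosphorylated" (T_dp) means
site-level or direct-substrate evidence; the mapping is configurable.  The
six levels live in the default profile and are editable.

## Random walk and distance refinement

On the source-reachable component (required for the ergodicity argument;
whether the original analysis used the full network is unstated), a
walker at node *i* moves to successor *j* with probability
p_ij = (1 − p0)·d_ij⁻¹ / Σ_k d_ik⁻¹ and returns to the source with
probability p0; terminal nodes return with probability 1.  The return
entries are implemented as explicit edges back to the source node (not an
extra absorbing state), so the stationary equation πP = π runs over the
original node set.  The chain is finite, irreducible and aperiodic for
0 < p0 < 1, so π exists, is unique and strictly positive.

π is computed by power iteration (tolerance 1e-10 on the L1 change, cap
100 000 iterations; since P is L1-non-expansive the returned iterate's
stationarity residual satisfies the same bound).  The distribution is
computed algebraically — a seeded trajectory sampler exists only as a
cross-validation aid in the tests.  A second, equal-weight run gives the
topology-only baseline π⁰, and distances refine as

    d̃_ij = d_ij · π⁰_i / π_i ,

demoting edges out of nodes visited less than topology alone predicts and
promoting over-visited ones.  The default return probability is p0 = 0.15;
no reference value is printed anywhere, so walk-dependent results are
treated as rankings, not numbers to reproduce.  Nodes without a
stationary score (outside the component) get their outgoing distances
scaled by the largest observed π⁰/π ratio — maximally demoted but finite,
keeping the graph searchable, since the formula is undefined at π_i = 0.
When all base distances are equal the two chains coincide and refinement
is exactly neutral.

## Near-shortest-path extraction

A path to target *t* is acceptable when its total distance is at most
(1 + ε)·shortest(t); ε = 0.2 by default ("up to 20% longer"), relative per
target, with an absolute-slack mode available.  The extracted subnetwork
is the union over targets of every node and edge on at least one
acceptable path; each element is annotated with its *overflow* — the
extra distance of the best acceptable path using it — zero for elements
of a strict shortest path.  The composite subnetwork can contain paths
longer than acceptable (two individually acceptable detours may combine);
this is a property of taking unions, not an error.  With several targets
the stored overflow is the global minimum; per-target values go to the
path report.

Implementation: one forward Dijkstra from the source and one reverse
Dijkstra per target (restricted to the source-reachable component) give
admissible bounds; acceptable simple paths are then enumerated by
depth-first branch-and-bound pruned with cost + dbwd_t(v) > budget.  The
cheaper alternative — retaining edge (u,v) whenever
dfwd(u) + d(u,v) + dbwd_t(v) ≤ budget, which is what backtracking from the
targets computes — was measured to over-include on cyclic graphs (≈7% of
random ≤10-node digraphs at ε = 0.5 gain elements reachable only by
node-revisiting walks, including edges into the source).  Enumeration
keeps membership and overflows exact on any digraph at the cost of
worst-case exponential time; with ε ≤ 0.2 on sparse signaling networks the
budget prunes the search to a small frontier.  Ties keep all co-optimal
predecessors; node overflow is the minimum over the paths through the
node, which equals the minimum over its retained incident edges.

## Synthetic data generator

The generator emulates every input the pipeline consumes — extended-SIF
and KGML pathway files (one KGML carries a group construct), a GMT
membership file, GAF/OBO annotation with an ontology stub containing the
configured term groups plus synthetic child terms (ids GO:00999xx, marked
synthetic — they do not exist in the real GO), a Uniprot-style id-mapping
table with planted unreviewed duplicates, and the two curation tables
with exact planted counts (ratio hits, exclusive/shared/oxidation-pair
peptides, mixed-direction proteins, ambiguous peptides, direct
substrates).

Each planted path source→kinase→target is embedded in a pathway whose
membership is target-rich (so enrichment selects it); the kinase carries
GO:0004713, the target site-level evidence, the source complex-level
evidence, making the planted distances 3 + 2 = 5 against noise routes of
≥ 6.  Noise edges are Erdős–Rényi draws within pathway memberships.  The
generator certifies its own ground truth: it runs the complete pipeline
and redraws the noise until (a) extraction at ε = 0 with scheme weights
returns exactly the planted edges and (b) after random-walk refinement at
ε = 0.2 the planted edges keep zero overflow.  Defaults — 60 proteins, 6
pathways of 8–15 members, 80 noise edges, 25% target fraction — are
chosen once as a realistically sparse, desk-scale miniature of a pathway
compendium; they are deliberately small enough that certified bundles
generate in well under a second.

What passing on fixtures does **not** show: real pathway databases are
larger, scale-free rather than Erdős–Rényi, with heavy membership overlap
and identifier noise; real phosphoproteomics carries localization
ambiguity and missingness the tables do not model.  The fixtures validate
the machinery and its contracts, not database-release-specific statistics
(network size, coverage counts), which depend on the specific KEGG /
Pathway Commons releases and are out of scope.

## Numerical choices and degenerate inputs

Fisher p-values come from `scipy.stats.fisher_exact` (two-sided, with a
one-sided `greater` mode as configuration); the tests pin them to an
exact rational enumeration oracle to 1e-12 for every margin with N ≤ 40.
Path acceptability uses a relative slack of 1e-9 so float summation never
drops a tied shortest path; distances must be strictly positive.  Empty
curation tables, unreachable targets and empty enrichment results yield
empty outputs with warnings, not errors; empty groups, missing sources,
p0 outside (0,1) and inconsistent walk runs raise.  All randomness flows
through `numpy.random.default_rng` seeds; fixed seeds give byte-identical
fixture files and deterministic CLI outputs.

## Known limitations

* Exact near-shortest enumeration is exponential in the worst case; very
  dense graphs with large ε may be slow (the bounds still prune, but no
  cap is imposed).
* The background set of the reference enrichment analysis is not
  recoverable; both supported choices are approximations.
* BioPAX semantics beyond extended-SIF, complex stoichiometry and
  PTM-site-level graphs are out of scope, as are GSEA-style ranked
  enrichment, Steiner-tree extraction and k-shortest-path enumeration.
* The walk's return probability is a free parameter; rankings are stable
  over a broad range but absolute π values are not comparable across
  networks.
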