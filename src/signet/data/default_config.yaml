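# Default analysis profile: every tunable of the pipeline in one place.
# Values here are the reference settings of the method; override any of
# them with a user config file or CLI flags.

alpha: 0.1            # pathway selection p-value cutoff (strict <, raw p)
epsilon: 0.2          # allowed overflow fraction for near-shortest paths
p0: 0.15              # random-walk return probability to the source node
tol: 1.0e-10          # stationary-distribution convergence tolerance (L1)
max_iter: 100000      # power-iteration cap
silac_threshold: 0.10 # minimum |ratio - 1| for complex-level targets
rescue_policy: best-p         # best-p | all-containing
fisher_alternative: two-sided # two-sided | greater
go_relations: [is_a]          # ontology closure relations (add part_of if wanted)

source_id: P43405     # spleen tyrosine kinase Syk, the reference signal origin

# six-level edge distance scheme
scheme:
  promoted_both: 1
  modifier_to_identified: 2
  demoted_plain: 8
  demoted_identified: 6
  identified_source: 3
  normal: 5

# process categories: groups of GO terms; a node gets the category when
# annotated to any listed term or a descendant
term_groups:
  adhesion-motility: [GO:0048870, GO:0007155, GO:0034330, GO:0022610, GO:0060352, GO:0030030]
  growth-death: [GO:0008283, GO:0007049, GO:0008219, GO:0019835, GO:0000920, GO:0007569, GO:0051301, GO:0060242]
  immunity-inflammation: [GO:0002376, GO:0001906]
  differentiation: [GO:0030154, GO:0036166]

# phospho-tyrosine modifiers: tyrosine kinase / phosphatase activity terms,
# with manual overrides applied after the GO-derived flags
modifier_terms: [GO:0004713, GO:0004725]
modifier_allow: []
modifier_deny: []

# hand-curated direct-substrate corrections: proteins whose in-vitro
# peptides were not retrieved exclusively in the positive cellular
# condition, one peptide-specific exclusion, and two forced inclusions
# supported by a shared exclusively-retrieved peptide
direct_substrate_excludes:
  - {protein: Q14192}                 # four-and-a-half LIM domains 2
  - {protein: Q06124}                 # PTPN11
  - {protein: P18031}                 # PTPN1
  - {protein: Q14247}                 # cortactin
  - {protein: P08670}                 # vimentin
  - {protein: Q05209}                 # PTPN12
  - {protein: P46821, sequence: ITSFPESEGYSyETSTK}  # one MAP1B peptide only
direct_substrate_includes: [P23528, Q9Y281]  # cofilin-1, cofilin-2

# KGML relation subtype -> [interaction type, sign]
kgml_type_map:
  phosphorylation: [phosphorylation, unknown]
  dephosphorylation: [phosphorylation, negative]
  activation: [regulation, positive]
  inhibition: [regulation, negative]
  expression: [regulation, positive]
  repression: [regulation, negative]
  ubiquitination: [modification, unknown]
  glycosylation: [modification, unknown]
  methylation: [modification, unknown]
  binding/association: [other, unknown]
  indirect effect: [other, unknown]
  compound: [other, unknown]

# extended-SIF relation -> [interaction type, sign, directed]
sif_type_map:
  controls-phosphorylation-of: [phosphorylation, unknown, true]
  controls-dephosphorylation-of: [phosphorylation, negative, true]
  controls-state-change-of: [modification, unknown, true]
  controls-expression-of: [regulation, unknown, true]
  controls-transport-of: [modification, unknown, true]
  catalysis-precedes: [other, unknown, true]
  in-complex-with: [other, unknown, false]
  interacts-with: [other, unknown, false]
  activates: [regulation, positive, true]
  inhibits: [regulation, negative, true]
  phosphorylates: [phosphorylation, unknown, true]
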