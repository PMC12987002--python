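# Structured consensus knowledge base: one entry per developmental stage class.
# Criteria texts paraphrase internationally agreed morphology-assessment
# terminology (Istanbul consensus tradition); no guideline text is reproduced
# verbatim.  forbidden_terms list structures that are biologically impossible
# at the stage and therefore must never appear in a generated report for it.
entries:
  - stage_key: 1cell
    stage_name: single-cell zygote
    consensus_criteria:
      - A normally fertilized zygote shows two pronuclei of similar size, centrally
        apposed, with nucleolar precursor bodies aligned at the pronuclear junction.
      - The second polar body should be extruded and the cytoplasm may show a
        peripheral halo; the zona pellucida should be intact and regular.
    typical_features:
      - pronuclei
      - polar body
      - cytoplasmic halo
      - zona pellucida
    forbidden_terms:
      - blastomere
      - inner cell mass
      - trophectoderm
      - blastocoel
      - compaction
    source_tag: istanbul_consensus
  - stage_key: 2cells
    stage_name: 2-cell cleavage-stage embryo
    consensus_criteria:
      - A good-quality 2-cell embryo shows two evenly sized, stage-appropriate
        blastomeres with less than 10 percent fragmentation.
      - Blastomere symmetry and mononucleation are the primary scoring criteria;
        uneven division or multinucleation lowers the grade.
    typical_features:
      - blastomeres
      - blastomere symmetry
      - fragmentation
      - zona pellucida
    forbidden_terms:
      - inner cell mass
      - trophectoderm
      - blastocoel
      - compaction
      - pronuclei
    source_tag: istanbul_consensus
  - stage_key: 3cells
    stage_name: 3-cell cleavage-stage embryo
    consensus_criteria:
      - The 3-cell configuration is a transient state between the 2-cell and 4-cell
        stages; blastomere size is expected to be uneven because one blastomere has
        divided ahead of the other.
      - Grading follows cleavage-stage criteria, relative blastomere size
        appropriate to the division pattern, and limited fragmentation.
    typical_features:
      - blastomeres
      - asynchronous division
      - fragmentation
      - zona pellucida
    forbidden_terms:
      - inner cell mass
      - trophectoderm
      - blastocoel
      - compaction
      - pronuclei
    source_tag: istanbul_consensus
  - stage_key: 4cells
    stage_name: 4-cell cleavage-stage embryo
    consensus_criteria:
      - A top-quality 4-cell embryo on Day 2 shows four evenly sized mononucleated
        blastomeres with less than 10 percent fragmentation.
      - Blastomere symmetry, absence of multinucleation and a regular zona
        pellucida align with consensus criteria for Day 2 assessment.
    typical_features:
      - blastomeres
      - blastomere symmetry
      - fragmentation
      - zona pellucida
    forbidden_terms:
      - inner cell mass
      - trophectoderm
      - blastocoel
      - compaction
      - pronuclei
    source_tag: istanbul_consensus
  - stage_key: more
    stage_name: advanced-stage embryo (morula or blastocyst)
    consensus_criteria:
      - From Day 4 the embryo compacts into a morula; by Day 5 a blastocyst forms
        with a blastocoel cavity, an inner cell mass and a trophectoderm layer.
      - Blastocyst grading scores the degree of expansion, the cohesion of the
        inner cell mass and the uniformity of the trophectoderm epithelium.
    typical_features:
      - compaction
      - blastocoel
      - inner cell mass
      - trophectoderm
      - expansion
    forbidden_terms:
      - pronuclei
      - polar body
    source_tag: istanbul_consensus
  - stage_key: empty
    stage_name: empty well
    consensus_criteria:
      - No embryo is visible in the well; only culture medium and well structure are
        present.
      - An empty-well image carries no gradable morphology and is excluded from
        embryo scoring.
    typical_features:
      - culture medium
      - well surface
    forbidden_terms:
      - blastomere
      - pronuclei
      - inner cell mass
      - trophectoderm
      - zona pellucida
    source_tag: laboratory_protocol
  - stage_key: not_defined
    stage_name: undefined or artifact image
    consensus_criteria:
      - The image cannot be assigned a developmental stage; debris, optical
        artifacts or ambiguous morphology prevent grading.
      - Undefined images are flagged for manual review rather than scored.
    typical_features:
      - debris
      - optical artifact
      - ambiguous morphology
    forbidden_terms:
      - inner cell mass
      - trophectoderm
      - pronuclei
    source_tag: laboratory_protocol
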