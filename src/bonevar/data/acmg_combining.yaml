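# Evidence-combination matrix for sequence-variant interpretation
# (the published ACMG/AMP 2015 combining rules, shipped as editable data so
# ClinGen refinements can be swapped in without code changes).
#
# Each rule lists MINIMUM counts of pathogenic-evidence strengths
# (very_strong / strong / moderate / supporting) or benign-evidence strengths
# (stand_alone / strong / supporting). A profile satisfies a rule when every
# listed count is met. Pathogenic rules are checked before likely-pathogenic,
# benign before likely-benign; if both a pathogenic-arm and a benign-arm rule
# fire, the verdict is uncertain_significance (conflicting evidence).
pathogenic:
  - {very_strong: 1, strong: 1}
  - {very_strong: 1, moderate: 2}
  - {very_strong: 1, moderate: 1, supporting: 1}
  - {very_strong: 1, supporting: 2}
  - {strong: 2}
  - {strong: 1, moderate: 3}
  - {strong: 1, moderate: 2, supporting: 2}
  - {strong: 1, moderate: 1, supporting: 4}
likely_pathogenic:
  - {very_strong: 1, moderate: 1}
  - {strong: 1, moderate: 1}
  - {strong: 1, supporting: 2}
  - {moderate: 3}
  - {moderate: 2, supporting: 2}
  - {moderate: 1, supporting: 4}
benign:
  - {stand_alone: 1}
  - {strong: 2}
likely_benign:
  - {strong: 1, supporting: 1}
  - {supporting: 2}
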