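# Dutch Lipid Clinic Network point table (standard values).
# Within each group only the highest-scoring satisfied condition counts.
family_history:
  premature_ascvd_relative: 1   # first-degree relative with premature ASCVD
  relative_ldl_gt95: 1          # first-degree relative with LDL-C >95th percentile
  relative_xanthomata_arcus: 2  # relative with tendon xanthomata and/or arcus cornealis
  child_ldl_gt95: 2             # child <18 y with LDL-C >95th percentile
personal_history:
  premature_chd: 2
  premature_cerebral_or_peripheral: 1
physical_exam:
  tendon_xanthomata: 6
  arcus_before_45: 4
ldl_bands:              # untreated LDL-C, mg/dl; bands by inclusive lower bound
  - {ldl_min: 330.0, points: 8}
  - {ldl_min: 250.0, points: 5}
  - {ldl_min: 190.0, points: 3}
  - {ldl_min: 155.0, points: 1}
dna:
  causative_variant: 8
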