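# Default synthetic-cohort generator configuration.
#
# The generator simulates a hypercholesterolemia-enriched screening
# population; applying the selection funnel (observed LDL-C >= 155 mg/dl,
# ages 18-70, no secondary cause in window) yields a cohort calibrated to the
# study conditions: LDL-C ~187 +/- 32 mg/dl, ~1.5% P/LP carriers with a
# markedly higher LDL-C, ~16% with PGS >= 1.16, ~4% on statins, and a genetic
# contribution of 7% of the population LDL-C variance.  See docs/methods.md
# for how each number was derived.
n_population: 20000
seed: 42
age: {mean: 50.0, sd: 12.0, min: 20.0, max: 80.0}
male_fraction: 0.413
white_fraction: 0.972
bmi: {mean: 29.5, sd: 7.7, min: 15.0, max: 60.0}

plp_carrier_rate: 0.005          # population rate; selection enriches to ~1.5%
monogenic_shift_mean: 85.0       # mg/dl, population scale (attenuates under truncation)
monogenic_shift_sd: 15.0
ldl_baseline: {intercept: 112.0, age_slope: 0.25, age_center: 50.0, male_offset: -6.0}
pgs_to_ldl_scale: 38.67          # mg/dl per score unit (1 mmol/l = 38.67 mg/dl)
residual_sd: 37.5                # mg/dl; solved so genetic factors explain 7% of variance
residual_log_skew: 0.40          # lognormal shape of the standardized residual
pgs_threshold: 1.16              # used only for truth labels (polygenic tail)

statin:
  rate_high_ldl: 0.60            # treatment probability when untreated LDL >= threshold
  high_ldl_threshold: 230.0
  rate_low_ldl: 0.012
  mix:
    - {type: atorvastatin, dose: 40, share: 0.30}
    - {type: atorvastatin, dose: 20, share: 0.20}
    - {type: simvastatin, dose: 40, share: 0.20}
    - {type: rosuvastatin, dose: 10, share: 0.15}
    - {type: pravastatin, dose: 40, share: 0.10}
    - {type: simvastatin, dose: 20, share: 0.05}

secondary_causes:
  hypothyroidism: 0.04
  cholestatic_liver_disease: 0.005
  severe_kidney_disease: 0.01
  nephrotic_syndrome: 0.002
  pregnancy: 0.015               # applied to females only

personal_ascvd_rate: 0.19        # probability of a personal ASCVD event record
family_history:
  premature_ascvd_relative: 0.171
  relative_ldl_gt95: 0.10
  relative_xanthomata_arcus: 0.02
  child_ldl_gt95: 0.01
  hypercholesterolemia: 0.25
physical_signs:
  tendon_xanthomata: 0.0012
  arcus_before_45: 0.0006
comorbidities: {diabetes: 0.102, hypertension: 0.359}

# Rare-variant catalogue.  truth_plp marks variants the generator treats as
# disease-causing (they receive the monogenic LDL shift); carrier_share splits
# plp_carrier_rate among them.  Non-causal entries carry independently at
# carrier_rate and exercise the triage filters downstream.
variant_catalogue:
  - {id: LDLR_W23X, chrom: "19", pos: 11210912, ref: G, alt: A, gene: LDLR,
     consequence: stop_gain, ref_af: null, clinvar: null, pred_verdict: null,
     supplied_tags: [], truth_plp: true, carrier_share: 0.42}
  - {id: LDLR_G197fs, chrom: "19", pos: 11218103, ref: CT, alt: C, gene: LDLR,
     consequence: frameshift, ref_af: 0.00001, clinvar: pathogenic, pred_verdict: null,
     supplied_tags: [], truth_plp: true, carrier_share: 0.30}
  - {id: APOB_R3527Q, chrom: "2", pos: 21229160, ref: C, alt: T, gene: APOB,
     consequence: missense, ref_af: 0.0002, clinvar: pathogenic, pred_verdict: damaging,
     supplied_tags: [PS3], truth_plp: true, carrier_share: 0.24}
  - {id: PCSK9_D374Y, chrom: "1", pos: 55518316, ref: G, alt: T, gene: PCSK9,
     consequence: missense, ref_af: null, clinvar: pathogenic, pred_verdict: damaging,
     supplied_tags: [PS3, PM1], truth_plp: true, carrier_share: 0.04}
  - {id: LDLR_A391T, chrom: "19", pos: 11221447, ref: G, alt: A, gene: LDLR,
     consequence: missense, ref_af: 0.0004, clinvar: null, pred_verdict: unknown,
     supplied_tags: [], truth_plp: false, carrier_rate: 0.010}
  - {id: APOB_syn, chrom: "2", pos: 21231524, ref: G, alt: A, gene: APOB,
     consequence: synonymous, ref_af: 0.0008, clinvar: null, pred_verdict: null,
     supplied_tags: [], truth_plp: false, carrier_rate: 0.012}
  - {id: PCSK9_E670G, chrom: "1", pos: 55529187, ref: A, alt: G, gene: PCSK9,
     consequence: missense, ref_af: 0.005, clinvar: null, pred_verdict: benign,
     supplied_tags: [], truth_plp: false, carrier_rate: 0.008}
  - {id: LDLR_intronic, chrom: "19", pos: 11213463, ref: C, alt: T, gene: LDLR,
     consequence: intronic, ref_af: null, clinvar: null, pred_verdict: null,
     supplied_tags: [], truth_plp: false, carrier_rate: 0.006}
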