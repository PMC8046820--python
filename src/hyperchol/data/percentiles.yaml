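# SYNTHETIC age/sex-specific LDL-C percentile reference (mg/dl).
# Derived from a Gaussian LDL model (male mean 90 + 0.55*age, female mean
# 85 + 0.62*age, SD 34 mg/dl) evaluated at band midpoints; bands half-open [age_min, age_max), last band closed.  NON-CLINICAL:
# ships only so the strata machinery is testable; replace with a measured
# population table for any real-data use.
percentile_reference:
  - {sex: male,   age_min: 18, age_max: 30, p95: 159.1, p99: 182.3}
  - {sex: male,   age_min: 30, age_max: 40, p95: 165.2, p99: 188.4}
  - {sex: male,   age_min: 40, age_max: 50, p95: 170.7, p99: 193.9}
  - {sex: male,   age_min: 50, age_max: 60, p95: 176.2, p99: 199.4}
  - {sex: male,   age_min: 60, age_max: 70, p95: 181.7, p99: 204.9}
  - {sex: female, age_min: 18, age_max: 30, p95: 155.8, p99: 179.0}
  - {sex: female, age_min: 30, age_max: 40, p95: 162.6, p99: 185.8}
  - {sex: female, age_min: 40, age_max: 50, p95: 168.8, p99: 192.0}
  - {sex: female, age_min: 50, age_max: 60, p95: 175.0, p99: 198.2}
  - {sex: female, age_min: 60, age_max: 70, p95: 181.2, p99: 204.4}
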