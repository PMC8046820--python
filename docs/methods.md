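# Methods

## Pipeline

The analysis classifies each participant of a hypercholesterolemia cohort
along two independent axes and cross-tabulates them.

**Selection.** The index date is the first date with LDL-C ≥ 155 mg/dl
(inclusive).  A participant is retained when they consented, an index date
exists, age at index is within 18–70 (both ends inclusive), and no secondary
cause of hypercholesterolemia (hypothyroidism, cholestatic liver disease,
severe kidney disease, nephrotic syndrome, pregnancy) is dated within ±365
days (inclusive) of the index date.  "Within a 1-year window around" is read
as symmetric and boundary-inclusive; both conventions are configurable.
Exclusions are attributed to the first failing rule in a fixed order
(consent → no index → age → secondary cause) so funnel counts are
order-independent and conserve the screened total.

**Untreated LDL-C.** Statins lower LDL-C approximately proportionally, so for
participants on a statin at the index date the untreated level is imputed as
`observed / (1 − r)`, with `r` a per-type, per-dose reduction from a
configuration table (commonly published mean reductions; validated to lie in
[0, 1) and be non-decreasing in dose).  By default the imputation basis is
the highest recorded LDL-C ("max"); an "index" mode uses the index-date
measure instead.  Unit conversion uses 1 mmol/l = 38.67 mg/dl exactly.
Age/sex-specific ≥95th/≥99th percentile flags come from a cut-point table;
the shipped default is a synthetic Gaussian-derived table (male mean
90 + 0.55·age, female 85 + 0.62·age, SD 34 mg/dl) — explicitly non-clinical,
present so the strata machinery is fully testable and swappable for a
measured population reference.

**DLCN.** The Dutch Lipid Clinic Network score is additive over five groups —
family history (max 2), personal history (max 2), physical signs (max 6),
untreated LDL-C band (155–189: 1, 190–249: 3, 250–329: 5, ≥330: 8), DNA
(8) — and within each group only the highest satisfied condition counts.
Categories: <3 unlikely, 3–5 possible, 6–8 probable, >8 definite; phenotypic
FH ⇔ total ≥ 6.  Premature atherosclerotic events are strict: <55 y (males),
<65 y (females).  Arcus cornealis scores only before age 45, per the
standard table.  The DNA criterion is **excluded by default** so the
phenotypic definition remains independent of the genetic analysis it is
compared against (including it would make the overlap analysis circular);
it can be enabled for other uses.

**Variant classification.** Candidate variants in *LDLR*/*APOB*/*PCSK9* pass
triage when functional (missense, stop-gain, frameshift, splice
donor/acceptor, in-frame indel, start-lost, stop-lost) and rare (reference
frequency strictly < 0.1%, or never observed).  Automatable ACMG/AMP tags
are then assigned: PVS1 for null variants in genes where loss of function is
the disease mechanism (*LDLR* yes; *APOB*/*PCSK9* no — their FH variants act
by altered/gain of function, so the gate is per-gene configuration), PM2 for
rarity, PP3/BP4 from a computational verdict, PP5/BP6 from an external
clinical-database assertion (toggleable, as later guidance deprecates them).
Evidence from manual curation enters as directly supplied tags (`!TAG`
retracts an automatic tag; asserting and retracting the same tag is an
error).  The combining engine implements the full ACMG/AMP table
(pathogenic, likely pathogenic, benign, likely benign, else uncertain) and
returns "uncertain" whenever pathogenic-direction and benign-direction rules
both fire.  The engine is verified against an independently written
brute-force enumerator over all evidence multisets with per-category counts
≤ 4.  Copy-number variants are out of scope and rejected explicitly.  A
participant is **monogenic** when carrying ≥1 alternate allele of ≥1 P/LP
variant.

**Polygenic score.** `raw = Σⱼ wⱼ dⱼ` over the 12-SNV panel; missing dosages
are imputed as `2·pⱼ` (Hardy–Weinberg expectation; a strict mode rejects
them; >50% missing always rejected).  Effect alleles are matched against VCF
REF/ALT; a mismatch is an orientation error, never a silent flip.
**Polygenic etiology** is raw ≥ 1.16 (the reference distribution's 90th
percentile, inclusive) in a participant without a monogenic finding —
monogenic takes precedence, and the polygenic marginal percentage uses the
full cohort as denominator.  An empirical reference distribution can be
supplied for percentile reporting; none ships because the derivation
cohort's distribution is not public.

**Summaries.** Every percentage is emitted with numerator and denominator and
rounded half-up to one decimal through a single shared routine.  Composite
figures that the source table quotes as sums of rounded components (26.0 =
7.0 + 19.0, while the direct ratio 37/142 rounds to 26.1) are reported both
ways with a note.  Group comparisons use Welch's t-test, one-way ANOVA, and
chi-square (two-sided, α = 0.05; significance stars at
0.05/0.01/0.001/0.0001; no multiplicity correction).  Variance explained is
reported from two separate OLS fits of untreated LDL-C — genetic predictors
(raw PGS, monogenic indicator) and clinical predictors (age, sex, race, BMI,
diabetes, family history of hypercholesterolemia) — matching the convention
of quoting each block's own R²; collinear or constant predictors raise an
error rather than being dropped silently.

## Synthetic cohort generator

The generator simulates a hypercholesterolemia-enriched screening population
(not the general population); applying the selection funnel to it yields the
analysis cohort.  Components, with defaults in `data/generator.yaml`:

* **Genotypes.** Panel dosages are Binomial(2, pⱼ) per SNV (Hardy–Weinberg,
  no linkage — all subjects unrelated).  The shipped panel uses the classic
  12 LDL-C score loci (rsIDs, genes, alleles), but its frequencies and
  weights are a calibrated stand-in: they were scaled once, analytically, so
  the implied score distribution puts its 90th percentile at the clinical
  cutoff 1.16 (population mean Σ2pⱼwⱼ ≈ 0.883, SD √(Σ2pⱼ(1−pⱼ)wⱼ²) ≈ 0.217).
* **LDL-C model.** untreated = 112 + 0.25·(age−50) − 6·male + 38.67·PGS +
  shift·carrier + ε, with age ~ Normal(50, 12) clipped to [20, 80], carrier
  status Bernoulli(0.005), shift ~ Normal(85, 15) mg/dl, and ε a
  **right-skewed** standardized lognormal (shape 0.40) scaled to SD 37.5
  mg/dl.  The skew is essential: a truncated Gaussian cannot show SD ≈ 32
  above a 155 mg/dl cut while the mean sits at ≈ 187.
* **Observation.** Statin users (more likely when untreated LDL-C is very
  high) have observed = untreated × (1 − r) with r from the coefficient
  table; selection operates on observed values, the clinical stages on
  imputed untreated values.  Secondary-cause diagnoses, family-history
  flags, physical signs and comorbidities are Bernoulli at configured
  prevalences, with diagnosis dates scattered around the index date so the
  exclusion window is exercised.
* **Rare variants.** A configurable catalogue mixes genuinely
  P/LP-classifiable variants (an *LDLR* stop-gain and frameshift, the *APOB*
  p.Arg3527Gln founder missense, a *PCSK9* gain-of-function missense — each
  with exactly the annotations that make the rule engine produce its class)
  with non-causal variants that exercise the triage filters (a VUS, a
  synonymous, a too-common missense, an intronic variant).  Causal-variant
  carriers receive the LDL shift; truth labels (monogenic / polygenic-tail /
  neither) partition the cohort and record the noise-free genetic component.

**Calibration.**  Defaults were fixed once, at design time, so that the
*selected* cohort reproduces the study conditions: untreated LDL-C
≈ 187 ± 32 mg/dl, P/LP carriers ≈ 1.5% (the population rate 0.005 is lower;
selection enriches carriers about three-fold), carrier-vs-rest difference
≈ 40 mg/dl (the population shift of 85 attenuates under truncation), ~16%
with PGS ≥ 1.16, and ~3% on statins.  The residual SD was solved so that
genetic factors (PGS + carrier shift) explain 7.0% of the population
variance in untreated LDL-C and the age/sex baseline about 1.1% — the two
variance-explained figures the analysis reports.  The closed form lives in
`GeneratorConfig.genetic_variance_fraction()`.

**Known deviations.**  Two emulation targets are deliberately not matched
exactly.  (1) The cohort PGS mean comes out ≈ 0.93 rather than ≈ 0.97:
with the genetic variance share pinned at 7%, the PGS–LDL correlation
(~0.21) bounds how much selection on LDL-C can enrich the score; pushing
the mean to 0.97 would require a much larger genetic share.  (2) The
phenotypic-FH rate in the simulated selected cohort is ~3% rather than
~8%, because criterion flags are drawn independently of LDL-C; real
family-history and event flags are positively correlated with LDL-C.
Neither affects the fixture-based overlap analysis, which is exact.

## Count fixture

`fixture_from_counts` builds a deterministic cohort that reproduces a table
of marginal and joint counts exactly *through the real classifiers* — no
label pass-through.  All LDL strata are realized on a single LDL axis with
percentile cut points 175/215 mg/dl (one age/sex band; the fixture carries
its own percentile reference) and clinical cuts at 190/250; subjects sit at
stratum midpoints (165/182/200/232/265 mg/dl).  This requires the stratum
and joint counts to be monotone along that axis — validated, with violations
rejected as unrealizable.  Monogenic subjects carry catalogue P/LP variants
(gene split as requested), polygenic subjects carry the all-effect-allele
panel genotype (raw score 2Σw ≈ 2.23 ≥ 1.16), and phenotypic-FH subjects get
the minimal flag set (relative with xanthomata: 2 points; premature CHD at
45: 2 points) that crosses the ≥ 6 line together with their ≥ 190 mg/dl band
points — which is why FH subjects must lie in the ≥ 190 stratum, also
validated.  The fixture reproduces the overlap marginals and joints; the
unlikely-vs-possible split below DLCN 6 is not constrained (matching it
would need joint information about sub-threshold flag patterns that the
count table does not carry).

## Numerical conventions

* Percentages: decimal arithmetic on exact ratios, half-up, one decimal,
  one shared routine; empty denominators yield an explicit undefined
  marker, never 0.
* Boundaries: LDL ≥ 155 inclusive (index and DLCN band), PGS ≥ 1.16
  inclusive, frequency < 0.1% strict, premature-event ages strict,
  age 18–70 inclusive, ±365-day window inclusive, percentile cut points
  inclusive.
* Determinism: all generator randomness flows through one
  `numpy.random.default_rng(seed)`; identical config + seed reproduces the
  cohort exactly (tested).  VCF INFO floats are 32-bit; frequencies are
  snapped to six significant digits on read so write/read round trips are
  exact.
* Problem sizes: calibration checks run at n = 50,000 (shared across
  assertions via a session fixture), pipeline-level tests at n ≤ 2,000,
  the ACMG oracle sweep over all 5⁷ evidence-count combinations.

## Limitations

* The synthetic percentile reference and statin coefficients are
  literature-typical configuration values, not measured tables; both are
  swappable data files.
* The ACMG engine automates only annotation-derivable criteria; curation
  evidence must be supplied as tags.  Per-variant reproduction of a real
  curation effort is out of reach by construction.
* The generator draws criterion flags independently of LDL-C and models no
  relatedness, linkage, or ancestry structure; passing calibration tests
  shows the pipeline arithmetic is right under the stated model, not that
  the model captures real EHR data.
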