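# hyperchol

Attributing primary hypercholesterolemia to **monogenic**, **polygenic**, or
**unexplained** etiology, and quantifying how poorly genetic etiology overlaps
with clinically defined familial hypercholesterolemia (FH).

## The problem

Severe LDL cholesterol elevation (LDL-C ≥ 155 mg/dl, ~4 mmol/l, without a
secondary cause such as hypothyroidism or nephrotic syndrome) can arise three
ways:

* **Monogenic** — a pathogenic or likely-pathogenic (P/LP) variant in *LDLR*,
  *APOB* or *PCSK9*, classified under the ACMG/AMP evidence-combining rules;
* **Polygenic** — an unlucky load of common LDL-raising alleles, measured by a
  12-SNV weighted score `PGS = Σⱼ wⱼ dⱼ` (effect-allele dosages `dⱼ ∈ {0,1,2}`,
  per-allele weights `wⱼ` in mmol/l), with polygenic etiology defined as
  PGS ≥ 1.16 — the reference population's 90th percentile — in a non-carrier;
* **Unexplained** — neither.

Clinically, FH is diagnosed with the Dutch Lipid Clinic Network (DLCN) point
score over family history, personal history of premature atherosclerotic
disease (<55 y males, <65 y females), physical signs, and untreated LDL-C
bands; a total ≥ 6 (probable/definite) defines phenotypic FH.  For
statin-treated individuals the untreated level is imputed as
`observed / (1 − r)` with a type- and dose-specific reduction `r`.

This package implements the full pipeline — cohort selection funnel, statin
back-correction and age/sex percentile strata, DLCN scoring, rare-variant
triage (functional consequence, reference frequency < 0.1%) with an ACMG/AMP
rule engine, polygenic scoring, and the genotype–phenotype overlap
cross-tabulation — plus a synthetic-cohort generator so every stage is
testable end to end without access-controlled data.

## Worked example

The numbered drivers under `analysis/` narrate the study: `01` simulates the
screening population, `02` runs the pipeline on its files, `03` reproduces
the reference cohort's overlap table from printed counts, `04` fits the
variance decomposition.  Running `python analysis/03_reference_overlap.py`
prints:

```
Overlap of genetic and phenotypic FH (reference cohort, n = 1682):
  phenotypic_fh_of_cohort: 142/1682 = 8.4%
  monogenic_of_cohort: 25/1682 = 1.5%
  polygenic_of_cohort: 262/1682 = 15.6%
  genetic_of_cohort: 287/1682 = 17.1%
  monogenic_of_fh: 10/142 = 7.0%
  polygenic_of_fh: 27/142 = 19.0%
  genetic_of_fh: 37/142 = 26.1%
  fh_of_genetic: 37/287 = 12.9%
  ...
note: direct rounding 26.1; sum of rounded components 26.0
```

Reading: 8.4% of the cohort meets clinical FH criteria and 17.1% has an
identifiable genetic etiology, but the two barely overlap — only ~26% of
clinical-FH cases have a genetic finding (7.0% monogenic + 19.0% polygenic),
and only 12.9% of genetic-etiology cases meet clinical criteria.  The yield
of monogenic findings rises with the LDL-C stratum (3.4% at ≥190 mg/dl,
11.6% at ≥250 mg/dl).  Every percentage carries its numerator and
denominator, and all rounding goes through one shared half-up routine.

`python analysis/04_variance_and_groups.py` additionally reports that genetic
factors (raw PGS + monogenic carriage) explain ~6.9% of the variance in
untreated LDL-C in the simulated population while clinical/demographic
factors explain ~1.0%, and that P/LP carriers in the selected cohort run
~36–39 mg/dl higher than the other groups (Welch t, p < 1e-22).

## Layout

```
src/hyperchol/     library: selection, lipids, dlcn, acmg, pgs, overlap,
                   synthetic, vcfio/tabio, pipeline, cli (+ data/*.yaml
                   configuration: SNV panel, DLCN points, statin
                   coefficients, percentile reference, generator defaults)
analysis/          numbered narrative drivers writing results/
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model, calibration and design notes
```
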