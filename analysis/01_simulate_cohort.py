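#!/usr/bin/env python
"""Simulate the default screening population and write its input files.

Generates the default synthetic population (n = 20,000, seed 42), writes the
genotype VCF + phenotype table + truth labels under scratch/cohort/ (inputs
for 02), and records a small distributional summary under results/.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main():
    from hyperchol.synthetic import GeneratorConfig, generate_population, write_cohort

    cfg = GeneratorConfig.default()
    cohort = generate_population(cfg)
    paths = write_cohort(cohort, ROOT / "scratch" / "cohort")

    t = cohort.truth
    sel = t[t["observed_ldl"] >= 155.0]
    summary = {
        "n_population": int(cohort.n),
        "seed": cfg.seed,
        "population_ldl_mean": round(float(t["untreated_ldl"].mean()), 1),
        "population_ldl_sd": round(float(t["untreated_ldl"].std()), 1),
        "selected_fraction": round(float((t["observed_ldl"] >= 155).mean()), 3),
        "selected_ldl_mean": round(float(sel["untreated_ldl"].mean()), 1),
        "selected_ldl_sd": round(float(sel["untreated_ldl"].std()), 1),
        "selected_plp_carrier_pct": round(100 * float(sel["carrier"].mean()), 2),
        "selected_pgs_mean": round(float(sel["pgs_raw"].mean()), 3),
        "configured_genetic_variance_fraction": round(cfg.genetic_variance_fraction(), 4),
    }
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote cohort files to {paths.vcf.parent}")
    print("Simulated screening population:")
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
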