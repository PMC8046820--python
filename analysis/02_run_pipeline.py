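#!/usr/bin/env python
"""Run the full etiology pipeline on the simulated cohort files.

Reads scratch/cohort/ (written by 01), executes selection -> statin
adjustment -> DLCN -> variant classification -> PGS -> overlap summary with
the default configuration, leaves the per-participant artifacts under
scratch/pipeline/, and copies the compact reports (funnel, overlap summary,
manifest) to results/.
"""

import json
import shutil
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main():
    from hyperchol.config import PipelineConfig
    from hyperchol.pipeline import run_pipeline

    cohort_dir = ROOT / "scratch" / "cohort"
    if not (cohort_dir / "genotypes.vcf").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    out_dir = ROOT / "scratch" / "pipeline"
    manifest = run_pipeline(
        PipelineConfig(), cohort_dir / "genotypes.vcf", cohort_dir / "phenotypes.tsv", out_dir
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in ("funnel.json", "summary.json", "manifest.json"):
        shutil.copy(out_dir / name, results / f"02_{name}")

    counts = manifest["counts"]
    print("Funnel:", {k: counts[k] for k in counts if k.startswith(("screened", "excluded", "retained"))})
    summary = json.loads((out_dir / "summary.json").read_text())
    print("Etiology in the selected cohort:")
    for key in ("monogenic_of_cohort", "polygenic_of_cohort", "genetic_of_cohort", "phenotypic_fh_of_cohort"):
        p = summary["percentages"][key]
        print(f"  {key}: {p['numerator']}/{p['denominator']} = {p['value']}%")


if __name__ == "__main__":
    main()
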