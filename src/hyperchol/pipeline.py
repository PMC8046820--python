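"""End-to-end orchestration: select -> adjust -> DLCN -> variants -> PGS -> summarize.

Each stage is a plain function over in-memory objects so tests and the
acceptance analysis can drive them directly; :func:`run_pipeline` wraps the
same functions with file I/O and writes a manifest (seed, config hash,
per-stage counts) alongside the artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .acmg import (
    AnnotatedVariant,
    ClassificationResult,
    assign_evidence,
    call_monogenic,
    combine_acmg,
    filter_variants,
)
from .config import PipelineConfig
from .dlcn import derive_inputs, score_dlcn
from .errors import CollinearityError, ConfigError
from .lipids import assign_percentile_strata, impute_untreated_ldl
from .overlap import CohortSummary, EtiologyCall, classify_etiology, crosstab_overlap, variance_explained
from .records import ParticipantRecord
from .selection import SelectionResult, apply_selection

log = logging.getLogger("hyperchol")


def stage_adjust(
    records: Sequence[ParticipantRecord],
    index_dates: Mapping[str, object],
    cfg: PipelineConfig,
    percentile_reference=None,
) -> pd.DataFrame:
    """Untreated-LDL imputation and percentile strata for retained participants."""
    reference = percentile_reference or cfg.percentile_reference
    rows = []
    for rec in records:
        index = index_dates[rec.participant_id]
        if cfg.imputation_basis == "index":
            basis = rec.ldl_on(index)
        else:
            basis = rec.max_ldl()
        if basis is None:
            raise ConfigError(f"{rec.participant_id}: no LDL measure available for imputation")
        untreated = impute_untreated_ldl(basis, rec.statin, cfg.statin_table)
        ge95, ge99 = assign_percentile_strata(untreated, rec.age, rec.sex, reference)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "age": rec.age,
                "sex": rec.sex,
                "male": rec.sex == "male",
                "white": rec.race == "white",
                "bmi": rec.bmi,
                "diabetes": rec.diabetes,
                "fam_hypercholesterolemia": rec.fam_hypercholesterolemia,
                "on_statin": rec.statin is not None and rec.statin.active_on_index,
                "observed_ldl": basis,
                "untreated_ldl": untreated,
                "ge95th": ge95,
                "ge99th": ge99,
                "ge190": untreated >= 190.0,
                "ge250": untreated >= 250.0,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def stage_dlcn(
    records: Sequence[ParticipantRecord],
    untreated: Mapping[str, float],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    rows = []
    for rec in records:
        inputs = derive_inputs(rec, untreated[rec.participant_id])
        result = score_dlcn(inputs, cfg.dlcn_points, include_dna=cfg.include_dna)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "dlcn_total": result.total,
                "dlcn_category": result.category,
                "phenotypic_fh": result.phenotypic_fh,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def stage_classify_variants(
    variants: Sequence[AnnotatedVariant], cfg: PipelineConfig
) -> Tuple[pd.DataFrame, Dict[str, ClassificationResult]]:
    """Triage filters plus ACMG classification; one row per candidate."""
    triage = filter_variants(variants, cfg.frequency_threshold)
    classifications: Dict[str, ClassificationResult] = {}
    rows = []
    for v in triage.failed_functional:
        rows.append({"variant": v.key, "gene": v.gene, "status": "fail_functional",
                     "classification": "", "rule": "", "evidence": ""})
    for v in triage.failed_rare:
        rows.append({"variant": v.key, "gene": v.gene, "status": "fail_rare",
                     "classification": "", "rule": "", "evidence": ""})
    for v in triage.passed:
        ev = assign_evidence(v, cfg.lof_mechanism, cfg.frequency_threshold, cfg.use_pp5_bp6)
        result = combine_acmg(ev)
        classifications[v.key] = result
        rows.append(
            {
                "variant": v.key,
                "gene": v.gene,
                "status": "classified",
                "classification": result.classification,
                "rule": result.rule,
                "evidence": ",".join(ev.tags()),
            }
        )
    return pd.DataFrame(rows), classifications


def stage_monogenic(
    participant_ids: Sequence[str],
    carriage: Mapping[str, Mapping[str, int]],
    classifications: Mapping[str, ClassificationResult],
    variants: Sequence[AnnotatedVariant],
) -> pd.DataFrame:
    """Per-participant monogenic flag and carried P/LP genes.

    Carriage of variants that failed the triage filters is dropped before the
    call: un-triaged variants are by definition not P/LP findings.
    """
    gene_of = {v.key: v.gene for v in variants}
    rows = []
    for pid in participant_ids:
        carried = {k: n for k, n in carriage.get(pid, {}).items() if k in classifications}
        flag = call_monogenic(carried, classifications)
        genes = sorted(
            {gene_of[k] for k, n in carried.items() if n > 0 and classifications[k].is_plp}
        )
        rows.append({"participant_id": pid, "monogenic": flag, "plp_genes": ",".join(genes)})
    return pd.DataFrame(rows).set_index("participant_id")


def stage_pgs(
    dosages: pd.DataFrame,
    participant_ids: Sequence[str],
    monogenic: Mapping[str, bool],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    from .pgs import classify_polygenic, compute_pgs

    rows = []
    for pid in participant_ids:
        row = dosages.loc[pid]
        vec = {snv: (None if pd.isna(d) else int(d)) for snv, d in row.items()}
        raw = compute_pgs(vec, cfg.panel, cfg.missing_policy)
        rows.append(
            {
                "participant_id": pid,
                "pgs_raw": raw,
                "polygenic": classify_polygenic(raw, cfg.pgs_threshold, monogenic[pid]),
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


@dataclass
class AnalysisResult:
    selection: SelectionResult
    table: pd.DataFrame  # merged per-participant table (retained cohort)
    calls: List[EtiologyCall]
    summary: CohortSummary
    variant_table: pd.DataFrame
    variance: Optional[object] = None
    variance_note: str = ""


def build_calls(table: pd.DataFrame) -> List[EtiologyCall]:
    calls = []
    for pid, row in table.iterrows():
        calls.append(
            EtiologyCall(
                participant_id=pid,
                etiology=classify_etiology(bool(row["monogenic"]), bool(row["polygenic"])),
                dlcn_category=row["dlcn_category"],
                phenotypic_fh=bool(row["phenotypic_fh"]),
                untreated_ldl=float(row["untreated_ldl"]),
                ge190=bool(row["ge190"]),
                ge250=bool(row["ge250"]),
                ge95th=bool(row["ge95th"]),
                ge99th=bool(row["ge99th"]),
                plp_genes=tuple(g for g in str(row["plp_genes"]).split(",") if g),
            )
        )
    return calls


def analyze_cohort(cohort, cfg: Optional[PipelineConfig] = None, run_variance: bool = True) -> AnalysisResult:
    """Run every stage on an in-memory synthetic cohort."""
    cfg = cfg or PipelineConfig()
    sel = apply_selection(cohort.participants, cfg.selection)
    retained = [p for p in cohort.participants if p.participant_id in set(sel.retained_ids)]
    log.info("selection: %d screened -> %d retained", sel.screened, sel.n_retained)

    adjusted = stage_adjust(retained, sel.index_dates, cfg, cohort.percentile_reference)
    dlcn = stage_dlcn(retained, adjusted["untreated_ldl"].to_dict(), cfg)
    variant_table, classifications = stage_classify_variants(cohort.variants, cfg)
    mono = stage_monogenic(
        [p.participant_id for p in retained], cohort.rare_carriage, classifications, cohort.variants
    )
    pgs = stage_pgs(
        cohort.genotypes, [p.participant_id for p in retained], mono["monogenic"].to_dict(), cfg
    )
    table = adjusted.join([dlcn, mono, pgs])
    calls = build_calls(table)
    summary = crosstab_overlap(calls)
    log.info(
        "etiology: %d monogenic, %d polygenic, %d none",
        summary.counts["monogenic"],
        summary.counts["polygenic"],
        summary.counts["total"] - summary.counts["genetic"],
    )
    variance = None
    note = ""
    if run_variance:
        try:
            variance = variance_explained(table)
        except (CollinearityError, ConfigError) as exc:
            note = f"variance decomposition skipped: {exc}"
            log.warning(note)
    return AnalysisResult(
        selection=sel,
        table=table,
        calls=calls,
        summary=summary,
        variant_table=variant_table,
        variance=variance,
        variance_note=note,
    )


def run_pipeline(cfg: PipelineConfig, vcf_path, pheno_path, out_dir) -> dict:
    """File-based end-to-end run; returns (and writes) the manifest."""
    from .pgs import SNVPanel  # noqa: F401  (panel travels inside cfg)
    from .tabio import read_phenotypes
    from .vcfio import read_genotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_phenotypes(pheno_path)
    dosages, variants, carriage = read_genotypes(vcf_path, cfg.panel)

    class _Shim:
        pass

    cohort = _Shim()
    cohort.participants = records
    cohort.genotypes = dosages
    cohort.variants = variants
    cohort.rare_carriage = carriage
    cohort.percentile_reference = None

    result = analyze_cohort(cohort, cfg)

    funnel = result.selection.funnel()
    pd.Series(funnel).to_csv(out / "funnel.tsv", sep="\t", header=["count"])
    (out / "funnel.json").write_text(json.dumps(funnel, indent=2))
    result.table.to_csv(out / "participants.tsv", sep="\t")
    result.variant_table.to_csv(out / "variants.tsv", sep="\t", index=False)
    summary_dict = result.summary.to_json_dict()
    (out / "summary.json").write_text(json.dumps(summary_dict, indent=2))
    pct_rows = [
        {"statistic": name, **vals} for name, vals in summary_dict["percentages"].items()
    ]
    pd.DataFrame(pct_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    if result.variance is not None:
        (out / "regression.json").write_text(
            json.dumps(
                {
                    "r2_genetic": result.variance.r2_genetic,
                    "r2_clinical": result.variance.r2_clinical,
                    "n": result.variance.n,
                },
                indent=2,
            )
        )
        result.variance.coefficients_genetic.to_csv(out / "regression_genetic.tsv", sep="\t")
        result.variance.coefficients_clinical.to_csv(out / "regression_clinical.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "counts": {
            **funnel,
            "variant_candidates": int(len(result.variant_table)),
            "variants_classified": int((result.variant_table["status"] == "classified").sum())
            if len(result.variant_table)
            else 0,
            **{k: int(v) for k, v in result.summary.counts.items()},
        },
        "variance_note": result.variance_note,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
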