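"""VCF reading and writing (v4.2, via pysam).

Panel SNVs are matched by rsID first, then by position; the effect allele
must equal REF or ALT — anything else is an orientation error, never a silent
strand flip.  Multi-allelic records are decomposed into bi-allelic
representations before matching.  Rare candidate variants in the three FH
genes travel in INFO keys GENE, CSQCLASS, REFAF, CLNSIG, PREDVERDICT and EVID
(comma-separated supplied ACMG tags).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import pysam

from .acmg import AnnotatedVariant
from .errors import ConfigError, OrientationError
from .pgs import SNVPanel

_INFO_FIELDS = (
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQCLASS", "1", "String", "Consequence class"),
    ("REFAF", "1", "Float", "Reference-population allele frequency"),
    ("CLNSIG", "1", "String", "External clinical-database classification"),
    ("PREDVERDICT", "1", "String", "Computational prediction verdict"),
    ("EVID", ".", "String", "Directly supplied ACMG evidence tags"),
    ("PANEL", "0", "Flag", "Polygenic-score panel SNV"),
    ("EAF", "1", "Float", "Panel effect-allele frequency"),
)


def _build_header(sample_ids, contigs) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_cohort_vcf(cohort, path) -> None:
    """Emit panel SNVs (dosage as GT) and rare variants (carriage as GT)."""
    path = Path(path)
    sample_ids = [p.participant_id for p in cohort.participants]
    panel_cols = list(cohort.genotypes.columns)

    from .config import load_default_panel

    try:
        panel = load_default_panel()
        panel_meta = {e.snv_id: e for e in panel.entries if e.snv_id in panel_cols}
    except Exception:
        panel_meta = {}

    records: List[dict] = []
    for snv_id in panel_cols:
        meta = panel_meta.get(snv_id)
        if meta is None:
            raise ConfigError(f"panel SNV {snv_id!r} has no metadata in the configured panel")
        dosages = cohort.genotypes[snv_id]
        records.append(
            {
                "chrom": meta.chrom,
                "pos": meta.pos,
                "id": snv_id,
                "ref": meta.other_allele,
                "alt": meta.effect_allele,
                "info": {"PANEL": True, "EAF": meta.eaf},
                "gt": {
                    sid: {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(dosages.loc[sid])]
                    for sid in sample_ids
                },
            }
        )
    for variant in cohort.variants:
        gt = {}
        for sid in sample_ids:
            count = cohort.rare_carriage.get(sid, {}).get(variant.key, 0)
            gt[sid] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[count]
        info: dict = {"GENE": variant.gene, "CSQCLASS": variant.consequence}
        if variant.ref_af is not None:
            info["REFAF"] = variant.ref_af
        if variant.clinvar is not None:
            info["CLNSIG"] = variant.clinvar
        if variant.pred_verdict is not None:
            info["PREDVERDICT"] = variant.pred_verdict
        if variant.supplied_tags:
            info["EVID"] = tuple(variant.supplied_tags)
        records.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "id": variant.variant_id,
                "ref": variant.ref,
                "alt": variant.alt,
                "info": info,
                "gt": gt,
            }
        )

    contigs = []
    for rec in records:
        if rec["chrom"] not in contigs:
            contigs.append(rec["chrom"])
    header = _build_header(sample_ids, contigs)
    try:
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for rec in sorted(records, key=lambda r: (contigs.index(r["chrom"]), r["pos"])):
                out = vcf.new_record(
                    contig=rec["chrom"],
                    start=rec["pos"] - 1,
                    stop=rec["pos"] - 1 + len(rec["ref"]),
                    alleles=(rec["ref"], rec["alt"]),
                    id=rec["id"],
                )
                for key, value in rec["info"].items():
                    out.info[key] = value
                for sid, gt in rec["gt"].items():
                    out.samples[sid]["GT"] = gt
                vcf.write(out)
    except OSError as exc:
        raise ConfigError(f"failed to write VCF {path}: {exc}") from exc



def _info(rec, key, default=None):
    """INFO lookup tolerant of keys missing from the header."""
    try:
        value = rec.info.get(key, default)
    except (KeyError, ValueError):
        return default
    return default if value is None else value

def read_genotypes(
    vcf_path, panel: SNVPanel
) -> Tuple[pd.DataFrame, List[AnnotatedVariant], Dict[str, Dict[str, int]]]:
    """Extract panel dosages and rare candidate variants from a VCF.

    Returns (dosage table [participant x SNV, NA = missing GT], rare-variant
    list, per-participant carriage of rare-variant alternate alleles).
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise ConfigError(f"VCF not found: {vcf_path}")
    panel_by_id = {e.snv_id: e for e in panel.entries}
    panel_by_pos = {(e.chrom, e.pos): e for e in panel.entries}

    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        dosage: Dict[str, List] = {e.snv_id: [pd.NA] * len(samples) for e in panel.entries}
        variants: List[AnnotatedVariant] = []
        carriage: Dict[str, Dict[str, int]] = {}
        sample_pos = {sid: i for i, sid in enumerate(samples)}

        for rec in vcf:
            entry = panel_by_id.get(rec.id) or panel_by_pos.get((rec.contig, rec.pos))
            if entry is not None:
                alleles = (rec.ref,) + tuple(rec.alts or ())
                if entry.effect_allele not in alleles:
                    raise OrientationError(
                        f"panel SNV {entry.snv_id}: effect allele {entry.effect_allele!r} matches "
                        f"neither REF ({rec.ref}) nor ALT ({','.join(rec.alts or ())})"
                    )
                effect_index = alleles.index(entry.effect_allele)
                for sid in samples:
                    gt = rec.samples[sid].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue  # stays missing
                    dosage[entry.snv_id][sample_pos[sid]] = sum(a == effect_index for a in gt)
                continue
            gene = _info(rec, "GENE")
            if gene is None:
                continue
            # decompose multi-allelic records into bi-allelic representations
            evid = _info(rec, "EVID")
            if isinstance(evid, str):
                evid = (evid,)
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                refaf = _info(rec, "REFAF")
                # INFO floats are 32-bit; snap to 6 significant digits so a
                # write/read cycle reproduces the stored frequency exactly
                variant = AnnotatedVariant(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=str(gene),
                    consequence=str(_info(rec, "CSQCLASS", "other")),
                    ref_af=None if refaf is None else float(f"{float(refaf):.6g}"),
                    clinvar=_info(rec, "CLNSIG"),
                    pred_verdict=_info(rec, "PREDVERDICT"),
                    supplied_tags=tuple(evid) if evid else (),
                    variant_id=rec.id if (rec.id and len(rec.alts) == 1) else None,
                )
                variant.validate()
                variants.append(variant)
                for sid in samples:
                    gt = rec.samples[sid].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    count = sum(a == alt_index for a in gt)
                    if count > 0:
                        carriage.setdefault(sid, {})[variant.key] = count

    dosage_df = pd.DataFrame(dosage, index=samples).astype("Int64")
    return dosage_df, variants, carriage
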