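"""Phenotype-table serialization (tab-separated, one row per participant).

Header columns
--------------
participant_id, age, sex, race, bmi, consented,
lipids          semicolon list of ``date:ldl:trig:hdl`` (ISO dates, mg/dl; empty
                subfield = not measured),
diagnoses       semicolon list of ``date:code:age_at_event``,
statin_type, statin_dose_mg, statin_active   (empty type = no statin),
fam_premature_ascvd, fam_relative_ldl_gt95, fam_relative_xanthomata_arcus,
fam_child_ldl_gt95, fam_hypercholesterolemia,
tendon_xanthomata, arcus_cornealis, arcus_age,
diabetes, hypertension     (booleans as 1/0)

Floats are written with ``repr`` so a write/read round trip is exact.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import List, Optional, Sequence

from .errors import ConfigError
from .records import Diagnosis, LipidMeasure, ParticipantRecord, StatinExposure

COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "race",
    "bmi",
    "consented",
    "lipids",
    "diagnoses",
    "statin_type",
    "statin_dose_mg",
    "statin_active",
    "fam_premature_ascvd",
    "fam_relative_ldl_gt95",
    "fam_relative_xanthomata_arcus",
    "fam_child_ldl_gt95",
    "fam_hypercholesterolemia",
    "tendon_xanthomata",
    "arcus_cornealis",
    "arcus_age",
    "diabetes",
    "hypertension",
]


def _opt(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def _parse_opt(text: str) -> Optional[float]:
    return None if text == "" else float(text)


def _flag(value: bool) -> str:
    return "1" if value else "0"


def _serialize_lipids(lipids: Sequence[LipidMeasure]) -> str:
    return ";".join(
        f"{m.date.isoformat()}:{_opt(m.ldl)}:{_opt(m.triglycerides)}:{_opt(m.hdl)}" for m in lipids
    )


def _parse_lipids(text: str) -> tuple:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        date_s, ldl_s, tg_s, hdl_s = part.split(":")
        out.append(
            LipidMeasure(
                dt.date.fromisoformat(date_s),
                float(ldl_s),
                _parse_opt(tg_s),
                _parse_opt(hdl_s),
            )
        )
    return tuple(out)


def _serialize_diagnoses(diagnoses: Sequence[Diagnosis]) -> str:
    return ";".join(f"{d.date.isoformat()}:{d.code}:{_opt(d.age_at_event)}" for d in diagnoses)


def _parse_diagnoses(text: str) -> tuple:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        date_s, code, age_s = part.split(":")
        out.append(Diagnosis(dt.date.fromisoformat(date_s), code, float(age_s)))
    return tuple(out)


def write_phenotypes(participants: Sequence[ParticipantRecord], path) -> None:
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(COLUMNS)
            for p in participants:
                writer.writerow(
                    [
                        p.participant_id,
                        repr(float(p.age)),
                        p.sex,
                        p.race,
                        _opt(p.bmi),
                        _flag(p.consented),
                        _serialize_lipids(p.lipids),
                        _serialize_diagnoses(p.diagnoses),
                        p.statin.statin_type if p.statin else "",
                        _opt(p.statin.dose_mg) if p.statin else "",
                        _flag(p.statin.active_on_index) if p.statin else "",
                        _flag(p.fam_premature_ascvd),
                        _flag(p.fam_relative_ldl_gt95),
                        _flag(p.fam_relative_xanthomata_arcus),
                        _flag(p.fam_child_ldl_gt95),
                        _flag(p.fam_hypercholesterolemia),
                        _flag(p.tendon_xanthomata),
                        _flag(p.arcus_cornealis),
                        _opt(p.arcus_age),
                        _flag(p.diabetes),
                        _flag(p.hypertension),
                    ]
                )
    except OSError as exc:
        raise ConfigError(f"failed to write phenotype table {path}: {exc}") from exc


def read_phenotypes(path) -> List[ParticipantRecord]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"phenotype table not found: {path}")
    out: List[ParticipantRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != COLUMNS:
            raise ConfigError(
                f"phenotype table {path}: unexpected header (expected {len(COLUMNS)} documented columns)"
            )
        for row in reader:
            vals = dict(zip(COLUMNS, row))
            statin = None
            if vals["statin_type"]:
                statin = StatinExposure(
                    statin_type=vals["statin_type"],
                    dose_mg=float(vals["statin_dose_mg"]),
                    active_on_index=vals["statin_active"] == "1",
                )
            out.append(
                ParticipantRecord(
                    participant_id=vals["participant_id"],
                    age=float(vals["age"]),
                    sex=vals["sex"],
                    race=vals["race"],
                    bmi=_parse_opt(vals["bmi"]),
                    consented=vals["consented"] == "1",
                    lipids=_parse_lipids(vals["lipids"]),
                    diagnoses=_parse_diagnoses(vals["diagnoses"]),
                    statin=statin,
                    fam_premature_ascvd=vals["fam_premature_ascvd"] == "1",
                    fam_relative_ldl_gt95=vals["fam_relative_ldl_gt95"] == "1",
                    fam_relative_xanthomata_arcus=vals["fam_relative_xanthomata_arcus"] == "1",
                    fam_child_ldl_gt95=vals["fam_child_ldl_gt95"] == "1",
                    fam_hypercholesterolemia=vals["fam_hypercholesterolemia"] == "1",
                    tendon_xanthomata=vals["tendon_xanthomata"] == "1",
                    arcus_cornealis=vals["arcus_cornealis"] == "1",
                    arcus_age=_parse_opt(vals["arcus_age"]),
                    diabetes=vals["diabetes"] == "1",
                    hypertension=vals["hypertension"] == "1",
                )
            )
    return out


def write_truth(truth, path) -> None:
    truth.to_csv(path, sep="\t", index_label="participant_id")


def read_truth(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="participant_id")
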