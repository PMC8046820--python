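"""Participant-level data model.

A :class:`ParticipantRecord` carries everything the clinical stages need:
dated lipid panels, dated diagnoses, statin exposure, family-history and
physical-sign flags.  Records are plain dataclasses so they serialize to a
one-row-per-participant tab-separated table (see :mod:`hyperchol.tabio`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import ConfigError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Diagnoses that make hypercholesterolemia "secondary" when dated within the
#: exclusion window around the index date.
SECONDARY_CAUSE_CODES = frozenset(
    {
        "hypothyroidism",
        "cholestatic_liver_disease",
        "severe_kidney_disease",
        "nephrotic_syndrome",
        "pregnancy",
    }
)

#: Atherosclerotic cardiovascular event codes (feed the DLCN personal-history
#: group via the premature-ASCVD rule).
ASCVD_CODES = frozenset({"CHD", "cerebrovascular", "peripheral_artery"})

OTHER_CODES = frozenset({"diabetes", "hypertension"})

DIAGNOSIS_CODES = SECONDARY_CAUSE_CODES | ASCVD_CODES | OTHER_CODES


@dataclass(frozen=True)
class LipidMeasure:
    date: dt.date
    ldl: float  # mg/dl
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None


@dataclass(frozen=True)
class Diagnosis:
    date: dt.date
    code: str
    age_at_event: float


@dataclass(frozen=True)
class StatinExposure:
    statin_type: str
    dose_mg: float
    active_on_index: bool = True


@dataclass
class ParticipantRecord:
    participant_id: str
    age: float  # years at index
    sex: str  # "male" / "female"
    race: str = "white"
    bmi: Optional[float] = None
    lipids: Sequence[LipidMeasure] = field(default_factory=tuple)
    diagnoses: Sequence[Diagnosis] = field(default_factory=tuple)
    statin: Optional[StatinExposure] = None
    fam_premature_ascvd: bool = False
    fam_relative_ldl_gt95: bool = False
    fam_relative_xanthomata_arcus: bool = False
    fam_child_ldl_gt95: bool = False
    tendon_xanthomata: bool = False
    arcus_cornealis: bool = False
    arcus_age: Optional[float] = None
    diabetes: bool = False
    hypertension: bool = False
    fam_hypercholesterolemia: bool = False
    consented: bool = True

    def validate(self) -> None:
        pid = self.participant_id
        if self.age < 0:
            raise ConfigError(f"{pid}: age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise ConfigError(f"{pid}: sex must be one of {SEXES}, got {self.sex!r}")
        for m in self.lipids:
            if not m.ldl > 0:
                raise ConfigError(f"{pid}: LDL-C must be > 0, got {m.ldl}")
            if not isinstance(m.date, dt.date):
                raise ConfigError(f"{pid}: lipid measure date invalid: {m.date!r}")
        for d in self.diagnoses:
            if d.code not in DIAGNOSIS_CODES:
                raise ConfigError(f"{pid}: unknown diagnosis code {d.code!r}")

    def copy(self, **changes) -> "ParticipantRecord":
        return replace(self, **changes)

    def max_ldl(self) -> Optional[float]:
        if not self.lipids:
            return None
        return max(m.ldl for m in self.lipids)

    def ldl_on(self, date: dt.date) -> Optional[float]:
        for m in self.lipids:
            if m.date == date:
                return m.ldl
        return None
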