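"""Dutch Lipid Clinic Network (DLCN) scoring.

The DLCN score is additive over five criterion groups — family history,
personal history, physical examination, (untreated) LDL-C level, and DNA —
and within each group only the highest-scoring satisfied condition counts.
Categories: unlikely (<3), possible (3-5), probable (6-8), definite (>8);
phenotypic familial hypercholesterolemia (FH) is a total of 6 or more.

The DNA criterion is excluded by default so the phenotypic definition stays
independent of the genetic analysis it is later compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .errors import ConfigError
from .records import ASCVD_CODES, FEMALE, MALE, ParticipantRecord

#: Age (strict upper bound) below which an ASCVD event counts as premature.
PREMATURE_AGE = {MALE: 55.0, FEMALE: 65.0}


def is_premature_ascvd(event_type: str, age_at_event: float, sex: str) -> bool:
    """True iff the ASCVD event occurred before 55 (males) / 65 (females), strict."""
    if event_type not in ASCVD_CODES:
        raise ConfigError(f"unknown ASCVD event type {event_type!r}; expected one of {sorted(ASCVD_CODES)}")
    if age_at_event < 0:
        raise ConfigError(f"age_at_event must be >= 0, got {age_at_event}")
    try:
        bound = PREMATURE_AGE[sex]
    except KeyError:
        raise ConfigError(f"unknown sex {sex!r}") from None
    return age_at_event < bound


@dataclass(frozen=True)
class LdlBand:
    lower: float  # inclusive
    points: int


class DLCNPointTable:
    """Configurable point values for each DLCN criterion group."""

    def __init__(
        self,
        family_history: Mapping[str, int],
        personal_history: Mapping[str, int],
        physical_exam: Mapping[str, int],
        ldl_bands: Sequence[Tuple[float, int]],
        dna_points: int,
    ):
        for group_name, group in (
            ("family_history", family_history),
            ("personal_history", personal_history),
            ("physical_exam", physical_exam),
        ):
            for cond, pts in group.items():
                if int(pts) < 0:
                    raise ConfigError(f"dlcn.{group_name}.{cond}: points must be >= 0, got {pts}")
        bands = sorted(((float(lo), int(p)) for lo, p in ldl_bands), reverse=True)
        if not bands:
            raise ConfigError("dlcn.ldl_bands must not be empty")
        self.family_history = dict(family_history)
        self.personal_history = dict(personal_history)
        self.physical_exam = dict(physical_exam)
        self.ldl_bands = tuple(LdlBand(lo, p) for lo, p in bands)
        self.dna_points = int(dna_points)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "DLCNPointTable":
        return cls(
            family_history=data["family_history"],
            personal_history=data["personal_history"],
            physical_exam=data["physical_exam"],
            ldl_bands=[(b["ldl_min"], b["points"]) for b in data["ldl_bands"]],
            dna_points=data["dna"]["causative_variant"],
        )

    def ldl_points(self, untreated_ldl: float) -> int:
        for band in self.ldl_bands:  # descending lower bounds
            if untreated_ldl >= band.lower:
                return band.points
        return 0


#: Default point values of the standard DLCN table.
DEFAULT_POINTS = DLCNPointTable(
    family_history={
        "premature_ascvd_relative": 1,
        "relative_ldl_gt95": 1,
        "relative_xanthomata_arcus": 2,
        "child_ldl_gt95": 2,
    },
    personal_history={
        "premature_chd": 2,
        "premature_cerebral_or_peripheral": 1,
    },
    physical_exam={
        "tendon_xanthomata": 6,
        "arcus_before_45": 4,
    },
    ldl_bands=[(330.0, 8), (250.0, 5), (190.0, 3), (155.0, 1)],
    dna_points=8,
)

CATEGORY_BOUNDS = ((3, "unlikely"), (6, "possible"), (9, "probable"))
CATEGORIES = ("unlikely", "possible", "probable", "definite")
PHENOTYPIC_FH_MIN = 6


def categorize(total: int) -> str:
    """Map a total DLCN score to its category (cut points 3, 6, 9)."""
    if total < 0:
        raise ConfigError(f"DLCN total must be >= 0, got {total}")
    for bound, name in CATEGORY_BOUNDS:
        if total < bound:
            return name
    return "definite"


@dataclass(frozen=True)
class DLCNInputs:
    """Criterion flags plus untreated LDL-C; the scorer's only inputs."""

    untreated_ldl: float
    fam_premature_ascvd: bool = False
    fam_relative_ldl_gt95: bool = False
    fam_relative_xanthomata_arcus: bool = False
    fam_child_ldl_gt95: bool = False
    premature_chd: bool = False
    premature_cerebral_or_peripheral: bool = False
    tendon_xanthomata: bool = False
    arcus_before_45: bool = False
    causative_variant: bool = False


@dataclass
class DLCNResult:
    group_points: Dict[str, int] = field(default_factory=dict)
    total: int = 0
    category: str = "unlikely"
    phenotypic_fh: bool = False


def derive_inputs(record: ParticipantRecord, untreated_ldl: float) -> DLCNInputs:
    """Lift a participant record into scorer inputs.

    Personal-history flags come from dated ASCVD diagnoses passed through the
    premature-ASCVD age rule; arcus counts only when noted before age 45.
    """
    premature_chd = False
    premature_cvd_pad = False
    for d in record.diagnoses:
        if d.code in ASCVD_CODES and is_premature_ascvd(d.code, d.age_at_event, record.sex):
            if d.code == "CHD":
                premature_chd = True
            else:
                premature_cvd_pad = True
    arcus_before_45 = bool(
        record.arcus_cornealis and record.arcus_age is not None and record.arcus_age < 45.0
    )
    return DLCNInputs(
        untreated_ldl=untreated_ldl,
        fam_premature_ascvd=record.fam_premature_ascvd,
        fam_relative_ldl_gt95=record.fam_relative_ldl_gt95,
        fam_relative_xanthomata_arcus=record.fam_relative_xanthomata_arcus,
        fam_child_ldl_gt95=record.fam_child_ldl_gt95,
        premature_chd=premature_chd,
        premature_cerebral_or_peripheral=premature_cvd_pad,
        tendon_xanthomata=record.tendon_xanthomata,
        arcus_before_45=arcus_before_45,
    )


def _group_max(conditions: Mapping[str, int], satisfied: Mapping[str, bool]) -> int:
    pts = [p for cond, p in conditions.items() if satisfied.get(cond, False)]
    return max(pts) if pts else 0


def score_dlcn(
    inputs: DLCNInputs,
    table: DLCNPointTable = DEFAULT_POINTS,
    include_dna: bool = False,
) -> DLCNResult:
    """Score one participant; only the top satisfied condition per group counts."""
    if inputs.untreated_ldl < 0:
        raise ConfigError(f"untreated LDL-C must be >= 0, got {inputs.untreated_ldl}")
    group_points = {
        "family_history": _group_max(
            table.family_history,
            {
                "premature_ascvd_relative": inputs.fam_premature_ascvd,
                "relative_ldl_gt95": inputs.fam_relative_ldl_gt95,
                "relative_xanthomata_arcus": inputs.fam_relative_xanthomata_arcus,
                "child_ldl_gt95": inputs.fam_child_ldl_gt95,
            },
        ),
        "personal_history": _group_max(
            table.personal_history,
            {
                "premature_chd": inputs.premature_chd,
                "premature_cerebral_or_peripheral": inputs.premature_cerebral_or_peripheral,
            },
        ),
        "physical_exam": _group_max(
            table.physical_exam,
            {
                "tendon_xanthomata": inputs.tendon_xanthomata,
                "arcus_before_45": inputs.arcus_before_45,
            },
        ),
        "ldl_level": table.ldl_points(inputs.untreated_ldl),
    }
    if include_dna:
        group_points["dna"] = table.dna_points if inputs.causative_variant else 0
    total = sum(group_points.values())
    return DLCNResult(
        group_points=group_points,
        total=total,
        category=categorize(total),
        phenotypic_fh=total >= PHENOTYPIC_FH_MIN,
    )
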