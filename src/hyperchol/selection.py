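"""Cohort inclusion/exclusion funnel.

A participant enters the analysis cohort when

* they consented and are alive,
* an index date exists (first LDL-C at or above the threshold),
* their age at index lies inside the configured bounds (inclusive), and
* no secondary cause of hypercholesterolemia (hypothyroidism, cholestatic
  liver disease, severe kidney disease, nephrotic syndrome, pregnancy) is
  dated within the symmetric window around the index date.

Exclusion reasons are attributed to the first failing rule in a fixed order
(consent -> no index -> age -> secondary cause) so funnel counts are
reproducible regardless of input ordering.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import ConfigError
from .records import ParticipantRecord, SECONDARY_CAUSE_CODES

EXCLUSION_ORDER = ("not_consented", "no_index_date", "age_out_of_range", "secondary_cause")


@dataclass(frozen=True)
class SelectionCriteria:
    age_min: float = 18.0
    age_max: float = 70.0
    ldl_threshold: float = 155.0  # mg/dl
    window_days: int = 365  # half-width of the secondary-cause window, inclusive
    secondary_causes: frozenset = SECONDARY_CAUSE_CODES

    def validate(self) -> None:
        if not self.age_min <= self.age_max:
            raise ConfigError(f"age_min ({self.age_min}) must not exceed age_max ({self.age_max})")
        if not self.ldl_threshold > 0:
            raise ConfigError(f"ldl_threshold must be > 0, got {self.ldl_threshold}")
        if self.window_days < 0:
            raise ConfigError(f"window_days must be >= 0, got {self.window_days}")


@dataclass
class SelectionResult:
    screened: int
    retained_ids: List[str]
    index_dates: Dict[str, dt.date]
    exclusions: Counter = field(default_factory=Counter)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def funnel(self) -> Dict[str, int]:
        out = {"screened": self.screened}
        for reason in EXCLUSION_ORDER:
            out[f"excluded_{reason}"] = self.exclusions.get(reason, 0)
        out["retained"] = self.n_retained
        return out


def find_index_date(record: ParticipantRecord, threshold: float = 155.0) -> Optional[dt.date]:
    """Earliest lipid-measure date with LDL-C >= threshold (inclusive), else None."""
    qualifying = [m.date for m in record.lipids if m.ldl >= threshold]
    return min(qualifying) if qualifying else None


def _secondary_cause_in_window(
    record: ParticipantRecord, index: dt.date, criteria: SelectionCriteria
) -> Optional[str]:
    for d in record.diagnoses:
        if d.code in criteria.secondary_causes:
            if abs((d.date - index).days) <= criteria.window_days:
                return d.code
    return None


def evaluate_participant(
    record: ParticipantRecord, criteria: SelectionCriteria
) -> Tuple[Optional[str], Optional[dt.date]]:
    """Return (exclusion_reason_or_None, index_date_or_None) for one record."""
    record.validate()
    if not record.consented:
        return "not_consented", None
    index = find_index_date(record, criteria.ldl_threshold)
    if index is None:
        return "no_index_date", None
    if not (criteria.age_min <= record.age <= criteria.age_max):
        return "age_out_of_range", index
    if _secondary_cause_in_window(record, index, criteria) is not None:
        return "secondary_cause", index
    return None, index


def apply_selection(
    records: Iterable[ParticipantRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionResult:
    criteria.validate()
    retained: List[str] = []
    index_dates: Dict[str, dt.date] = {}
    exclusions: Counter = Counter()
    screened = 0
    for rec in records:
        screened += 1
        reason, index = evaluate_participant(rec, criteria)
        if reason is None:
            retained.append(rec.participant_id)
            index_dates[rec.participant_id] = index
        else:
            exclusions[reason] += 1
    return SelectionResult(
        screened=screened,
        retained_ids=retained,
        index_dates=index_dates,
        exclusions=exclusions,
    )
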