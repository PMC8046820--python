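"""Lipid arithmetic: unit conversion, statin back-correction, percentile strata.

Statin therapy lowers LDL-C by an approximately fixed proportion *r* that
depends on drug and daily dose, so the untreated level is imputed
multiplicatively: ``untreated = observed / (1 - r)``.  The coefficient table
ships as configuration and is validated for monotonicity in dose.

The age/sex LDL-C percentile reference shipped with the package is a
synthetic, Gaussian-derived table for testing the strata machinery; it is not
a clinical reference and is meant to be replaced by a population table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .errors import ConfigError, UnknownStatinError
from .records import StatinExposure

#: 1 mmol/l of LDL cholesterol in mg/dl.
MG_PER_MMOL = 38.67

_UNITS = ("mg/dl", "mmol/l")


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert LDL-C between mg/dl and mmol/l (exact inverse both ways)."""
    if from_unit not in _UNITS:
        raise ConfigError(f"unknown unit {from_unit!r}; expected one of {_UNITS}")
    if to_unit not in _UNITS:
        raise ConfigError(f"unknown unit {to_unit!r}; expected one of {_UNITS}")
    if from_unit == to_unit:
        return value
    if from_unit == "mmol/l":
        return value * MG_PER_MMOL
    return value / MG_PER_MMOL


class StatinCoefficientTable:
    """Map (statin type, daily dose in mg) -> proportional LDL-C reduction."""

    def __init__(self, table: Mapping[str, Mapping[float, float]]):
        self._table: Dict[str, Dict[float, float]] = {}
        for statin, doses in table.items():
            entries = dict(sorted((float(d), float(r)) for d, r in doses.items()))
            prev = -1.0
            for dose, r in entries.items():
                if not (0.0 <= r < 1.0):
                    raise ConfigError(
                        f"statin_coefficients[{statin}][{dose:g}]: reduction must be in [0, 1), got {r}"
                    )
                if r < prev:
                    raise ConfigError(
                        f"statin_coefficients[{statin}]: reductions must be non-decreasing in dose"
                    )
                prev = r
            self._table[statin] = entries

    def reduction(self, statin_type: str, dose_mg: float) -> float:
        try:
            return self._table[statin_type][float(dose_mg)]
        except KeyError:
            known = {s: sorted(d) for s, d in self._table.items()}
            raise UnknownStatinError(
                f"no coefficient for {statin_type!r} at {dose_mg} mg; known entries: {known}"
            ) from None

    def items(self):
        for statin, doses in self._table.items():
            for dose, r in doses.items():
                yield statin, dose, r


def impute_untreated_ldl(
    observed: float,
    statin: Optional[StatinExposure],
    table: StatinCoefficientTable,
) -> float:
    """Back-correct an on-treatment LDL-C; identity for untreated subjects.

    Only statins active at the measurement (``active_on_index``) are
    corrected for.
    """
    if not observed > 0:
        raise ConfigError(f"observed LDL-C must be > 0, got {observed}")
    if statin is None or not statin.active_on_index:
        return observed
    r = table.reduction(statin.statin_type, statin.dose_mg)
    return observed / (1.0 - r)


@dataclass(frozen=True)
class PercentileBand:
    sex: str
    age_min: float
    age_max: float  # inclusive
    p95: float
    p99: float


class PercentileReference:
    """Sex- and age-band-specific LDL-C cut points (95th and 99th percentile)."""

    def __init__(self, bands: Sequence[PercentileBand]):
        for b in bands:
            if not (b.p95 > 0 and b.p99 > b.p95):
                raise ConfigError(
                    f"percentile band ({b.sex}, {b.age_min}-{b.age_max}): "
                    f"need 0 < p95 < p99, got p95={b.p95}, p99={b.p99}"
                )
        self._bands = tuple(bands)

    @classmethod
    def from_rows(cls, rows: Sequence[Mapping]) -> "PercentileReference":
        return cls(
            [
                PercentileBand(
                    sex=r["sex"],
                    age_min=float(r["age_min"]),
                    age_max=float(r["age_max"]),
                    p95=float(r["p95"]),
                    p99=float(r["p99"]),
                )
                for r in rows
            ]
        )

    def cut_points(self, sex: str, age: float) -> Tuple[float, float]:
        """Bands are half-open [age_min, age_max); the sex's last band includes its upper edge."""
        last = None
        for b in self._bands:
            if b.sex != sex:
                continue
            if b.age_min <= age < b.age_max:
                return b.p95, b.p99
            if last is None or b.age_max > last.age_max:
                last = b
        if last is not None and age == last.age_max:
            return last.p95, last.p99
        raise ConfigError(f"no percentile reference band covers sex={sex!r}, age={age}")


def assign_percentile_strata(
    untreated_ldl: float, age: float, sex: str, reference: PercentileReference
) -> Tuple[bool, bool]:
    """Flags (>=95th percentile, >=99th percentile); inclusive comparisons.

    The table invariant p99 > p95 makes the flags nested: >=99th implies >=95th.
    """
    p95, p99 = reference.cut_points(sex, age)
    ge95 = untreated_ldl >= p95
    ge99 = untreated_ldl >= p99
    return ge95 or ge99, ge99
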