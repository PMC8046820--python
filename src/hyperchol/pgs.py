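"""12-SNV weighted polygenic score (PGS) for LDL-C.

The raw score is the weighted sum of effect-allele dosages,
``raw = sum_j w_j d_j`` with weights in mmol/l per allele, all oriented to the
LDL-raising allele (hence positive).  Polygenic etiology is a raw score at or
above the reference 90th-percentile cutoff (1.16) in a participant without a
monogenic finding — monogenic takes precedence.

Missing dosages are imputed as twice the effect-allele frequency by default
(the Hardy-Weinberg expectation); a strict policy rejects them instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError

DEFAULT_PGS_THRESHOLD = 1.16


@dataclass(frozen=True)
class SNVEntry:
    snv_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # effect-allele frequency
    weight: float  # mmol/l per effect allele


class SNVPanel:
    """Ordered SNV panel; the default configuration carries 12 entries."""

    def __init__(self, entries: Sequence[SNVEntry], expected_size: Optional[int] = None):
        ids = [e.snv_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("snv_panel: identifiers must be unique")
        if expected_size is not None and len(entries) != expected_size:
            raise ConfigError(
                f"snv_panel: expected {expected_size} entries, got {len(entries)}"
            )
        for e in entries:
            if not (math.isfinite(e.weight) and e.weight > 0):
                raise ConfigError(f"snv_panel[{e.snv_id}]: weight must be finite and > 0")
            if not (0.0 < e.eaf < 1.0):
                raise ConfigError(f"snv_panel[{e.snv_id}]: eaf must be in (0, 1), got {e.eaf}")
        self.entries = tuple(entries)
        self._by_id = {e.snv_id: e for e in entries}

    @classmethod
    def from_rows(cls, rows: Sequence[Mapping], expected_size: Optional[int] = None) -> "SNVPanel":
        return cls(
            [
                SNVEntry(
                    snv_id=r["id"],
                    chrom=str(r["chrom"]),
                    pos=int(r["pos"]),
                    effect_allele=r["effect_allele"],
                    other_allele=r["other_allele"],
                    eaf=float(r["eaf"]),
                    weight=float(r["weight"]),
                )
                for r in rows
            ],
            expected_size=expected_size,
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, snv_id: str) -> SNVEntry:
        try:
            return self._by_id[snv_id]
        except KeyError:
            raise ConfigError(f"unknown SNV identifier {snv_id!r}") from None

    def __contains__(self, snv_id: str) -> bool:
        return snv_id in self._by_id

    @property
    def ids(self):
        return tuple(e.snv_id for e in self.entries)

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.eaf for e in self.entries])

    def max_score(self) -> float:
        return 2.0 * float(self.weights.sum())

    def analytic_mean(self) -> float:
        """Population mean of the raw score under Hardy-Weinberg: sum 2 p_j w_j."""
        return float(np.sum(2 * self.frequencies * self.weights))

    def analytic_variance(self) -> float:
        """Population variance under Hardy-Weinberg: sum 2 p_j (1-p_j) w_j^2."""
        p, w = self.frequencies, self.weights
        return float(np.sum(2 * p * (1 - p) * w**2))


@dataclass
class PGSResult:
    raw: float
    percentile: Optional[float] = None
    polygenic: bool = False


def compute_pgs(
    dosages: Mapping[str, Optional[int]],
    panel: SNVPanel,
    missing_policy: str = "impute",
) -> float:
    """Raw weighted-sum score for one participant.

    *dosages* maps SNV identifier to effect-allele count in {0, 1, 2}; ``None``
    (or an absent panel key) marks a missing genotype.  Under the default
    policy a missing dosage is replaced by ``2 * eaf``; the strict policy
    rejects any missingness.  More than 50% missing is always rejected.
    """
    if missing_policy not in ("impute", "strict"):
        raise ConfigError(f"missing_policy must be 'impute' or 'strict', got {missing_policy!r}")
    for snv_id in dosages:
        if snv_id not in panel:
            raise ConfigError(f"unknown SNV identifier {snv_id!r} in dosage vector")
    raw = 0.0
    n_missing = 0
    for entry in panel.entries:
        d = dosages.get(entry.snv_id)
        if d is None:
            if missing_policy == "strict":
                raise ConfigError(f"missing dosage at {entry.snv_id} under strict policy")
            n_missing += 1
            raw += entry.weight * 2.0 * entry.eaf
        else:
            if d not in (0, 1, 2):
                raise ConfigError(f"dosage at {entry.snv_id} must be in {{0,1,2}}, got {d}")
            raw += entry.weight * d
    if n_missing * 2 > len(panel):
        raise ConfigError(
            f"{n_missing}/{len(panel)} dosages missing; more than 50% cannot be imputed"
        )
    return raw


def classify_polygenic(
    raw: float, threshold: float = DEFAULT_PGS_THRESHOLD, monogenic: bool = False
) -> bool:
    """Polygenic flag: raw >= threshold (inclusive) and no monogenic finding."""
    if not math.isfinite(threshold):
        raise ConfigError(f"PGS threshold must be finite, got {threshold}")
    return (not monogenic) and raw >= threshold


def reference_percentile(raw: float, reference: Sequence[float]) -> float:
    """Percentile of *raw* against an empirical reference distribution.

    Defined as 100 x (proportion of reference values strictly below raw);
    monotone non-decreasing in raw.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ConfigError("reference distribution must be non-empty")
    return 100.0 * float(np.count_nonzero(ref < raw)) / ref.size
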