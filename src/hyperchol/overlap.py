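"""Final etiology calls, genotype-phenotype overlap tables, and group statistics.

Etiology is a three-way partition: monogenic (P/LP carrier, takes precedence),
polygenic (PGS at/above the reference 90th-percentile cutoff in a non-carrier),
or none.  The overlap summary reports every percentage with its explicit
numerator and denominator; the polygenic marginal uses the full cohort as
denominator.  Percentages are rounded half-up to one decimal through the
shared routine in :mod:`hyperchol.rounding`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ConfigError
from .rounding import percentage

ETIOLOGIES = ("monogenic", "polygenic", "none")


@dataclass(frozen=True)
class EtiologyCall:
    participant_id: str
    etiology: str
    dlcn_category: str
    phenotypic_fh: bool
    untreated_ldl: float
    ge190: bool = False
    ge250: bool = False
    ge95th: bool = False
    ge99th: bool = False
    plp_genes: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.etiology not in ETIOLOGIES:
            raise ConfigError(f"etiology must be one of {ETIOLOGIES}, got {self.etiology!r}")


def classify_etiology(monogenic: bool, polygenic: bool) -> str:
    """Monogenic takes precedence; then polygenic; else none."""
    if monogenic:
        return "monogenic"
    if polygenic:
        return "polygenic"
    return "none"


@dataclass(frozen=True)
class Pct:
    """A reported percentage with its audit trail."""

    numerator: int
    denominator: int
    value: Optional[float]  # None marks an undefined (empty-denominator) cell

    @classmethod
    def of(cls, numerator: int, denominator: int) -> "Pct":
        return cls(numerator, denominator, percentage(numerator, denominator))


@dataclass
class CohortSummary:
    counts: Dict[str, int] = field(default_factory=dict)
    percentages: Dict[str, Pct] = field(default_factory=dict)
    notes: Dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "percentages": {
                k: {"numerator": p.numerator, "denominator": p.denominator, "value": p.value}
                for k, p in self.percentages.items()
            },
            "notes": dict(self.notes),
        }


def crosstab_overlap(calls: Sequence[EtiologyCall]) -> CohortSummary:
    """All cohort-level overlap counts and percentages.

    Emits marginals over the full cohort, conditionals within phenotypic FH,
    within each etiology, and within each LDL stratum.  A composite
    "genetic within FH" figure is reported both directly and as the sum of
    its rounded monogenic/polygenic components, which can disagree in the
    last decimal; the note records both.
    """
    if not calls:
        raise ConfigError("crosstab_overlap requires a non-empty cohort")
    n = len(calls)
    mono = [c for c in calls if c.etiology == "monogenic"]
    poly = [c for c in calls if c.etiology == "polygenic"]
    genetic = mono + poly
    fh = [c for c in calls if c.phenotypic_fh]
    mono_fh = [c for c in mono if c.phenotypic_fh]
    poly_fh = [c for c in poly if c.phenotypic_fh]
    ge190 = [c for c in calls if c.ge190]
    ge250 = [c for c in calls if c.ge250]
    ge95 = [c for c in calls if c.ge95th]
    ge99 = [c for c in calls if c.ge99th]
    ldlr = [c for c in mono if "LDLR" in c.plp_genes]
    apob = [c for c in mono if "APOB" in c.plp_genes]
    pcsk9 = [c for c in mono if "PCSK9" in c.plp_genes]

    counts = {
        "total": n,
        "monogenic": len(mono),
        "polygenic": len(poly),
        "genetic": len(genetic),
        "phenotypic_fh": len(fh),
        "monogenic_fh": len(mono_fh),
        "polygenic_fh": len(poly_fh),
        "genetic_fh": len(mono_fh) + len(poly_fh),
        "ldl_ge190": len(ge190),
        "ldl_ge250": len(ge250),
        "ldl_ge_p95": len(ge95),
        "ldl_ge_p99": len(ge99),
        "monogenic_ldlr": len(ldlr),
        "monogenic_apob": len(apob),
        "monogenic_pcsk9": len(pcsk9),
        "dlcn_unlikely": sum(c.dlcn_category == "unlikely" for c in calls),
        "dlcn_possible": sum(c.dlcn_category == "possible" for c in calls),
        "dlcn_probable_definite": sum(
            c.dlcn_category in ("probable", "definite") for c in calls
        ),
    }

    def stratum_mono(stratum: List[EtiologyCall]) -> int:
        return sum(c.etiology == "monogenic" for c in stratum)

    pcts = {
        # marginals over the full cohort
        "monogenic_of_cohort": Pct.of(len(mono), n),
        "polygenic_of_cohort": Pct.of(len(poly), n),
        "genetic_of_cohort": Pct.of(len(genetic), n),
        "phenotypic_fh_of_cohort": Pct.of(len(fh), n),
        # conditionals within phenotypic FH
        "monogenic_of_fh": Pct.of(len(mono_fh), len(fh)),
        "polygenic_of_fh": Pct.of(len(poly_fh), len(fh)),
        "genetic_of_fh": Pct.of(len(mono_fh) + len(poly_fh), len(fh)),
        # conditionals within each etiology
        "fh_of_genetic": Pct.of(len(mono_fh) + len(poly_fh), len(genetic)),
        "fh_of_monogenic": Pct.of(len(mono_fh), len(mono)),
        "fh_of_polygenic": Pct.of(len(poly_fh), len(poly)),
        # monogenic yield within LDL strata
        "monogenic_of_ldl_ge190": Pct.of(stratum_mono(ge190), len(ge190)),
        "monogenic_of_ldl_ge250": Pct.of(stratum_mono(ge250), len(ge250)),
        "monogenic_of_ldl_ge_p95": Pct.of(stratum_mono(ge95), len(ge95)),
        "monogenic_of_ldl_ge_p99": Pct.of(stratum_mono(ge99), len(ge99)),
        # gene split among monogenic
        "ldlr_of_monogenic": Pct.of(len(ldlr), len(mono)),
        "apob_of_monogenic": Pct.of(len(apob), len(mono)),
        "pcsk9_of_monogenic": Pct.of(len(pcsk9), len(mono)),
    }

    summary = CohortSummary(counts=counts, percentages=pcts)
    direct = pcts["genetic_of_fh"].value
    m, p = pcts["monogenic_of_fh"].value, pcts["polygenic_of_fh"].value
    if m is not None and p is not None:
        component_sum = round(m + p, 1)
        summary.counts["genetic_of_fh_component_sum_x10"] = int(round(component_sum * 10))
        summary.notes["genetic_of_fh"] = (
            f"direct rounding {direct}; sum of rounded components {component_sum}"
        )
    return summary


def group_compare(groups: Mapping[str, Sequence[float]], kind: str):
    """Two-sided group comparison: Welch t (two groups), one-way ANOVA, or chi-square.

    For ``kind='chi2'`` the mapping values are category counts (a contingency
    table row per group).  Returns (statistic, p_value, significant_at_0.05).
    """
    names = list(groups)
    if len(names) < 2:
        raise ConfigError("group_compare requires at least two groups")
    if kind == "chi2":
        table = np.array([np.asarray(groups[g], dtype=float) for g in names])
        if table.min() < 0:
            raise ConfigError("chi-square requires non-negative counts")
        stat, p, _, _ = stats.chi2_contingency(table)
    elif kind in ("ttest", "anova"):
        arrays = [np.asarray(groups[g], dtype=float) for g in names]
        for g, a in zip(names, arrays):
            if a.size < 2:
                raise ConfigError(f"group {g!r} has fewer than 2 observations")
        if all(np.allclose(a.var(), 0.0) for a in arrays) and kind == "anova":
            raise ConfigError("all groups have zero variance")
        if kind == "ttest":
            if len(arrays) != 2:
                raise ConfigError("t-test requires exactly two groups")
            stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        else:
            stat, p = stats.f_oneway(*arrays)
    else:
        raise ConfigError(f"unknown comparison kind {kind!r}")
    return float(stat), float(p), bool(p < 0.05)


SIGNIFICANCE_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


def significance_stars(p: float) -> str:
    return "*" * sum(p < t for t in SIGNIFICANCE_THRESHOLDS) or "ns"


@dataclass
class VarianceDecomposition:
    r2_genetic: float
    r2_clinical: float
    n: int
    coefficients_genetic: pd.DataFrame
    coefficients_clinical: pd.DataFrame


def _ols_r2(y: np.ndarray, X: pd.DataFrame) -> Tuple[float, pd.DataFrame]:
    import statsmodels.api as sm

    exog = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(exog.values)
    if rank < exog.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {exog.shape[1]} columns); "
            "collinear or constant predictors must be resolved, not dropped silently"
        )
    fit = sm.OLS(y, exog).fit()
    coefs = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p_value": fit.pvalues}
    )
    return float(fit.rsquared), coefs


def variance_explained(
    table: pd.DataFrame,
    ldl_col: str = "untreated_ldl",
    genetic_cols: Sequence[str] = ("pgs_raw", "monogenic"),
    clinical_cols: Sequence[str] = ("age", "male", "white", "bmi", "diabetes", "fam_hypercholesterolemia"),
) -> VarianceDecomposition:
    """R-squared of the genetic and the clinical linear model, fit separately.

    The genetic model regresses untreated LDL-C on the raw PGS and a monogenic
    indicator; the clinical model on demographics and history.  Two separate
    ordinary-least-squares fits, matching the convention of reporting each
    block's own variance explained.
    """
    needed = {ldl_col, *genetic_cols, *clinical_cols}
    missing = needed - set(table.columns)
    if missing:
        raise ConfigError(f"variance_explained: missing columns {sorted(missing)}")
    df = table.dropna(subset=sorted(needed))
    n = len(df)
    if n <= max(len(genetic_cols), len(clinical_cols)) + 1:
        raise ConfigError(f"too few rows ({n}) for the requested predictors")
    y = df[ldl_col].to_numpy(dtype=float)
    r2_g, coef_g = _ols_r2(y, df[list(genetic_cols)])
    r2_c, coef_c = _ols_r2(y, df[list(clinical_cols)])
    return VarianceDecomposition(
        r2_genetic=r2_g,
        r2_clinical=r2_c,
        n=n,
        coefficients_genetic=coef_g,
        coefficients_clinical=coef_c,
    )
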