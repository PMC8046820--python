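"""Synthetic genotype-phenotype cohorts.

Two construction paths:

* :func:`generate_population` draws a stochastic screening population with the
  statistical structure the analysis assumes — Hardy-Weinberg panel genotypes,
  an additive LDL-C model (baseline by age/sex + polygenic score contribution
  + a large shift in rare pathogenic-variant carriers + right-skewed residual),
  statin exposure that lowers the *observed* LDL-C multiplicatively, and
  configurable prevalences for secondary causes, history flags and signs.

* :func:`fixture_from_counts` builds a deterministic cohort whose journey
  through the real classifiers reproduces a requested table of marginal and
  joint counts exactly (attribute values at stratum midpoints, minimal flag
  sets, genuine P/LP variants for monogenic subjects) — no label pass-through.

Truth labels (monogenic / polygenic-tail / neither) partition every cohort and
record the noise-free genetic LDL-C component for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .acmg import AnnotatedVariant
from .errors import ConfigError, FixtureError
from .lipids import PercentileBand, PercentileReference, StatinCoefficientTable
from .records import (
    Diagnosis,
    FEMALE,
    LipidMeasure,
    MALE,
    ParticipantRecord,
    StatinExposure,
)

_BASE_DATE = dt.date(2015, 1, 1)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PanelSNV:
    snv_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    weight: float


@dataclass(frozen=True)
class CatalogueEntry:
    variant: AnnotatedVariant
    truth_plp: bool
    carrier_share: float = 0.0  # share of plp_carrier_rate (causal variants)
    carrier_rate: float = 0.0  # independent rate (non-causal variants)


def _require_prob(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")
    return value


def _require_finite(value: float, name: str, positive: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ConfigError(f"{name} must be finite, got {value}")
    if positive and value <= 0:
        raise ConfigError(f"{name} must be > 0, got {value}")
    return value


@dataclass
class GeneratorConfig:
    """Validated generator settings; see data/generator.yaml for defaults."""

    n_population: int
    seed: int
    snv_panel: Tuple[PanelSNV, ...]
    plp_carrier_rate: float
    monogenic_shift_mean: float
    monogenic_shift_sd: float
    ldl_intercept: float
    ldl_age_slope: float
    ldl_age_center: float
    ldl_male_offset: float
    pgs_to_ldl_scale: float
    residual_sd: float
    residual_log_skew: float
    pgs_threshold: float
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    male_fraction: float
    white_fraction: float
    bmi_mean: float
    bmi_sd: float
    bmi_min: float
    bmi_max: float
    statin_rate_high: float
    statin_high_threshold: float
    statin_rate_low: float
    statin_mix: Tuple[Tuple[str, float, float], ...]  # (type, dose, share)
    secondary_causes: Dict[str, float]
    personal_ascvd_rate: float
    family_history: Dict[str, float]
    physical_signs: Dict[str, float]
    comorbidities: Dict[str, float]
    variant_catalogue: Tuple[CatalogueEntry, ...]

    @classmethod
    def from_mapping(cls, data: Mapping) -> "GeneratorConfig":
        n = int(data["n_population"])
        if n < 1:
            raise ConfigError(f"n_population must be >= 1, got {n}")
        panel = []
        for row in data["snv_panel"]:
            eaf = _require_prob(row["eaf"], f"snv_panel[{row['id']}].eaf")
            weight = _require_finite(row["weight"], f"snv_panel[{row['id']}].weight", positive=True)
            panel.append(
                PanelSNV(
                    snv_id=row["id"],
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    effect_allele=row["effect_allele"],
                    other_allele=row["other_allele"],
                    eaf=eaf,
                    weight=weight,
                )
            )
        catalogue = []
        for row in data.get("variant_catalogue", []):
            variant = AnnotatedVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                consequence=row["consequence"],
                ref_af=None if row.get("ref_af") is None else float(row["ref_af"]),
                clinvar=row.get("clinvar"),
                pred_verdict=row.get("pred_verdict"),
                supplied_tags=tuple(row.get("supplied_tags") or ()),
                variant_id=row["id"],
            )
            variant.validate()
            catalogue.append(
                CatalogueEntry(
                    variant=variant,
                    truth_plp=bool(row.get("truth_plp", False)),
                    carrier_share=_require_prob(
                        row.get("carrier_share", 0.0), f"variant_catalogue[{row['id']}].carrier_share"
                    ),
                    carrier_rate=_require_prob(
                        row.get("carrier_rate", 0.0), f"variant_catalogue[{row['id']}].carrier_rate"
                    ),
                )
            )
        shares = [e.carrier_share for e in catalogue if e.truth_plp]
        if shares and abs(sum(shares) - 1.0) > 1e-9:
            raise ConfigError(
                f"variant_catalogue: carrier_share of causal variants must sum to 1, got {sum(shares)}"
            )
        statin = data["statin"]
        mix = tuple(
            (m["type"], float(m["dose"]), _require_prob(m["share"], "statin.mix.share"))
            for m in statin["mix"]
        )
        if abs(sum(s for _, _, s in mix) - 1.0) > 1e-9:
            raise ConfigError("statin.mix shares must sum to 1")
        age = data["age"]
        bmi = data["bmi"]
        base = data["ldl_baseline"]
        return cls(
            n_population=n,
            seed=int(data["seed"]),
            snv_panel=tuple(panel),
            plp_carrier_rate=_require_prob(data["plp_carrier_rate"], "plp_carrier_rate"),
            monogenic_shift_mean=_require_finite(data["monogenic_shift_mean"], "monogenic_shift_mean"),
            monogenic_shift_sd=_require_finite(data["monogenic_shift_sd"], "monogenic_shift_sd"),
            ldl_intercept=_require_finite(base["intercept"], "ldl_baseline.intercept"),
            ldl_age_slope=_require_finite(base["age_slope"], "ldl_baseline.age_slope"),
            ldl_age_center=_require_finite(base["age_center"], "ldl_baseline.age_center"),
            ldl_male_offset=_require_finite(base["male_offset"], "ldl_baseline.male_offset"),
            pgs_to_ldl_scale=_require_finite(data["pgs_to_ldl_scale"], "pgs_to_ldl_scale"),
            residual_sd=_require_finite(data["residual_sd"], "residual_sd", positive=True),
            residual_log_skew=_require_finite(data["residual_log_skew"], "residual_log_skew"),
            pgs_threshold=_require_finite(data["pgs_threshold"], "pgs_threshold"),
            age_mean=_require_finite(age["mean"], "age.mean"),
            age_sd=_require_finite(age["sd"], "age.sd", positive=True),
            age_min=_require_finite(age["min"], "age.min"),
            age_max=_require_finite(age["max"], "age.max"),
            male_fraction=_require_prob(data["male_fraction"], "male_fraction"),
            white_fraction=_require_prob(data.get("white_fraction", 1.0), "white_fraction"),
            bmi_mean=_require_finite(bmi["mean"], "bmi.mean"),
            bmi_sd=_require_finite(bmi["sd"], "bmi.sd", positive=True),
            bmi_min=_require_finite(bmi["min"], "bmi.min"),
            bmi_max=_require_finite(bmi["max"], "bmi.max"),
            statin_rate_high=_require_prob(statin["rate_high_ldl"], "statin.rate_high_ldl"),
            statin_high_threshold=_require_finite(statin["high_ldl_threshold"], "statin.high_ldl_threshold"),
            statin_rate_low=_require_prob(statin["rate_low_ldl"], "statin.rate_low_ldl"),
            statin_mix=mix,
            secondary_causes={
                k: _require_prob(v, f"secondary_causes.{k}") for k, v in data["secondary_causes"].items()
            },
            personal_ascvd_rate=_require_prob(data["personal_ascvd_rate"], "personal_ascvd_rate"),
            family_history={
                k: _require_prob(v, f"family_history.{k}") for k, v in data["family_history"].items()
            },
            physical_signs={
                k: _require_prob(v, f"physical_signs.{k}") for k, v in data["physical_signs"].items()
            },
            comorbidities={
                k: _require_prob(v, f"comorbidities.{k}") for k, v in data["comorbidities"].items()
            },
            variant_catalogue=tuple(catalogue),
        )

    @classmethod
    def default(cls, n_population: Optional[int] = None, seed: Optional[int] = None) -> "GeneratorConfig":
        from .config import load_default_generator_mapping

        data = dict(load_default_generator_mapping())
        if n_population is not None:
            data["n_population"] = n_population
        if seed is not None:
            data["seed"] = seed
        return cls.from_mapping(data)

    # -- analytic moments (closed forms used by calibration tests) ----------

    def pgs_analytic_mean(self) -> float:
        return sum(2 * s.eaf * s.weight for s in self.snv_panel)

    def pgs_analytic_variance(self) -> float:
        return sum(2 * s.eaf * (1 - s.eaf) * s.weight**2 for s in self.snv_panel)

    def genetic_variance_fraction(self) -> float:
        """Configured share of untreated-LDL variance due to genetic factors.

        Genetic variance = (pgs scale)^2 * Var(PGS) + carrier-shift variance;
        non-genetic variance = age/sex baseline terms + residual.  Age variance
        uses the truncated-normal closed form for the clipped age draw.
        """
        from scipy import stats

        k = self.plp_carrier_rate
        var_shift = (self.monogenic_shift_mean**2) * k * (1 - k) + (self.monogenic_shift_sd**2) * k
        var_g = (self.pgs_to_ldl_scale**2) * self.pgs_analytic_variance() + var_shift
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        var_age = stats.truncnorm.var(a, b, loc=self.age_mean, scale=self.age_sd)
        var_clin = (self.ldl_age_slope**2) * var_age + (
            self.ldl_male_offset**2
        ) * self.male_fraction * (1 - self.male_fraction)
        var_total = var_g + var_clin + self.residual_sd**2
        return var_g / var_total


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SyntheticCohort:
    participants: List[ParticipantRecord]
    genotypes: pd.DataFrame  # index participant id, columns SNV id, dosage in {0,1,2}
    rare_carriage: Dict[str, Dict[str, int]]
    variants: List[AnnotatedVariant]
    truth: pd.DataFrame  # index participant id
    percentile_reference: Optional[PercentileReference] = None

    def __post_init__(self):
        ids = {p.participant_id for p in self.participants}
        known_variants = {v.key for v in self.variants}
        for pid, carriage in self.rare_carriage.items():
            if pid not in ids:
                raise ConfigError(f"rare carriage references unknown participant {pid!r}")
            for key in carriage:
                if key not in known_variants:
                    raise ConfigError(f"carried variant {key!r} has no variant record")
        dosages = self.genotypes.to_numpy()
        if dosages.size and not np.isin(dosages, (0, 1, 2)).all():
            raise ConfigError("panel dosages must be in {0, 1, 2}")

    @property
    def n(self) -> int:
        return len(self.participants)


# ---------------------------------------------------------------------------
# stochastic generator


def generate_population(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a synthetic screening population under the configured model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_population
    k_snv = len(config.snv_panel)
    p = np.array([s.eaf for s in config.snv_panel])
    w = np.array([s.weight for s in config.snv_panel])

    dosages = rng.binomial(2, np.broadcast_to(p, (n, k_snv)))
    pgs_raw = dosages @ w

    age = np.round(np.clip(rng.normal(config.age_mean, config.age_sd, n), config.age_min, config.age_max), 1)
    male = rng.random(n) < config.male_fraction
    white = rng.random(n) < config.white_fraction
    bmi = np.round(np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), config.bmi_min, config.bmi_max), 1)

    causal = [e for e in config.variant_catalogue if e.truth_plp]
    carrier = rng.random(n) < config.plp_carrier_rate
    if causal:
        shares = np.array([e.carrier_share for e in causal])
        which = rng.choice(len(causal), size=n, p=shares / shares.sum())
    else:
        carrier = np.zeros(n, dtype=bool)
        which = np.zeros(n, dtype=int)
    shift = np.where(
        carrier, rng.normal(config.monogenic_shift_mean, config.monogenic_shift_sd, n), 0.0
    )

    s = config.residual_log_skew
    if s > 0:
        m1 = math.exp(s**2 / 2)
        sv = math.sqrt((math.exp(s**2) - 1) * math.exp(s**2))
        z = (rng.lognormal(0.0, s, n) - m1) / sv
    else:
        z = rng.normal(0.0, 1.0, n)
    untreated = (
        config.ldl_intercept
        + config.ldl_age_slope * (age - config.ldl_age_center)
        + config.ldl_male_offset * male
        + config.pgs_to_ldl_scale * pgs_raw
        + shift
        + config.residual_sd * z
    )
    untreated = np.round(np.clip(untreated, 40.0, None), 2)
    genetic_component = config.pgs_to_ldl_scale * pgs_raw + shift

    p_statin = np.where(
        untreated >= config.statin_high_threshold, config.statin_rate_high, config.statin_rate_low
    )
    on_statin = rng.random(n) < p_statin
    mix_shares = np.array([m[2] for m in config.statin_mix])
    mix_idx = rng.choice(len(config.statin_mix), size=n, p=mix_shares / mix_shares.sum())

    from .config import load_default_statin_table

    statin_table = load_default_statin_table()
    reductions = np.array(
        [statin_table.reduction(t, d) for t, d, _ in config.statin_mix]
    )
    observed = np.where(on_statin, np.round(untreated * (1 - reductions[mix_idx]), 2), untreated)

    index_offset = rng.integers(0, 1461, n)
    has_prior = rng.random(n) < 0.5
    prior_delta = rng.integers(200, 601, n)
    trig = np.round(np.clip(rng.normal(155.0, 68.0, n), 40.0, 600.0), 1)
    hdl = np.round(np.clip(rng.normal(55.0, 15.0, n), 20.0, 120.0), 1)

    sec_draw = {
        cause: rng.random(n) < rate for cause, rate in sorted(config.secondary_causes.items())
    }
    sec_offset = {
        cause: rng.integers(-900, 901, n) for cause in sorted(config.secondary_causes)
    }
    has_ascvd = rng.random(n) < config.personal_ascvd_rate
    ascvd_type = rng.choice(["CHD", "cerebrovascular", "peripheral_artery"], size=n)
    ascvd_age_frac = rng.uniform(0.5, 0.95, n)

    fam = {
        flag: rng.random(n) < rate for flag, rate in sorted(config.family_history.items())
    }
    tendon = rng.random(n) < config.physical_signs.get("tendon_xanthomata", 0.0)
    arcus = rng.random(n) < config.physical_signs.get("arcus_before_45", 0.0)
    arcus_age = np.round(rng.uniform(30.0, 44.9, n), 1)
    diabetes = rng.random(n) < config.comorbidities.get("diabetes", 0.0)
    hypertension = rng.random(n) < config.comorbidities.get("hypertension", 0.0)

    noncausal = [e for e in config.variant_catalogue if not e.truth_plp]
    noncausal_carriers = {
        e.variant.key: rng.random(n) < e.carrier_rate for e in noncausal
    }

    width = max(6, len(str(n)))
    pids = [f"S{i:0{width}d}" for i in range(1, n + 1)]

    participants: List[ParticipantRecord] = []
    rare_carriage: Dict[str, Dict[str, int]] = {}
    etiology_truth = []
    plp_variant_col = []
    plp_gene_col = []
    for i, pid in enumerate(pids):
        d0 = _BASE_DATE + dt.timedelta(days=int(index_offset[i]))
        lipids = []
        if has_prior[i]:
            prior_ldl = round(float(observed[i]) * 0.8, 2)
            if prior_ldl > 0:
                lipids.append(
                    LipidMeasure(d0 - dt.timedelta(days=int(prior_delta[i])), prior_ldl, float(trig[i]), float(hdl[i]))
                )
        lipids.append(LipidMeasure(d0, float(observed[i]), float(trig[i]), float(hdl[i])))
        diagnoses = []
        for cause in sorted(config.secondary_causes):
            if sec_draw[cause][i] and (cause != "pregnancy" or not male[i]):
                diagnoses.append(
                    Diagnosis(d0 + dt.timedelta(days=int(sec_offset[cause][i])), cause, float(age[i]))
                )
        if has_ascvd[i]:
            event_age = round(float(age[i]) * float(ascvd_age_frac[i]), 1)
            diagnoses.append(
                Diagnosis(d0 - dt.timedelta(days=365), str(ascvd_type[i]), event_age)
            )
        statin = (
            StatinExposure(
                statin_type=config.statin_mix[mix_idx[i]][0],
                dose_mg=config.statin_mix[mix_idx[i]][1],
                active_on_index=True,
            )
            if on_statin[i]
            else None
        )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=float(age[i]),
                sex=MALE if male[i] else FEMALE,
                race="white" if white[i] else "other",
                bmi=float(bmi[i]),
                lipids=tuple(lipids),
                diagnoses=tuple(diagnoses),
                statin=statin,
                fam_premature_ascvd=bool(fam["premature_ascvd_relative"][i]),
                fam_relative_ldl_gt95=bool(fam["relative_ldl_gt95"][i]),
                fam_relative_xanthomata_arcus=bool(fam["relative_xanthomata_arcus"][i]),
                fam_child_ldl_gt95=bool(fam["child_ldl_gt95"][i]),
                tendon_xanthomata=bool(tendon[i]),
                arcus_cornealis=bool(arcus[i]),
                arcus_age=float(arcus_age[i]) if arcus[i] else None,
                diabetes=bool(diabetes[i]),
                hypertension=bool(hypertension[i]),
                fam_hypercholesterolemia=bool(fam.get("hypercholesterolemia", np.zeros(n, bool))[i]),
            )
        )
        carried: Dict[str, int] = {}
        if carrier[i] and causal:
            carried[causal[which[i]].variant.key] = 1
        for key, mask in noncausal_carriers.items():
            if mask[i]:
                carried[key] = 1
        if carried:
            rare_carriage[pid] = carried
        if carrier[i] and causal:
            etiology_truth.append("monogenic")
            plp_variant_col.append(causal[which[i]].variant.key)
            plp_gene_col.append(causal[which[i]].variant.gene)
        elif pgs_raw[i] >= config.pgs_threshold:
            etiology_truth.append("polygenic_tail")
            plp_variant_col.append("")
            plp_gene_col.append("")
        else:
            etiology_truth.append("neither")
            plp_variant_col.append("")
            plp_gene_col.append("")

    genotypes = pd.DataFrame(dosages, index=pids, columns=[s_.snv_id for s_ in config.snv_panel])
    truth = pd.DataFrame(
        {
            "etiology_truth": etiology_truth,
            "carrier": carrier,
            "plp_variant": plp_variant_col,
            "plp_gene": plp_gene_col,
            "pgs_raw": pgs_raw,
            "genetic_component": genetic_component,
            "untreated_ldl": untreated,
            "observed_ldl": observed,
            "on_statin": on_statin,
            "age": age,
            "male": male,
            "white": white,
            "bmi": bmi,
            "diabetes": diabetes,
            "fam_hypercholesterolemia": [p_.fam_hypercholesterolemia for p_ in participants],
        },
        index=pids,
    )
    return SyntheticCohort(
        participants=participants,
        genotypes=genotypes,
        rare_carriage=rare_carriage,
        variants=[e.variant for e in config.variant_catalogue],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# deterministic count fixture


#: Cohort marginals and joints the analysis is benchmarked against
#: (counts of the published screening study the pipeline re-implements).
REFERENCE_COHORT_COUNTS: Dict[str, int] = {
    "total": 1682,
    "monogenic": 25,
    "polygenic": 262,
    "phenotypic_fh": 142,
    "monogenic_phenotypic_fh": 10,
    "polygenic_phenotypic_fh": 27,
    "ldl_ge190": 590,
    "ldl_ge250": 69,
    "ldl_ge_p95": 818,
    "ldl_ge_p99": 372,
    "monogenic_ldl_ge190": 20,
    "monogenic_ldl_ge250": 8,
    "monogenic_ldl_ge_p95": 21,
    "monogenic_ldl_ge_p99": 18,
    "monogenic_ldlr": 18,
    "monogenic_apob": 6,
    "monogenic_pcsk9": 1,
}

_FIXTURE_P95 = 175.0
_FIXTURE_P99 = 215.0
_STRATUM_MIDPOINTS = (165.0, 182.0, 200.0, 232.0, 265.0)
_FIXTURE_DATE = dt.date(2015, 6, 1)


def _validate_counts(c: Dict[str, int]) -> None:
    total = c["total"]
    if total < 1:
        raise FixtureError("total must be >= 1")
    for key, value in c.items():
        if value < 0:
            raise FixtureError(f"count {key} must be >= 0, got {value}")
        if key != "total" and value > total:
            raise FixtureError(f"count {key}={value} exceeds total={total}")
    if c["monogenic"] + c["polygenic"] > total:
        raise FixtureError("monogenic + polygenic exceed total")
    if c["monogenic_phenotypic_fh"] > min(c["monogenic"], c["phenotypic_fh"]):
        raise FixtureError(
            f"joint monogenic_phenotypic_fh={c['monogenic_phenotypic_fh']} exceeds a marginal "
            f"(monogenic={c['monogenic']}, phenotypic_fh={c['phenotypic_fh']})"
        )
    if c["polygenic_phenotypic_fh"] > min(c["polygenic"], c["phenotypic_fh"]):
        raise FixtureError("joint polygenic_phenotypic_fh exceeds a marginal")
    if c["monogenic_phenotypic_fh"] + c["polygenic_phenotypic_fh"] > c["phenotypic_fh"]:
        raise FixtureError("FH joints exceed the FH marginal")
    if not (c["ldl_ge_p95"] >= c["ldl_ge190"] >= c["ldl_ge_p99"] >= c["ldl_ge250"]):
        raise FixtureError(
            "strata counts must be monotone along the LDL axis "
            "(ge_p95 >= ge190 >= ge_p99 >= ge250) to be realizable with one LDL value per subject"
        )
    chain = (
        c["monogenic"],
        c["monogenic_ldl_ge_p95"],
        c["monogenic_ldl_ge190"],
        c["monogenic_ldl_ge_p99"],
        c["monogenic_ldl_ge250"],
    )
    if not all(a >= b for a, b in zip(chain, chain[1:])):
        raise FixtureError("monogenic joint counts must be monotone along the LDL axis")
    for joint, stratum in (
        ("monogenic_ldl_ge190", "ldl_ge190"),
        ("monogenic_ldl_ge250", "ldl_ge250"),
        ("monogenic_ldl_ge_p95", "ldl_ge_p95"),
        ("monogenic_ldl_ge_p99", "ldl_ge_p99"),
    ):
        if c[joint] > c[stratum]:
            raise FixtureError(f"joint {joint} exceeds stratum {stratum}")
    gene_sum = c["monogenic_ldlr"] + c["monogenic_apob"] + c["monogenic_pcsk9"]
    if c["monogenic"] and gene_sum != c["monogenic"]:
        raise FixtureError(
            f"gene split ({gene_sum}) must sum to the monogenic count ({c['monogenic']})"
        )
    if c["monogenic_phenotypic_fh"] > c["monogenic_ldl_ge190"]:
        raise FixtureError(
            "monogenic FH subjects need LDL >= 190 to reach a DLCN total of 6 "
            "with the minimal flag set; increase monogenic_ldl_ge190"
        )
    nonmono_fh = c["phenotypic_fh"] - c["monogenic_phenotypic_fh"]
    if nonmono_fh > c["ldl_ge190"] - c["monogenic_ldl_ge190"]:
        raise FixtureError("not enough non-monogenic LDL>=190 slots for the FH count")


def _fixture_catalogue() -> List[CatalogueEntry]:
    from .config import load_default_generator_mapping

    data = load_default_generator_mapping()
    cfg = GeneratorConfig.from_mapping(data)
    return [e for e in cfg.variant_catalogue if e.truth_plp]


def fixture_from_counts(
    counts: Optional[Mapping[str, int]] = None,
) -> SyntheticCohort:
    """Deterministic cohort reproducing a table of printed counts exactly.

    Subjects live on a single LDL axis with strata cut at the fixture's
    percentile cut points (175 / 215 mg/dl) and the clinical thresholds
    (190 / 250 mg/dl); attribute values sit at stratum midpoints.  Monogenic
    subjects carry genuine P/LP-classifiable variants, polygenic subjects
    carry the all-effect-allele panel genotype, and phenotypic-FH subjects get
    the minimal flag set (relative with xanthomata + premature CHD) that,
    combined with their LDL band points, crosses the DLCN >= 6 line — so the
    fixture exercises the real classifiers end to end.
    """
    c = dict(REFERENCE_COHORT_COUNTS if counts is None else {k: 0 for k in REFERENCE_COHORT_COUNTS})
    if counts is not None:
        unknown = set(counts) - set(REFERENCE_COHORT_COUNTS)
        if unknown:
            raise FixtureError(f"unknown count keys: {sorted(unknown)}")
        c.update({k: int(v) for k, v in counts.items()})
    _validate_counts(c)

    total = c["total"]
    stratum_sizes = [
        total - c["ldl_ge_p95"],
        c["ldl_ge_p95"] - c["ldl_ge190"],
        c["ldl_ge190"] - c["ldl_ge_p99"],
        c["ldl_ge_p99"] - c["ldl_ge250"],
        c["ldl_ge250"],
    ]
    mono_per_stratum = [
        c["monogenic"] - c["monogenic_ldl_ge_p95"],
        c["monogenic_ldl_ge_p95"] - c["monogenic_ldl_ge190"],
        c["monogenic_ldl_ge190"] - c["monogenic_ldl_ge_p99"],
        c["monogenic_ldl_ge_p99"] - c["monogenic_ldl_ge250"],
        c["monogenic_ldl_ge250"],
    ]
    for stratum, (size, m) in enumerate(zip(stratum_sizes, mono_per_stratum)):
        if m > size:
            raise FixtureError(f"monogenic count in stratum {stratum} exceeds the stratum size")

    catalogue = _fixture_catalogue()
    by_gene: Dict[str, List[CatalogueEntry]] = {}
    for e in catalogue:
        by_gene.setdefault(e.variant.gene, []).append(e)
    for gene, key in (("LDLR", "monogenic_ldlr"), ("APOB", "monogenic_apob"), ("PCSK9", "monogenic_pcsk9")):
        if c[key] > 0 and gene not in by_gene:
            raise FixtureError(f"no P/LP catalogue variant available for {gene}")

    # Per-subject plan: (stratum, etiology, fh, variant_key, gene)
    plan: List[Tuple[int, str, bool, Optional[str], Optional[str]]] = []

    # monogenic subjects: gene assignment round-robins within each gene's variants
    gene_queue: List[Tuple[str, CatalogueEntry]] = []
    for gene, key in (("LDLR", "monogenic_ldlr"), ("APOB", "monogenic_apob"), ("PCSK9", "monogenic_pcsk9")):
        variants = by_gene.get(gene, [])
        for j in range(c[key]):
            gene_queue.append((gene, variants[j % len(variants)]))
    mono_strata: List[int] = []
    for stratum, m in enumerate(mono_per_stratum):
        mono_strata.extend([stratum] * m)
    # FH flags go to monogenic subjects with LDL >= 190, highest strata last
    fh_needed = c["monogenic_phenotypic_fh"]
    mono_fh_flags = []
    for stratum in mono_strata:
        if stratum >= 2 and fh_needed > 0:
            mono_fh_flags.append(True)
            fh_needed -= 1
        else:
            mono_fh_flags.append(False)
    for stratum, fh, (gene, entry) in zip(mono_strata, mono_fh_flags, gene_queue):
        plan.append((stratum, "monogenic", fh, entry.variant.key, gene))

    free_slots = [size - m for size, m in zip(stratum_sizes, mono_per_stratum)]

    def take_slots(n_needed: int, strata_order: Sequence[int], what: str) -> List[int]:
        got: List[int] = []
        for stratum in strata_order:
            take = min(n_needed - len(got), free_slots[stratum])
            got.extend([stratum] * take)
            free_slots[stratum] -= take
            if len(got) == n_needed:
                return got
        raise FixtureError(f"not enough slots to place {what}")

    for stratum in take_slots(c["polygenic_phenotypic_fh"], (2, 3, 4), "polygenic FH subjects"):
        plan.append((stratum, "polygenic", True, None, None))
    nonmono_nonpoly_fh = c["phenotypic_fh"] - c["monogenic_phenotypic_fh"] - c["polygenic_phenotypic_fh"]
    for stratum in take_slots(nonmono_nonpoly_fh, (2, 3, 4), "unexplained FH subjects"):
        plan.append((stratum, "none", True, None, None))
    for stratum in take_slots(c["polygenic"] - c["polygenic_phenotypic_fh"], (0, 1, 2, 3, 4), "polygenic subjects"):
        plan.append((stratum, "polygenic", False, None, None))
    remaining = total - len(plan)
    for stratum in take_slots(remaining, (0, 1, 2, 3, 4), "remaining subjects"):
        plan.append((stratum, "none", False, None, None))

    width = max(6, len(str(total)))
    participants: List[ParticipantRecord] = []
    rare_carriage: Dict[str, Dict[str, int]] = {}
    dosage_rows: List[List[int]] = []
    truth_rows = []
    from .config import load_default_panel

    panel = load_default_panel()
    for i, (stratum, etiology, fh, variant_key, gene) in enumerate(plan):
        pid = f"F{i + 1:0{width}d}"
        ldl = _STRATUM_MIDPOINTS[stratum]
        diagnoses: Tuple[Diagnosis, ...] = ()
        if fh:
            diagnoses = (Diagnosis(_FIXTURE_DATE, "CHD", 45.0),)
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=50.0,
                sex=MALE,
                bmi=27.0,
                lipids=(LipidMeasure(_FIXTURE_DATE, ldl, 150.0, 55.0),),
                diagnoses=diagnoses,
                fam_relative_xanthomata_arcus=fh,
            )
        )
        dosage_rows.append([2 if etiology == "polygenic" else 0] * len(panel))
        if variant_key is not None:
            rare_carriage[pid] = {variant_key: 1}
        truth_rows.append(
            {
                "etiology_truth": {"monogenic": "monogenic", "polygenic": "polygenic_tail", "none": "neither"}[etiology],
                "carrier": etiology == "monogenic",
                "plp_variant": variant_key or "",
                "plp_gene": gene or "",
                "pgs_raw": float(panel.max_score()) if etiology == "polygenic" else 0.0,
                "genetic_component": 0.0,
                "untreated_ldl": ldl,
                "observed_ldl": ldl,
                "phenotypic_fh_truth": fh,
            }
        )

    pids = [p.participant_id for p in participants]
    genotypes = pd.DataFrame(dosage_rows, index=pids, columns=list(panel.ids))
    truth = pd.DataFrame(truth_rows, index=pids)
    reference = PercentileReference(
        [PercentileBand(MALE, 18.0, 70.0, _FIXTURE_P95, _FIXTURE_P99)]
    )
    return SyntheticCohort(
        participants=participants,
        genotypes=genotypes,
        rare_carriage=rare_carriage,
        variants=[e.variant for e in catalogue],
        truth=truth,
        percentile_reference=reference,
    )


# ---------------------------------------------------------------------------
# writing


@dataclass(frozen=True)
class CohortPaths:
    vcf: Path
    phenotypes: Path
    truth: Path


def write_cohort(cohort: SyntheticCohort, out_dir) -> CohortPaths:
    """Write genotypes (VCF), phenotypes (TSV) and truth labels (TSV)."""
    from .tabio import write_phenotypes, write_truth
    from .vcfio import write_cohort_vcf

    if cohort.n == 0:
        raise ConfigError("cannot write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "genotypes.vcf"
    pheno_path = out / "phenotypes.tsv"
    truth_path = out / "truth.tsv"
    write_cohort_vcf(cohort, vcf_path)
    write_phenotypes(cohort.participants, pheno_path)
    write_truth(cohort.truth, truth_path)
    return CohortPaths(vcf=vcf_path, phenotypes=pheno_path, truth=truth_path)
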