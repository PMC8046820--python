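"""Rare-variant triage and ACMG/AMP classification for the three FH genes.

Candidate variants in LDLR/APOB/PCSK9 are kept when they are (a) functional
(protein-altering or splice-disrupting) and (b) rare (reference-population
allele frequency strictly below 0.1%, or never observed).  Surviving variants
receive automatable evidence tags — PVS1 (null variant where loss of function
is the disease mechanism), PM2 (absent/rare in reference populations),
PP3/BP4 (computational prediction), PP5/BP6 (external clinical assertion) —
plus any directly supplied tags (standing in for manual curation), and the
full ACMG/AMP combining table maps the evidence multiset to the five-tier
class.  A participant is called monogenic when they carry at least one
alternate allele of a pathogenic or likely-pathogenic variant.

Loss-of-function is gene-mechanism dependent: LDLR is haploinsufficient, but
FH-causing APOB and PCSK9 variants act by altered/gain of function, so PVS1
is gated per gene (configurable).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import ConfigError, EvidenceConflictError, NotSupportedError

FH_GENES = ("LDLR", "APOB", "PCSK9")

FUNCTIONAL_CLASSES = frozenset(
    {
        "missense",
        "stop_gain",
        "frameshift",
        "splice_acceptor",
        "splice_donor",
        "inframe_indel",
        "start_lost",
        "stop_lost",
    }
)

#: Consequence classes that count as "null" for PVS1.
NULL_CLASSES = frozenset(
    {"stop_gain", "frameshift", "splice_acceptor", "splice_donor", "start_lost"}
)

NON_FUNCTIONAL_CLASSES = frozenset({"synonymous", "intronic", "other"})
CONSEQUENCE_CLASSES = FUNCTIONAL_CLASSES | NON_FUNCTIONAL_CLASSES

#: Default disease mechanism gate: PVS1 applies only where LoF causes disease.
DEFAULT_LOF_MECHANISM = {"LDLR": True, "APOB": False, "PCSK9": False}

DEFAULT_FREQUENCY_THRESHOLD = 0.001  # "<0.1%"

_TAG_RE = re.compile(r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])$")

PATHOGENIC_CLASSES = ("pathogenic", "likely_pathogenic")
FIVE_TIER = ("pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign")


def _category(tag: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if tag.startswith(prefix):
            return prefix
    raise ConfigError(f"unknown evidence tag {tag!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    ref_af: Optional[float] = None
    clinvar: Optional[str] = None  # external clinical-database class
    pred_verdict: Optional[str] = None  # {"damaging", "benign", "unknown"}
    supplied_tags: Tuple[str, ...] = ()
    variant_id: Optional[str] = None

    @property
    def key(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def validate(self) -> None:
        if self.gene not in FH_GENES:
            raise ConfigError(f"{self.key}: gene must be one of {FH_GENES}, got {self.gene!r}")
        if self.consequence == "cnv":
            raise NotSupportedError(f"{self.key}: copy-number variants are not supported")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ConfigError(
                f"{self.key}: unknown consequence class {self.consequence!r}"
            )
        if self.ref_af is not None and not (0.0 <= self.ref_af <= 1.0):
            raise ConfigError(f"{self.key}: ref_af must be in [0, 1], got {self.ref_af}")


class EvidenceSet:
    """Multiset of ACMG/AMP evidence tags from the closed vocabulary."""

    def __init__(self, tags: Iterable[str] = ()):
        self._counts: Counter = Counter()
        for tag in tags:
            self.add(tag)

    def add(self, tag: str, count: int = 1) -> None:
        if not _TAG_RE.match(tag):
            raise ConfigError(f"invalid ACMG evidence tag {tag!r}")
        if count < 0:
            raise ConfigError(f"evidence count must be >= 0 for {tag}")
        self._counts[tag] += count

    def discard(self, tag: str) -> None:
        self._counts.pop(tag, None)

    def count(self, category: str) -> int:
        """Total count of tags whose strength category is *category* (e.g. 'PM')."""
        return sum(
            n for tag, n in self._counts.items()
            if _category(tag) == category
        )

    def tags(self) -> Tuple[str, ...]:
        return tuple(sorted(self._counts.elements()))

    def __contains__(self, tag: str) -> bool:
        return self._counts.get(tag, 0) > 0

    def __len__(self) -> int:
        return sum(self._counts.values())

    def __repr__(self) -> str:
        return f"EvidenceSet({list(self.tags())})"


@dataclass
class ClassificationResult:
    classification: str  # one of FIVE_TIER
    rule: str  # identifier of the fired combining rule
    evidence: EvidenceSet

    @property
    def is_plp(self) -> bool:
        return self.classification in PATHOGENIC_CLASSES


def functional_filter(variant: AnnotatedVariant) -> bool:
    """True iff the consequence class is protein-altering or splice-disrupting."""
    variant.validate()
    return variant.consequence in FUNCTIONAL_CLASSES


def rare_filter(
    variant: AnnotatedVariant, threshold: float = DEFAULT_FREQUENCY_THRESHOLD
) -> bool:
    """True iff reference frequency is absent (never observed) or strictly below threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"frequency threshold must be in (0, 1], got {threshold}")
    if variant.ref_af is None:
        return True
    return variant.ref_af < threshold


@dataclass
class FilterResult:
    """Candidate triage with first-failure attribution (functional, then rare)."""

    passed: List[AnnotatedVariant] = field(default_factory=list)
    failed_functional: List[AnnotatedVariant] = field(default_factory=list)
    failed_rare: List[AnnotatedVariant] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.passed) + len(self.failed_functional) + len(self.failed_rare)


def filter_variants(
    variants: Iterable[AnnotatedVariant],
    threshold: float = DEFAULT_FREQUENCY_THRESHOLD,
) -> FilterResult:
    result = FilterResult()
    for v in variants:
        if not functional_filter(v):
            result.failed_functional.append(v)
        elif not rare_filter(v, threshold):
            result.failed_rare.append(v)
        else:
            result.passed.append(v)
    return result


def assign_evidence(
    variant: AnnotatedVariant,
    lof_mechanism: Mapping[str, bool] = DEFAULT_LOF_MECHANISM,
    frequency_threshold: float = DEFAULT_FREQUENCY_THRESHOLD,
    use_pp5_bp6: bool = True,
) -> EvidenceSet:
    """Deterministic, annotation-derivable evidence tags plus supplied ones.

    Supplied tags prefixed with ``!`` retract the corresponding automatic tag;
    supplying both ``TAG`` and ``!TAG`` is a contradiction and raises.
    """
    variant.validate()
    ev = EvidenceSet()
    if variant.consequence in NULL_CLASSES and lof_mechanism.get(variant.gene, False):
        ev.add("PVS1")
    if rare_filter(variant, frequency_threshold):
        ev.add("PM2")
    if variant.pred_verdict == "damaging":
        ev.add("PP3")
    elif variant.pred_verdict == "benign":
        ev.add("BP4")
    if use_pp5_bp6 and variant.clinvar is not None:
        if variant.clinvar in ("pathogenic", "likely_pathogenic"):
            ev.add("PP5")
        elif variant.clinvar in ("benign", "likely_benign"):
            ev.add("BP6")
    asserted = {t for t in variant.supplied_tags if not t.startswith("!")}
    retracted = {t[1:] for t in variant.supplied_tags if t.startswith("!")}
    conflict = asserted & retracted
    if conflict:
        raise EvidenceConflictError(
            f"{variant.key}: tags both asserted and retracted: {sorted(conflict)}"
        )
    for tag in retracted:
        if not _TAG_RE.match(tag):
            raise ConfigError(f"{variant.key}: invalid retraction !{tag}")
        ev.discard(tag)
    for tag in asserted:
        if tag not in ev:  # merge; automatic + supplied duplicates count once
            ev.add(tag)
    return ev


def combine_acmg(evidence: EvidenceSet) -> ClassificationResult:
    """Apply the ACMG/AMP combining table to an evidence multiset.

    Pathogenic- and benign-direction rules are evaluated independently; when
    both directions fire the verdict is uncertain (conflicting evidence).
    """
    pvs = evidence.count("PVS")
    ps = evidence.count("PS")
    pm = evidence.count("PM")
    pp = evidence.count("PP")
    ba = evidence.count("BA")
    bs = evidence.count("BS")
    bp = evidence.count("BP")

    pathogenic_rules = (
        ("P1", pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2)),
        ("P2", ps >= 2),
        ("P3", ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4))),
    )
    likely_pathogenic_rules = (
        ("LP1", pvs >= 1 and pm >= 1),
        ("LP2", ps >= 1 and 1 <= pm <= 2),
        ("LP3", ps >= 1 and pp >= 2),
        ("LP4", pm >= 3),
        ("LP5", pm >= 2 and pp >= 2),
        ("LP6", pm >= 1 and pp >= 4),
    )
    benign_rules = (
        ("B1", ba >= 1),
        ("B2", bs >= 2),
    )
    likely_benign_rules = (
        ("LB1", bs >= 1 and bp >= 1),
        ("LB2", bp >= 2),
    )

    p_fired = next((r for r, ok in pathogenic_rules if ok), None)
    lp_fired = next((r for r, ok in likely_pathogenic_rules if ok), None)
    b_fired = next((r for r, ok in benign_rules if ok), None)
    lb_fired = next((r for r, ok in likely_benign_rules if ok), None)

    pathogenic_direction = p_fired or lp_fired
    benign_direction = b_fired or lb_fired

    if pathogenic_direction and benign_direction:
        return ClassificationResult("uncertain", "conflict", evidence)
    if p_fired:
        return ClassificationResult("pathogenic", p_fired, evidence)
    if lp_fired:
        return ClassificationResult("likely_pathogenic", lp_fired, evidence)
    if b_fired:
        return ClassificationResult("benign", b_fired, evidence)
    if lb_fired:
        return ClassificationResult("likely_benign", lb_fired, evidence)
    return ClassificationResult("uncertain", "none", evidence)


def classify_variant(
    variant: AnnotatedVariant,
    lof_mechanism: Mapping[str, bool] = DEFAULT_LOF_MECHANISM,
    frequency_threshold: float = DEFAULT_FREQUENCY_THRESHOLD,
    use_pp5_bp6: bool = True,
) -> ClassificationResult:
    """Evidence assignment followed by combining, for one triaged variant."""
    ev = assign_evidence(variant, lof_mechanism, frequency_threshold, use_pp5_bp6)
    return combine_acmg(ev)


def call_monogenic(
    carriage: Mapping[str, int],
    classifications: Mapping[str, ClassificationResult],
) -> bool:
    """True iff >=1 alternate allele of >=1 pathogenic/likely-pathogenic variant.

    *carriage* maps variant key -> alternate-allele count for one participant.
    Referencing an unclassified variant is an error, not a silent skip.
    """
    for key, count in carriage.items():
        if key not in classifications:
            raise ConfigError(f"genotype references unclassified variant {key!r}")
        if count > 0 and classifications[key].is_plp:
            return True
    return False
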