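"""Variant triage and ACMG/AMP combining: filters, evidence, oracle equivalence."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperchol.acmg import (
    AnnotatedVariant,
    EvidenceSet,
    assign_evidence,
    call_monogenic,
    classify_variant,
    combine_acmg,
    filter_variants,
    functional_filter,
    rare_filter,
)
from hyperchol.errors import ConfigError, EvidenceConflictError, NotSupportedError


def make_variant(gene="LDLR", consequence="missense", ref_af=None, clinvar=None,
                 pred_verdict=None, supplied_tags=(), vid="v1"):
    return AnnotatedVariant(
        chrom="19", pos=11_200_000, ref="G", alt="A", gene=gene,
        consequence=consequence, ref_af=ref_af, clinvar=clinvar,
        pred_verdict=pred_verdict, supplied_tags=tuple(supplied_tags), variant_id=vid,
    )


class TestFilters:
    @pytest.mark.parametrize(
        "consequence,passes",
        [("stop_gain", True), ("missense", True), ("frameshift", True),
         ("splice_donor", True), ("synonymous", False), ("intronic", False)],
    )
    def test_functional_filter(self, consequence, passes):
        assert functional_filter(make_variant(consequence=consequence)) is passes

    @pytest.mark.parametrize(
        "ref_af,passes",
        [(0.0009, True), (0.001, False), (0.01, False), (None, True), (0.0, True)],
    )
    def test_rare_filter_strict_below_point1_percent(self, ref_af, passes):
        assert rare_filter(make_variant(ref_af=ref_af), 0.001) is passes

    def test_cnv_raises_not_supported(self):
        with pytest.raises(NotSupportedError):
            functional_filter(make_variant(consequence="cnv"))

    def test_filter_conservation_with_first_failure_attribution(self):
        variants = [
            make_variant(consequence="synonymous", ref_af=0.5, vid="both_fail"),  # functional first
            make_variant(consequence="missense", ref_af=0.5, vid="common"),
            make_variant(consequence="stop_gain", vid="keeper"),
        ]
        result = filter_variants(variants)
        assert result.n_candidates == 3
        assert [v.variant_id for v in result.failed_functional] == ["both_fail"]
        assert [v.variant_id for v in result.failed_rare] == ["common"]
        assert [v.variant_id for v in result.passed] == ["keeper"]


class TestAssignEvidence:
    def test_ldlr_frameshift_absent_gets_pvs1_pm2(self):
        ev = assign_evidence(make_variant(consequence="frameshift"))
        assert ev.tags() == ("PM2", "PVS1")

    def test_pcsk9_stop_gain_mechanism_gate_blocks_pvs1(self):
        ev = assign_evidence(make_variant(gene="PCSK9", consequence="stop_gain"))
        assert "PVS1" not in ev
        assert "PM2" in ev

    def test_missense_damaging_gets_pp3(self):
        ev = assign_evidence(make_variant(pred_verdict="damaging", ref_af=0.0005))
        assert ev.tags() == ("PM2", "PP3")

    def test_clinical_database_tags_and_toggle(self):
        v = make_variant(clinvar="pathogenic")
        assert "PP5" in assign_evidence(v)
        assert "PP5" not in assign_evidence(v, use_pp5_bp6=False)
        assert "BP6" in assign_evidence(make_variant(clinvar="benign"))

    def test_supplied_tags_merge_and_retraction(self):
        ev = assign_evidence(make_variant(consequence="frameshift", supplied_tags=("PS3", "!PVS1")))
        assert "PS3" in ev and "PVS1" not in ev

    def test_contradictory_supplied_tags_rejected(self):
        with pytest.raises(EvidenceConflictError):
            assign_evidence(make_variant(supplied_tags=("PS3", "!PS3")))

    def test_invalid_tag_rejected(self):
        with pytest.raises(ConfigError):
            EvidenceSet(["PX9"])


class TestCombineExamples:
    def test_empty_evidence_is_uncertain(self):
        assert combine_acmg(EvidenceSet()).classification == "uncertain"

    def test_pvs1_pm2_is_likely_pathogenic(self):
        assert combine_acmg(EvidenceSet(["PVS1", "PM2"])).classification == "likely_pathogenic"

    def test_pvs1_pm2_pp3_is_pathogenic(self):
        assert combine_acmg(EvidenceSet(["PVS1", "PM2", "PP3"])).classification == "pathogenic"

    def test_conflicting_directions_are_uncertain(self):
        result = combine_acmg(EvidenceSet(["BA1", "PVS1", "PS1"]))
        assert result.classification == "uncertain"
        assert result.rule == "conflict"

    def test_benign_rules(self):
        assert combine_acmg(EvidenceSet(["BA1"])).classification == "benign"
        assert combine_acmg(EvidenceSet(["BS1", "BS2"])).classification == "benign"
        assert combine_acmg(EvidenceSet(["BS1", "BP1"])).classification == "likely_benign"
        assert combine_acmg(EvidenceSet(["BP1", "BP2"])).classification == "likely_benign"


# --- independent brute-force oracle of the combining table -----------------


def oracle_classification(pvs, ps, pm, pp, ba, bs, bp):
    """Literal transcription of the guideline combining table."""
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and 1 <= pm <= 2)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    path_dir = pathogenic or likely_pathogenic
    benign_dir = benign or likely_benign
    if path_dir and benign_dir:
        return "uncertain"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain"


def evidence_from_counts(pvs, ps, pm, pp, ba, bs, bp):
    ev = EvidenceSet()
    for tag, n in (("PVS1", pvs), ("PS1", ps), ("PM1", pm), ("PP1", pp),
                   ("BA1", ba), ("BS1", bs), ("BP1", bp)):
        if n:
            ev.add(tag, n)
    return ev


def test_engine_matches_oracle_on_a_spot_grid():
    """Quick spot check on a sub-grid; the exhaustive sweep runs in the acceptance suite."""
    for counts in itertools.product((0, 1, 2), repeat=7):
        ev = evidence_from_counts(*counts)
        assert combine_acmg(ev).classification == oracle_classification(*counts), counts


@given(st.tuples(*[st.integers(0, 4)] * 7))
def test_pathogenic_monotonicity(self_counts):
    """Adding pathogenic-direction evidence to a non-conflicted set never moves toward benign."""
    order = {"benign": 0, "likely_benign": 1, "uncertain": 2, "likely_pathogenic": 3, "pathogenic": 4}
    pvs, ps, pm, pp, ba, bs, bp = self_counts
    if ba or bs or bp:  # keep the base set free of benign evidence (no conflicts)
        ba = bs = bp = 0
    base = combine_acmg(evidence_from_counts(pvs, ps, pm, pp, ba, bs, bp)).classification
    for i in range(4):
        bumped = [pvs, ps, pm, pp]
        bumped[i] += 1
        more = combine_acmg(evidence_from_counts(*bumped, ba, bs, bp)).classification
        assert order[more] >= order[base]


class TestCallMonogenic:
    def test_het_carrier_of_likely_pathogenic_is_monogenic(self):
        cls = {"v1": classify_variant(make_variant(consequence="stop_gain"))}
        assert cls["v1"].classification == "likely_pathogenic"
        assert call_monogenic({"v1": 1}, cls) is True

    def test_carrier_of_uncertain_only_is_not_monogenic(self):
        cls = {"v1": classify_variant(make_variant(ref_af=0.0005))}  # missense, PM2 only
        assert cls["v1"].classification == "uncertain"
        assert call_monogenic({"v1": 2}, cls) is False

    def test_reference_everywhere_is_not_monogenic(self):
        assert call_monogenic({}, {}) is False

    def test_unclassified_variant_reference_errors(self):
        with pytest.raises(ConfigError, match="unclassified"):
            call_monogenic({"ghost": 1}, {})


def test_classification_order_independent():
    variants = [
        make_variant(consequence="stop_gain", vid="a"),
        make_variant(gene="APOB", clinvar="pathogenic", pred_verdict="damaging",
                     supplied_tags=("PS3",), vid="b"),
        make_variant(ref_af=0.0005, vid="c"),
    ]
    forward = {v.variant_id: classify_variant(v).classification for v in variants}
    backward = {v.variant_id: classify_variant(v).classification for v in reversed(variants)}
    assert forward == backward
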