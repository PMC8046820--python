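"""Polygenic-score computation: bounds, linearity, missingness, threshold, percentile."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperchol.config import load_default_panel
from hyperchol.errors import ConfigError
from hyperchol.pgs import (
    SNVPanel,
    SNVEntry,
    classify_polygenic,
    compute_pgs,
    reference_percentile,
)

PANEL = load_default_panel()


def dosage_vector(values):
    return dict(zip(PANEL.ids, values))


class TestComputePgs:
    def test_all_zero_dosages(self):
        assert compute_pgs(dosage_vector([0] * 12), PANEL) == 0.0

    def test_all_two_dosages_equal_twice_weight_sum(self):
        expected = 2 * sum(e.weight for e in PANEL.entries)  # brute-force over config
        assert compute_pgs(dosage_vector([2] * 12), PANEL) == pytest.approx(expected)

    def test_missing_imputed_as_2p(self):
        entry = PANEL.entries[0]
        vec = dosage_vector([0] * 12)
        vec[entry.snv_id] = None
        assert compute_pgs(vec, PANEL) == pytest.approx(2 * entry.eaf * entry.weight)

    def test_strict_policy_rejects_missing(self):
        vec = dosage_vector([0] * 12)
        vec[PANEL.ids[0]] = None
        with pytest.raises(ConfigError, match="strict"):
            compute_pgs(vec, PANEL, missing_policy="strict")

    def test_more_than_half_missing_rejected(self):
        vec = dosage_vector([None] * 7 + [0] * 5)
        with pytest.raises(ConfigError, match="50%"):
            compute_pgs(vec, PANEL)

    def test_unknown_snv_id_rejected(self):
        with pytest.raises(ConfigError, match="unknown SNV"):
            compute_pgs({"rs000": 1}, PANEL)

    def test_invalid_dosage_rejected(self):
        vec = dosage_vector([0] * 12)
        vec[PANEL.ids[0]] = 3
        with pytest.raises(ConfigError):
            compute_pgs(vec, PANEL)

    @given(st.lists(st.integers(0, 2), min_size=12, max_size=12))
    def test_bounds(self, dosages):
        raw = compute_pgs(dosage_vector(dosages), PANEL)
        assert 0.0 <= raw <= PANEL.max_score() + 1e-12
        if all(d == 0 for d in dosages):
            assert raw == 0.0
        if all(d == 2 for d in dosages):
            assert raw == pytest.approx(PANEL.max_score())

    @given(
        st.lists(st.integers(0, 1), min_size=12, max_size=12),
        st.lists(st.integers(0, 1), min_size=12, max_size=12),
    )
    def test_linearity(self, a, b):
        combined = [x + y for x, y in zip(a, b)]
        assert compute_pgs(dosage_vector(combined), PANEL) == pytest.approx(
            compute_pgs(dosage_vector(a), PANEL) + compute_pgs(dosage_vector(b), PANEL)
        )


class TestClassifyPolygenic:
    def test_threshold_inclusive(self):
        assert classify_polygenic(1.16, monogenic=False) is True

    def test_just_below_threshold(self):
        assert classify_polygenic(1.1599, monogenic=False) is False

    def test_monogenic_takes_precedence(self):
        assert classify_polygenic(1.16, monogenic=True) is False
        assert classify_polygenic(2.0, monogenic=True) is False


class TestReferencePercentile:
    def test_below_minimum_is_zero(self):
        assert reference_percentile(0.1, [1.0, 2.0, 3.0]) == 0.0

    def test_above_maximum_is_hundred(self):
        assert reference_percentile(9.0, [1.0, 2.0, 3.0]) == 100.0

    def test_median_by_counting(self):
        ref = [0.5, 0.8, 1.0, 1.2, 1.5]  # odd n, unique values
        assert reference_percentile(1.0, ref) == pytest.approx(40.0)  # 2 of 5 strictly below
        assert abs(reference_percentile(1.0, ref) - 50.0) <= 100.0 / len(ref)

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigError):
            reference_percentile(1.0, [])

    @given(st.floats(0, 3, allow_nan=False), st.floats(0, 1, allow_nan=False))
    def test_monotone_in_raw(self, raw, bump):
        ref = list(np.linspace(0.3, 2.0, 37))
        assert reference_percentile(raw + bump, ref) >= reference_percentile(raw, ref)


class TestPanelValidation:
    def test_default_panel_has_12_unique_positive_weights(self):
        assert len(PANEL) == 12
        assert len(set(PANEL.ids)) == 12
        assert all(e.weight > 0 for e in PANEL.entries)

    def test_duplicate_ids_rejected(self):
        e = PANEL.entries[0]
        with pytest.raises(ConfigError, match="unique"):
            SNVPanel([e, e])

    def test_degenerate_frequency_rejected(self):
        bad = SNVEntry("rsX", "1", 1, "A", "G", eaf=0.0, weight=0.1)
        with pytest.raises(ConfigError, match="eaf"):
            SNVPanel([bad])

    def test_analytic_moments_match_brute_force_enumeration(self):
        """Closed forms vs direct expectation over all genotypes of a 3-SNV panel."""
        small = SNVPanel(
            [
                SNVEntry("a", "1", 1, "A", "G", 0.2, 0.5),
                SNVEntry("b", "1", 2, "A", "G", 0.5, 0.3),
                SNVEntry("c", "1", 3, "A", "G", 0.8, 0.2),
            ]
        )
        import itertools

        mean = 0.0
        second = 0.0
        for dosages in itertools.product((0, 1, 2), repeat=3):
            prob = 1.0
            for d, e in zip(dosages, small.entries):
                p = e.eaf
                prob *= {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}[d]
            score = sum(d * e.weight for d, e in zip(dosages, small.entries))
            mean += prob * score
            second += prob * score**2
        assert small.analytic_mean() == pytest.approx(mean)
        assert small.analytic_variance() == pytest.approx(second - mean**2)
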