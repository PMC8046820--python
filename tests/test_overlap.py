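"""Etiology calls, cross-tab percentages with audit trail, group statistics."""

import numpy as np
import pandas as pd
import pytest

from hyperchol.errors import CollinearityError, ConfigError
from hyperchol.overlap import (
    EtiologyCall,
    classify_etiology,
    crosstab_overlap,
    group_compare,
    significance_stars,
    variance_explained,
)
from hyperchol.rounding import percentage, round_half_up


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(10, 142, 7.0), (27, 262, 10.3), (37, 287, 12.9), (37, 142, 26.1),
         (25, 1682, 1.5), (262, 1682, 15.6), (287, 1682, 17.1), (1, 8, 12.5)],
    )
    def test_shared_half_up_convention(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_up_at_tie(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(12.25, 1) == 12.3

    def test_zero_denominator_is_undefined_not_zero(self):
        assert percentage(5, 0) is None


class TestClassifyEtiology:
    def test_monogenic_takes_precedence(self):
        assert classify_etiology(True, True) == "monogenic"
        assert classify_etiology(True, False) == "monogenic"

    def test_polygenic_then_none(self):
        assert classify_etiology(False, True) == "polygenic"
        assert classify_etiology(False, False) == "none"


def call(pid, etiology="none", fh=False, ldl=165.0, **kw):
    return EtiologyCall(
        participant_id=pid, etiology=etiology, dlcn_category="probable" if fh else "unlikely",
        phenotypic_fh=fh, untreated_ldl=ldl,
        ge190=ldl >= 190, ge250=ldl >= 250, ge95th=ldl >= 175, ge99th=ldl >= 215, **kw,
    )


class TestCrosstab:
    def test_single_monogenic_fh_participant_is_100_percent_everywhere(self):
        summary = crosstab_overlap([call("p", "monogenic", fh=True, ldl=260.0, plp_genes=("LDLR",))])
        for name in ("monogenic_of_cohort", "fh_of_monogenic", "monogenic_of_fh",
                     "monogenic_of_ldl_ge190", "monogenic_of_ldl_ge250", "ldlr_of_monogenic"):
            assert summary.percentages[name].value == 100.0, name

    def test_empty_subgroup_reported_as_undefined(self):
        summary = crosstab_overlap([call("p")])
        assert summary.percentages["fh_of_monogenic"].value is None
        assert summary.percentages["monogenic_of_ldl_ge250"].value is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            crosstab_overlap([])

    def test_percentages_recompute_from_emitted_counts(self):
        calls = (
            [call(f"m{i}", "monogenic", fh=i < 2, ldl=230.0) for i in range(5)]
            + [call(f"p{i}", "polygenic", fh=i < 3, ldl=200.0) for i in range(20)]
            + [call(f"n{i}", ldl=165.0) for i in range(75)]
        )
        summary = crosstab_overlap(calls)
        for name, pct in summary.percentages.items():
            assert pct.value == percentage(pct.numerator, pct.denominator), name

    def test_partition_counts_sum_to_total(self):
        calls = [call(f"x{i}", e) for i, e in enumerate(["monogenic", "polygenic", "none", "none"])]
        s = crosstab_overlap(calls)
        assert s.counts["monogenic"] + s.counts["polygenic"] + (
            s.counts["total"] - s.counts["genetic"]
        ) == s.counts["total"]
        assert (
            s.counts["dlcn_unlikely"] + s.counts["dlcn_possible"] + s.counts["dlcn_probable_definite"]
            == s.counts["total"]
        )


class TestGroupCompare:
    def test_identical_groups_t_statistic_zero(self):
        stat, p, sig = group_compare({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]}, "ttest")
        assert stat == pytest.approx(0.0)
        assert not sig

    def test_equal_count_chi2_p_is_one(self):
        _, p, sig = group_compare({"a": [50, 50], "b": [50, 50]}, "chi2")
        assert p == pytest.approx(1.0)
        assert not sig

    def test_monogenic_shift_detected_with_high_power(self):
        """A +46 mg/dl carrier shift at n=5000 is essentially always detected."""
        rng = np.random.default_rng(12345)
        detections = 0
        for _ in range(40):
            carriers = rng.normal(232.0, 55.0, 75)
            rest = rng.normal(186.0, 31.0, 4925)
            _, p, _ = group_compare({"mono": carriers, "rest": rest}, "ttest")
            detections += p < 0.01
        assert detections == 40

    def test_anova_type_I_error_calibrated(self):
        """Three equal-mean groups reject at ~5% under the null."""
        rng = np.random.default_rng(999)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = {k: rng.normal(0, 1, 30) for k in "abc"}
            _, p, _ = group_compare(groups, "anova")
            rejections += p < 0.05
        assert 0.035 < rejections / n_rep < 0.065

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            group_compare({"a": [1.0]}, "ttest")
        with pytest.raises(ConfigError):
            group_compare({"a": [1, 2, 3]}, "badkind")

    def test_significance_stars_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(3e-5) == "****"


class TestVarianceExplained:
    @staticmethod
    def _table(n, rng, genetic_effect):
        pgs = rng.normal(0.9, 0.22, n)
        mono = rng.random(n) < 0.01
        ldl = 150 + genetic_effect * pgs + 60 * genetic_effect / 40 * mono + rng.normal(0, 35, n)
        return pd.DataFrame(
            {
                "untreated_ldl": ldl,
                "pgs_raw": pgs,
                "monogenic": mono,
                "age": rng.uniform(20, 70, n),
                "male": rng.random(n) < 0.5,
                "white": rng.random(n) < 0.9,
                "bmi": rng.normal(29, 7, n),
                "diabetes": rng.random(n) < 0.1,
                "fam_hypercholesterolemia": rng.random(n) < 0.25,
            }
        )

    def test_null_genetic_effect_gives_near_zero_r2(self):
        table = self._table(50_000, np.random.default_rng(5), genetic_effect=0.0)
        vd = variance_explained(table)
        assert vd.r2_genetic < 0.001
        assert vd.n == 50_000

    def test_duplicated_predictor_raises_collinearity(self):
        table = self._table(500, np.random.default_rng(6), genetic_effect=40.0)
        table["pgs_copy"] = table["pgs_raw"]
        with pytest.raises(CollinearityError):
            variance_explained(table, genetic_cols=("pgs_raw", "pgs_copy", "monogenic"))

    def test_constant_predictor_raises_collinearity(self):
        table = self._table(500, np.random.default_rng(7), genetic_effect=40.0)
        table["white"] = True
        with pytest.raises(CollinearityError):
            variance_explained(table)

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigError, match="missing columns"):
            variance_explained(pd.DataFrame({"untreated_ldl": [1.0, 2.0]}))
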