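"""Synthetic cohorts: determinism, HWE, analytic moments, parameter recovery, fixture."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hyperchol.errors import ConfigError, FixtureError
from hyperchol.synthetic import (
    GeneratorConfig,
    REFERENCE_COHORT_COUNTS,
    fixture_from_counts,
    generate_population,
)


def default_mapping(**overrides):
    from hyperchol.config import load_default_generator_mapping

    data = load_default_generator_mapping()
    data.update(overrides)
    return data


class TestConfigValidation:
    def test_negative_probability_rejected_with_field_name(self):
        with pytest.raises(ConfigError, match="plp_carrier_rate"):
            GeneratorConfig.from_mapping(default_mapping(plp_carrier_rate=-0.1))

    def test_nonfinite_value_rejected_with_field_name(self):
        with pytest.raises(ConfigError, match="residual_sd"):
            GeneratorConfig.from_mapping(default_mapping(residual_sd=float("nan")))

    def test_zero_population_rejected(self):
        with pytest.raises(ConfigError, match="n_population"):
            GeneratorConfig.from_mapping(default_mapping(n_population=0))

    def test_nonpositive_weight_rejected(self):
        data = default_mapping()
        data["snv_panel"] = [dict(data["snv_panel"][0], weight=0.0)]
        with pytest.raises(ConfigError, match="weight"):
            GeneratorConfig.from_mapping(data)


class TestDegenerateConfigs:
    def test_zero_frequencies_give_zero_dosage_and_zero_score(self):
        data = default_mapping(n_population=200, seed=1)
        data["snv_panel"] = [dict(row, eaf=0.0) for row in data["snv_panel"]]
        cohort = generate_population(GeneratorConfig.from_mapping(data))
        assert (cohort.genotypes.to_numpy() == 0).all()
        assert (cohort.truth["pgs_raw"] == 0.0).all()

    def test_zero_carrier_rate_gives_no_monogenic_truth(self):
        data = default_mapping(n_population=500, seed=2, plp_carrier_rate=0.0)
        cohort = generate_population(GeneratorConfig.from_mapping(data))
        assert not cohort.truth["carrier"].any()
        assert "monogenic" not in set(cohort.truth["etiology_truth"])


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = GeneratorConfig.default(n_population=300, seed=77)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert a.genotypes.equals(b.genotypes)
        assert a.truth.equals(b.truth)
        assert a.participants == b.participants
        assert a.rare_carriage == b.rare_carriage

    def test_different_seed_differs(self):
        a = generate_population(GeneratorConfig.default(n_population=300, seed=77))
        b = generate_population(GeneratorConfig.default(n_population=300, seed=78))
        assert not a.truth["untreated_ldl"].equals(b.truth["untreated_ldl"])


class TestStatisticalStructure:
    def test_hwe_genotype_counts(self, population_50k):
        """Per-SNV genotype counts match p^2 / 2pq / q^2 for >= 11 of 12 SNVs."""
        cfg = GeneratorConfig.default(n_population=50_000, seed=987)
        passes = 0
        n = population_50k.n
        for snv in cfg.snv_panel:
            counts = population_50k.genotypes[snv.snv_id].value_counts().reindex([0, 1, 2], fill_value=0)
            q = snv.eaf
            expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
            chi2 = ((counts.to_numpy() - expected) ** 2 / expected).sum()
            p_value = stats.chi2.sf(chi2, df=2)
            passes += p_value > 0.001
        assert passes >= 11

    def test_pgs_moments_match_closed_form(self, population_50k):
        cfg = GeneratorConfig.default(n_population=50_000, seed=987)
        raw = population_50k.truth["pgs_raw"]
        assert raw.mean() == pytest.approx(cfg.pgs_analytic_mean(), abs=0.02)
        assert raw.std() == pytest.approx(np.sqrt(cfg.pgs_analytic_variance()), abs=0.02)

    def test_parameter_recovery_within_three_se(self, population_50k):
        """OLS on the generated population recovers the configured effects."""
        import statsmodels.api as sm

        cfg = GeneratorConfig.default(n_population=50_000, seed=987)
        t = population_50k.truth
        X = sm.add_constant(
            pd.DataFrame({"pgs_raw": t["pgs_raw"], "carrier": t["carrier"].astype(float)})
        )
        fit = sm.OLS(t["untreated_ldl"], X).fit()
        assert abs(fit.params["pgs_raw"] - cfg.pgs_to_ldl_scale) < 3 * fit.bse["pgs_raw"]
        assert abs(fit.params["carrier"] - cfg.monogenic_shift_mean) < 3 * fit.bse["carrier"]

    def test_truth_labels_partition_cohort(self, small_population):
        labels = small_population.truth["etiology_truth"]
        assert set(labels) <= {"monogenic", "polygenic_tail", "neither"}
        assert len(labels) == small_population.n

    def test_statin_users_observed_is_reduced_untreated(self, small_population):
        t = small_population.truth
        users = t[t["on_statin"]]
        assert (users["observed_ldl"] < users["untreated_ldl"]).all()
        assert (t.loc[~t["on_statin"], "observed_ldl"] == t.loc[~t["on_statin"], "untreated_ldl"]).all()


class TestFixture:
    def test_reference_counts_reproduced_exactly(self, fixture_cohort):
        t = fixture_cohort.truth
        assert len(t) == REFERENCE_COHORT_COUNTS["total"]
        assert (t["etiology_truth"] == "monogenic").sum() == REFERENCE_COHORT_COUNTS["monogenic"]
        assert (t["etiology_truth"] == "polygenic_tail").sum() == REFERENCE_COHORT_COUNTS["polygenic"]
        assert (t["untreated_ldl"] >= 190).sum() == REFERENCE_COHORT_COUNTS["ldl_ge190"]
        assert (t["untreated_ldl"] >= 250).sum() == REFERENCE_COHORT_COUNTS["ldl_ge250"]

    def test_all_zero_counts_total_ten(self):
        cohort = fixture_from_counts({"total": 10})
        assert cohort.n == 10
        assert (cohort.truth["etiology_truth"] == "neither").all()
        assert not cohort.rare_carriage

    def test_inconsistent_joint_rejected(self):
        with pytest.raises(FixtureError, match="exceeds"):
            fixture_from_counts({"total": 100, "monogenic": 25, "phenotypic_fh": 40,
                                 "monogenic_phenotypic_fh": 30})

    def test_marginal_above_total_rejected(self):
        with pytest.raises(FixtureError):
            fixture_from_counts({"total": 10, "polygenic": 11})

    def test_non_monotone_strata_rejected(self):
        with pytest.raises(FixtureError, match="monotone"):
            fixture_from_counts({"total": 100, "ldl_ge190": 50, "ldl_ge_p95": 20})

    def test_unknown_count_key_rejected(self):
        with pytest.raises(FixtureError, match="unknown"):
            fixture_from_counts({"total": 10, "bogus": 1})

    def test_monogenic_subjects_carry_real_plp_variants(self, fixture_cohort):
        from hyperchol.acmg import classify_variant

        classifications = {v.key: classify_variant(v) for v in fixture_cohort.variants}
        mono_ids = fixture_cohort.truth.index[fixture_cohort.truth["etiology_truth"] == "monogenic"]
        for pid in mono_ids:
            carried = fixture_cohort.rare_carriage[pid]
            assert any(classifications[k].is_plp for k in carried)

    def test_determinism(self):
        a = fixture_from_counts()
        b = fixture_from_counts()
        assert a.truth.equals(b.truth)
        assert a.participants == b.participants
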