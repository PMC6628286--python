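import math

import numpy as np
import pandas as pd
import pytest

from conftest import FINAL_COVARIATES, random_study
from dietinflam import models
from dietinflam.models import (
    FitError,
    ModelSpec,
    crude_or_2x2,
    fit_logistic,
    lrt_interaction,
    sensitivity_suite,
    stratified_analysis,
    trend_test,
)
from dietinflam.simulate import GeneratorConfig, generate_study

# 2x2 exposure/outcome counts of a published combined-score contrast
# (highest vs lowest score category): cross-product ratio 1.3814
PRINTED_COUNTS = (499, 790, 642, 1404)


def table_2x2(a, b, c, d):
    """Expand cell counts into subject-level rows."""
    return pd.DataFrame(
        {
            "case_status": [1] * a + [0] * b + [1] * c + [0] * d,
            "exposed": [1] * (a + b) + [0] * (c + d),
        }
    )


class TestCrudeOr:
    def test_printed_counts_cross_product(self):
        out = crude_or_2x2(*PRINTED_COUNTS)
        assert out["or"] == pytest.approx(1.3814, abs=5e-5)
        lo, hi = out["ci95"]
        assert lo < out["or"] < hi

    def test_symmetric_table_is_null(self):
        assert crude_or_2x2(10, 10, 10, 10)["or"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_is_an_error(self):
        with pytest.raises(ValueError, match="zero cell"):
            crude_or_2x2(1, 1, 1, 0)

    def test_negative_cell_is_an_error(self):
        with pytest.raises(ValueError):
            crude_or_2x2(-1, 1, 1, 1)


class TestFitLogistic:
    @pytest.mark.parametrize("counts", [PRINTED_COUNTS, (30, 40, 50, 60), (12, 7, 9, 31)])
    def test_mle_matches_2x2_oracle(self, counts):
        study = table_2x2(*counts)
        result = fit_logistic(study, ModelSpec(exposure="exposed"))
        oracle = crude_or_2x2(*counts)
        assert result.terms.loc["exposed", "or"] == pytest.approx(oracle["or"], rel=1e-6)
        assert result.terms.loc["exposed", "ci_low"] == pytest.approx(oracle["ci95"][0], rel=1e-4)
        assert result.n_cases == counts[0] + counts[2]

    def test_wald_interval_construction(self):
        study = table_2x2(30, 40, 50, 60)
        t = fit_logistic(study, ModelSpec(exposure="exposed")).terms.loc["exposed"]
        assert t["ci_low"] == pytest.approx(math.exp(t["estimate"] - 1.96 * t["se"]), rel=1e-12)
        assert t["ci_high"] == pytest.approx(math.exp(t["estimate"] + 1.96 * t["se"]), rel=1e-12)

    def test_constant_exposure_is_rank_deficient(self):
        study = table_2x2(30, 40, 50, 60)
        study["exposed"] = 1
        with pytest.raises(FitError, match="rank deficient"):
            fit_logistic(study, ModelSpec(exposure="exposed"))

    def test_single_outcome_level_rejected(self):
        study = table_2x2(30, 40, 50, 60)
        study["case_status"] = 0
        with pytest.raises(FitError, match="both levels"):
            fit_logistic(study, ModelSpec(exposure="exposed"))

    def test_missing_column_named(self):
        study = table_2x2(30, 40, 50, 60)
        with pytest.raises(FitError, match="ghost"):
            fit_logistic(study, ModelSpec(exposure="exposed", covariates=("ghost",)))

    def test_unknown_level_kept_as_own_dummy(self):
        rng = np.random.default_rng(0)
        study = table_2x2(80, 90, 100, 110)
        study["family_history"] = rng.choice(["no", "yes", "unknown"], len(study))
        result = fit_logistic(
            study,
            ModelSpec(exposure="exposed", covariates=("family_history",),
                      categorical_refs={"family_history": "no"}),
        )
        assert "family_history[unknown]" in result.terms.index
        assert "family_history[yes]" in result.terms.index

    def test_missing_rows_counted_not_fatal(self):
        study = table_2x2(80, 90, 100, 110)
        study["age"] = np.random.default_rng(6).normal(60, 10, len(study))
        study.loc[:4, "age"] = np.nan
        result = fit_logistic(study, ModelSpec(exposure="exposed", covariates=("age",)))
        assert result.n_excluded == 5


class TestTrend:
    def test_null_two_level_toy_has_p_near_one(self):
        # equal case odds in both exposure groups -> exactly zero slope
        study = table_2x2(50, 100, 50, 100)
        study["quartile"] = np.where(study["exposed"] == 1, 2, 1)
        p = trend_test(study, ModelSpec(exposure="quartile", exposure_type="quartile"))
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_planted_monotone_trend_detected(self):
        rng = np.random.default_rng(4)
        n = 5000
        q = rng.integers(1, 5, n)
        eta = -1.0 + 0.25 * q
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        study = pd.DataFrame({"case_status": y, "quartile": q})
        p = trend_test(study, ModelSpec(exposure="quartile", exposure_type="quartile"))
        assert p < 0.001

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(12345)
        reps = 1000
        hits = 0
        for _ in range(reps):
            study = random_study(rng, n=250)
            study["quartile"] = rng.integers(1, 5, len(study))
            p = trend_test(study, ModelSpec(exposure="quartile", exposure_type="quartile"))
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestLrt:
    def test_degenerate_modifier_gives_null_test(self):
        study = table_2x2(50, 60, 70, 80)
        study["modifier"] = 0  # constant-zero column: no product term survives
        out = lrt_interaction(study, ModelSpec(exposure="exposed"), "modifier")
        assert out.statistic == 0.0 and out.df == 0 and out.p == 1.0

    def test_statistic_nonnegative_on_random_data(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            study = random_study(rng, n=120, beta=rng.normal(0, 0.3))
            out = lrt_interaction(
                study, ModelSpec(exposure="exposure", covariates=("modifier",)), "modifier"
            )
            assert out.statistic >= 0.0
            assert 0.0 <= out.p <= 1.0

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(777)
        reps = 1000
        hits = 0
        for _ in range(reps):
            study = random_study(rng, n=250, beta=0.3)
            out = lrt_interaction(
                study, ModelSpec(exposure="exposure", covariates=("modifier",)), "modifier"
            )
            hits += out.p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_planted_interaction_detected(self):
        # slope doubles (log 2) in the modifier stratum
        rng = np.random.default_rng(31)
        detected = 0
        reps = 20
        for _ in range(reps):
            study = random_study(rng, n=4000, beta=0.3, interaction=math.log(2))
            out = lrt_interaction(
                study, ModelSpec(exposure="exposure", covariates=("modifier",)), "modifier"
            )
            detected += out.p < 0.01
        assert detected >= 0.9 * reps


@pytest.fixture(scope="module")
def sim(request):
    return generate_study(GeneratorConfig(n_subjects=6000, seed=55))


class TestStratifiedAndSensitivity:
    def test_identical_strata_identical_ors(self):
        study = table_2x2(60, 70, 80, 90)
        study["stratum"] = "a"
        twin = study.copy()
        twin["stratum"] = "b"
        both = pd.concat([study, twin], ignore_index=True)
        out = stratified_analysis(both, ModelSpec(exposure="exposed"), "stratum")
        assert out["a"].terms.loc["exposed", "or"] == pytest.approx(
            out["b"].terms.loc["exposed", "or"], rel=1e-9)

    def test_degenerate_stratum_skipped_with_warning(self, caplog):
        study = table_2x2(60, 70, 80, 90)
        study["stratum"] = "a"
        cases_only = study[study["case_status"] == 1].copy()
        cases_only["stratum"] = "b"
        with caplog.at_level("WARNING"):
            out = stratified_analysis(
                pd.concat([study, cases_only], ignore_index=True),
                ModelSpec(exposure="exposed"), "stratum")
        assert set(out) == {"a"}
        assert any("skipped" in r.message for r in caplog.records)

    def test_independent_stratifier_keeps_or_near_pooled(self, sim):
        spec = ModelSpec(exposure="edii", covariates=("age", "sex"))
        pooled = fit_logistic(sim.study, spec)
        out = stratified_analysis(sim.study, spec, "study_area")  # no planted area effect
        b0 = pooled.terms.loc["edii", "estimate"]
        for res in out.values():
            b, se = res.terms.loc["edii", ["estimate", "se"]]
            assert abs(b - b0) < 3 * se

    def test_sensitivity_exclusion_accounting(self, sim):
        spec = ModelSpec(exposure="edii", covariates=FINAL_COVARIATES)
        out = sensitivity_suite(sim.study, spec)
        assert set(out) == {"exclude_delayed", "energy_alcohol_adjusted", "nondrinkers"}
        delayed = ((sim.study["case_status"] == 1)
                   & (sim.study["months_diagnosis_to_interview"] > 6)).sum()
        main = fit_logistic(sim.study, spec)
        assert out["exclude_delayed"].n_cases == main.n_cases - delayed
        assert "energy_nonalcohol" in out["energy_alcohol_adjusted"].terms.index
        nond = (sim.study["alcohol_g"] == 0).sum()
        assert out["nondrinkers"].n_cases + out["nondrinkers"].n_controls == nond

    def test_no_delayed_cases_reproduces_main_fit(self):
        study = table_2x2(60, 70, 80, 90)
        study["months_diagnosis_to_interview"] = np.where(study["case_status"] == 1, 2.0, np.nan)
        study["alcohol_g"] = 0.0
        study["energy_nonalcohol"] = 1800.0
        spec = ModelSpec(exposure="exposed")
        out = sensitivity_suite(study, spec)
        main = fit_logistic(study, spec)
        assert out["exclude_delayed"].terms.loc["exposed", "or"] == pytest.approx(
            main.terms.loc["exposed", "or"], rel=1e-12)

    def test_missing_columns_skip_with_warning(self, caplog):
        study = table_2x2(60, 70, 80, 90)
        with caplog.at_level("WARNING"):
            out = sensitivity_suite(study, ModelSpec(exposure="exposed"))
        assert out == {}
        assert len([r for r in caplog.records if "skipped" in r.message]) == 3


class TestParameterRecovery:
    @pytest.mark.parametrize("planted_or", [1.04, 1.14, 1.22])
    def test_per_unit_log_or_recovered_within_3_se(self, planted_or):
        config = GeneratorConfig(
            n_subjects=20000, seed=int(planted_or * 1000),
            log_or_edii=math.log(planted_or),
        )
        sim = generate_study(config)
        result = fit_logistic(sim.study, ModelSpec(exposure="edii", covariates=FINAL_COVARIATES))
        b, se = result.terms.loc["edii", ["estimate", "se"]]
        assert abs(b - math.log(planted_or)) < 3 * se
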