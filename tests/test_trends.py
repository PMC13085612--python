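import math

import numpy as np
import pytest

from cuvigil.case_store import CaseReport, CaseSet
from cuvigil.trends import (YearlyCounts, aggregate_yearly_counts,
                            fit_logistic_glm, fit_poisson_glm, period_totals,
                            tabulate_descriptives)

from conftest import report


def series(counts, start=2000, drug="X"):
    return YearlyCounts(drug, [(start + i, c) for i, c in enumerate(counts)])


class TestAggregate:
    def test_gap_years_zero_filled(self):
        cs = CaseSet([report("a", year=2019), report("b", year=2019),
                      report("c", year=2019), report("d", year=2021),
                      report("e", year=2021)])
        yc = aggregate_yearly_counts(cs, "X")
        assert yc.series == [(2019, 3), (2020, 0), (2021, 2)]

    def test_missing_years_counted_separately(self):
        cs = CaseSet([report("a", year=2019), report("b", year=None)])
        yc = aggregate_yearly_counts(cs, "X")
        assert yc.series == [(2019, 1)]
        assert yc.missing_year_reports == 1

    def test_empty_cohort(self):
        yc = aggregate_yearly_counts(CaseSet([]), "X")
        assert yc.series == []

    def test_period_totals_match_direct_count(self):
        yc = series([2, 3, 0, 5], start=1998)
        assert period_totals(yc, 2000) == (5, 5)


class TestPoissonTrend:
    def test_flat_series_irr_one(self):
        fit = fit_poisson_glm([series([5, 5, 5, 5, 5])])
        irr, _, _ = fit.irr["X"]
        assert irr == pytest.approx(1.0, abs=1e-10)

    def test_exact_doubling_recovered_to_full_precision(self):
        fit = fit_poisson_glm([series([3, 6, 12, 24, 48])])
        irr, _, _ = fit.irr["X"]
        assert irr == pytest.approx(2.0, abs=1e-10)
        # intercept at the centered midpoint is ln 12 (the mid-series count)
        assert fit.terms["intercept"].estimate == pytest.approx(math.log(12),
                                                                abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        counts = rng.poisson(8.0, size=12)
        s = series(counts.tolist())
        fit = fit_poisson_glm([s])
        years = s.years() - s.years().mean()  # same centering
        X = sm.add_constant(years)
        ref = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        assert fit.terms["year"].estimate == pytest.approx(ref.params[1],
                                                           abs=1e-8)
        assert fit.terms["year"].se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_interaction_recovers_slope_difference(self):
        s1 = series([10, 10, 11, 10, 10, 11, 10, 10], drug="A")
        s2 = series([5, 6, 8, 10, 13, 17, 22, 29], drug="B")
        fit = fit_poisson_glm([s1, s2], with_interaction=True)
        assert fit.interaction is not None
        assert fit.irr["B"][0] > fit.irr["A"][0]
        assert fit.interaction.estimate == pytest.approx(
            math.log(fit.irr["B"][0] / fit.irr["A"][0]), abs=1e-9)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_poisson_glm([series([0, 0, 0, 0])])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_glm([series([3, 4])])


class TestLogistic:
    def _cases(self, table):
        # table[[a,b],[c,d]]: rows = covariate level (F, M), cols = (yes, no)
        out = []
        k = 0
        for sex, (yes, no) in zip(("female", "male"), table):
            for serious, n in ((True, yes), (False, no)):
                for _ in range(n):
                    k += 1
                    out.append(report(f"L{k}", sex=sex, serious=serious,
                                      outcomes=()))
        return CaseSet(out)

    def test_saturated_2x2_equals_sample_odds_ratio(self):
        fit = fit_logistic_glm(self._cases([[30, 10], [10, 30]]),
                               covariates=("sex",))
        # OR for male vs female = (10*10)/(30*30) = 1/9
        assert fit.terms["sex[male]"].estimate == pytest.approx(-math.log(9),
                                                                abs=1e-8)
        assert fit.terms["sex[male]"].exp_estimate == pytest.approx(1 / 9,
                                                                    abs=1e-8)

    def test_independent_covariate_gives_or_one(self):
        fit = fit_logistic_glm(self._cases([[20, 20], [20, 20]]),
                               covariates=("sex",))
        assert fit.terms["sex[male]"].exp_estimate == pytest.approx(1.0,
                                                                    abs=1e-8)

    def test_separation_detected(self):
        with pytest.raises(ValueError, match="separation"):
            fit_logistic_glm(self._cases([[30, 0], [0, 30]]),
                             covariates=("sex",))

    def test_single_class_outcome_rejected(self):
        cs = CaseSet([report(f"S{i}", serious=True, outcomes=())
                      for i in range(10)])
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_glm(cs, covariates=("sex",))

    def test_missing_covariates_dropped_and_counted(self):
        cs = self._cases([[10, 10], [10, 10]])
        cs.reports.append(report("U1", sex="unspecified", serious=True,
                                 outcomes=()))
        fit = fit_logistic_glm(cs, covariates=("sex",))
        assert fit.n_used == 40
        assert fit.n_dropped_missing == 1

    def test_age_effect_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        ages = rng.uniform(10, 80, 300)
        p = 1 / (1 + np.exp(-(-2.0 + 0.04 * ages)))
        y = (rng.random(300) < p).astype(float)
        cs = CaseSet([report(f"H{i}", age=float(ages[i]),
                             serious=bool(y[i]), outcomes=())
                      for i in range(300)])
        fit = fit_logistic_glm(cs, covariates=("age_years",))
        X = sm.add_constant(ages)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.terms["age_years"].estimate == pytest.approx(ref.params[1],
                                                                abs=1e-7)


class TestDescriptives:
    def test_sex_counts(self):
        cs = CaseSet([report("a", sex="female"), report("b", sex="female"),
                      report("c", sex="female"), report("d", sex="male"),
                      report("e", sex="unspecified")])
        frame = tabulate_descriptives({"D": cs}, "sex")
        assert frame["D"].to_dict() == {"female": 3, "male": 1,
                                        "unspecified": 1}

    def test_single_valued_dimensions_sum_to_cohort_size(self):
        cs = CaseSet([report(f"r{i}", age=a, sex=s, country=c)
                      for i, (a, s, c) in enumerate([
                          (5, "female", "US"), (30, "male", "DE"),
                          (70, "female", "CN"), (None, "unspecified", None)])])
        for dim in ("continent", "reporter_type", "age_group", "sex",
                    "seriousness"):
            frame = tabulate_descriptives({"D": cs}, dim)
            assert frame["D"].sum() == cs.n

    def test_outcomes_dimension_is_multivalued(self):
        cs = CaseSet([report("a", outcomes=("death", "hospitalization")),
                      report("b", outcomes=("other",))])
        frame = tabulate_descriptives({"D": cs}, "outcomes")
        assert frame["D"].sum() == 3

    def test_age_groups(self):
        cs = CaseSet([report("a", age=2.0), report("b", age=40.0),
                      report("c", age=64.9), report("d", age=65.0),
                      report("e", age=None)])
        frame = tabulate_descriptives({"D": cs}, "age_group")
        assert frame["D"].to_dict() == {"<18": 1, "18-64": 2, ">=65": 1,
                                        "unknown": 1}
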