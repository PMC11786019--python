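import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hdmtx.assoc import (
    AssociationResult,
    ContingencyTable2x2,
    adjust_multiplicity,
    course_level_test,
    fisher_exact,
    fisher_pvalue,
    genetic_coding,
    pk_linear_model,
    pk_mixed_model,
    relapse_cox,
    shapiro_gate,
)
from hdmtx.cohort import CohortConfig, simulate_cohort
from hdmtx.exceptions import (
    CollinearityError,
    InsufficientDataError,
    InvalidInputError,
    NoEventsError,
    ZeroMarginError,
)


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration over all
    tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = []
    p_obs = None
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        probs.append(p)
        if x == a:
            p_obs = p
    # sum all tables no more probable than the observed (with a tie guard)
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


class TestGeneticCoding:
    def test_codings(self):
        g = np.array([0, 1, 2])
        assert (genetic_coding(g, "additive") == [0, 1, 2]).all()
        assert (genetic_coding(g, "dominant") == [0, 1, 1]).all()
        assert (genetic_coding(g, "recessive") == [0, 0, 1]).all()

    def test_dominant_plus_recessive_equals_additive(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 500)
        total = genetic_coding(g, "dominant") + genetic_coding(g, "recessive")
        assert (total == genetic_coding(g, "additive")).all()

    def test_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            genetic_coding([0, 3], "additive")
        with pytest.raises(InvalidInputError):
            genetic_coding([0, 1], "codominant")


class TestFisherExact:
    def test_toxicity_contingency_table(self):
        # severe HEM in rs717620 T carriers (20/27) vs CC homozygotes (20/53)
        res = fisher_exact(
            ContingencyTable2x2(20, 7, 20, 33, ("T carriers", "CC"), "severe HEM")
        )
        assert res.estimate == pytest.approx(4.62, abs=0.01)
        assert res.pvalue == pytest.approx(4.11e-3, rel=0.01)
        assert res.ci_low == pytest.approx(1.54, abs=0.01)
        assert res.ci_high == pytest.approx(15.39, abs=0.01)
        assert "T carriers vs CC" in res.direction

    def test_identical_rows_are_null(self):
        res = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert res.estimate == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_margin_raises_but_p_defined(self):
        table = ContingencyTable2x2(0, 0, 10, 5)
        with pytest.raises(ZeroMarginError):
            fisher_exact(table)
        assert fisher_pvalue(table) == pytest.approx(1.0)

    def test_p_matches_enumeration_on_small_tables(self):
        # subset here; the acceptance suite sweeps every table with n <= 16
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            table = ContingencyTable2x2(a, b, c, d)
            assert fisher_pvalue(table) == pytest.approx(
                enumerate_fisher_p(a, b, c, d), rel=1e-8, abs=1e-12
            )

    @given(st.integers(1, 12), st.integers(1, 12), st.integers(1, 12), st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_cmle_shrinks_toward_one(self, a, b, c, d):
        # the conditional MLE lies between 1 and the unconditional sample OR
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        sample_or = (a * d) / (b * c)
        lo, hi = sorted([1.0, sample_or])
        assert lo - 1e-9 <= res.estimate <= hi + 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestRankTests:
    def test_small_separated_groups_exact_p(self):
        # complete separation at n=3+3 is NOT significant: exact rank p = 0.1
        res = course_level_test({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert res.pvalue == pytest.approx(0.1)

    def test_empty_group_is_an_error(self):
        with pytest.raises(InvalidInputError):
            course_level_test({"a": [1, 2], "b": []})

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = course_level_test({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.pvalue == 1.0
        assert res.degenerate

    def test_dunn_z_squared_matches_kw_for_two_groups(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.5, 1, 25)}
        res = course_level_test(groups)
        z = res.dunn["z"].iloc[0]
        assert z**2 == pytest.approx(res.statistic, rel=1e-9)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 400
        for _ in range(reps):
            g = {"a": rng.normal(size=25), "b": rng.normal(size=25)}
            if course_level_test(g).pvalue < 0.05:
                rejections += 1
        assert 0.02 < rejections / reps < 0.08

    def test_dunn_adjustment_methods(self):
        rng = np.random.default_rng(10)
        groups = {k: rng.normal(size=15) for k in "abcd"}
        bon = course_level_test(groups, adjust="bonferroni").dunn
        holm = course_level_test(groups, adjust="holm").dunn
        raw = course_level_test(groups, adjust="none").dunn
        assert (bon["p_adj"] >= raw["p_adj"] - 1e-12).all()
        assert (holm["p_adj"] <= bon["p_adj"] + 1e-12).all()


@pytest.fixture(scope="module")
def cohort_frame():
    pts = simulate_cohort(CohortConfig(n=2000, seed=31)).patients
    pts["abcc4_gg"] = genetic_coding(pts["rs7317112"], "recessive")
    return pts


@pytest.fixture(scope="module")
def relapse_frame():
    pts = simulate_cohort(CohortConfig(n=1500, seed=32)).patients
    pts["slco_dom"] = genetic_coding(pts["rs4149056"], "dominant")
    return pts


class TestLinearModels:

    def test_configured_effects_recovered_multivariate(self, cohort_frame):
        results = pk_linear_model(
            cohort_frame, "true_mean_level_24h_um", ["age_years", "abcc4_gg"],
            multivariate=True, log10_endpoint=True,
        )
        by_term = {r.term: r for r in results}
        # older patients have higher levels; GG genotype lower levels
        assert by_term["age_years"].estimate > 0
        assert by_term["abcc4_gg"].estimate < 0
        assert by_term["age_years"].extra["p_lrt"] < 1e-3
        assert by_term["abcc4_gg"].extra["p_lrt"] < 1e-3

    def test_interaction_term(self, cohort_frame):
        results = pk_linear_model(
            cohort_frame, "true_mean_cl", ["age_years", "abcc4_gg"],
            multivariate=True, interactions=[("age_years", "abcc4_gg")],
        )
        terms = {r.term for r in results}
        assert "age_years:abcc4_gg" in terms

    def test_collinear_design_rejected(self, cohort_frame):
        df = cohort_frame.assign(age_copy=cohort_frame["age_years"] * 2)
        with pytest.raises(CollinearityError):
            pk_linear_model(df, "true_mean_cl", ["age_years", "age_copy"],
                            multivariate=True)

    def test_insufficient_n(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            pk_linear_model(df, "y", ["x"])

    def test_mixed_model_random_intercept_nonnegative(self, small_cohort):
        conc = small_cohort.concentrations
        lev24 = conc[conc["time_h"] == 24].copy()
        ages = small_cohort.patients.set_index("patient_id")["age_years"]
        lev24["age_years"] = lev24["patient_id"].map(ages)
        results = pk_mixed_model(lev24, "conc_um", ["age_years"],
                                 group="patient_id", log10_endpoint=True)
        assert results[0].extra["re_var"] >= 0.0
        assert np.isfinite(results[0].estimate)


class TestCox:
    def test_protective_allele_direction(self, relapse_frame):
        res = relapse_cox(relapse_frame, covariates=["slco_dom"])[0]
        assert res.estimate < 1.0
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_inversion_symmetry(self, relapse_frame):
        # relabeling the exposed group inverts the hazard ratio exactly
        df = relapse_frame.copy()
        df["inv"] = 1.0 - df["slco_dom"]
        hr = relapse_cox(df, covariates=["slco_dom"])[0].estimate
        hr_inv = relapse_cox(df, covariates=["inv"])[0].estimate
        assert hr * hr_inv == pytest.approx(1.0, abs=1e-8)

    def test_zero_events_rejected(self, relapse_frame):
        df = relapse_frame.copy()
        df["relapse"] = 0
        with pytest.raises(NoEventsError):
            relapse_cox(df, covariates=["slco_dom"])

    def test_nonpositive_times_rejected(self, relapse_frame):
        df = relapse_frame.head(50).copy()
        df.loc[df.index[0], "followup_years"] = 0.0
        with pytest.raises(InvalidInputError):
            relapse_cox(df, covariates=["slco_dom"])


class TestMultiplicity:
    def test_bonferroni_with_explicit_family(self):
        out = adjust_multiplicity([0.004], m=10)
        assert out["p_adj"].iloc[0] == pytest.approx(0.04)
        assert bool(out["significant"].iloc[0])
        # 0.004 < 0.05/10 = 0.005: significant at the family threshold
        assert 0.004 < 0.05 / 10

    def test_all_ones_never_significant(self):
        out = adjust_multiplicity([1.0, 1.0, 1.0])
        assert not out["significant"].any()

    def test_single_test_identity(self):
        out = adjust_multiplicity([0.03], m=1)
        assert out["p_adj"].iloc[0] == pytest.approx(0.03)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            adjust_multiplicity([])
        with pytest.raises(InvalidInputError):
            adjust_multiplicity([1.5])
        with pytest.raises(InvalidInputError):
            adjust_multiplicity([0.1, 0.2], m=1)


class TestResultContract:
    def test_ci_must_bracket_estimate(self):
        with pytest.raises(InvalidInputError):
            AssociationResult(2.0, 3.0, 4.0, 0.5, "t", 10, "d")

    def test_shapiro_gate_warns_only(self):
        rng = np.random.default_rng(11)
        skewed = rng.lognormal(0, 1.5, 200)
        with pytest.warns(UserWarning, match="normality"):
            res = shapiro_gate(skewed)
        assert res.pvalue < 0.05
        normalish = rng.normal(0, 1, 200)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = shapiro_gate(normalish)
        assert res2.pvalue > 0.001
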