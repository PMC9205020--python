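"""Exposure preprocessing and regression surfaces: unit-conversion and
quartile oracles, 2x2 logistic closed form, BH-FDR brute-force oracle,
correlation fixture, imputation policy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metalage import (
    creatinine_correct,
    fdr_adjust,
    fit_linear,
    fit_logistic,
    impute_covariates,
    pearson_correlation_matrix,
    quartile_encode,
    trend_test,
)
from metalage.cohort import DataError
from metalage.exposure import design_matrix, metal_outcome_table


class TestCreatinineCorrection:
    def test_unit_identity(self):
        # 1 ug/L at 100 mg/dL creatinine (= 1 g/L) is 1 ug/g
        assert creatinine_correct(1.0, 100.0) == pytest.approx(1.0)

    def test_hand_conversion(self):
        assert creatinine_correct(0.5, 50.0) == pytest.approx(1.0)

    def test_zero_creatinine_is_error(self):
        with pytest.raises(DataError):
            creatinine_correct(np.array([1.0]), np.array([0.0]))


class TestQuartileEncode:
    def test_one_to_eight(self):
        enc = quartile_encode(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(enc.quartile, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DataError):
            quartile_encode(np.full(20, 3.0))

    def test_lognormal_sample_splits_into_equal_quarters(self):
        rng = np.random.default_rng(10)
        v = np.exp(rng.normal(0, 1, 1000))
        enc = quartile_encode(v)
        counts = np.bincount(enc.quartile, minlength=5)[1:]
        np.testing.assert_array_equal(counts, [250, 250, 250, 250])

    def test_weighted_cutpoints_shift_with_weights(self):
        v = np.arange(1.0, 101.0)
        w = np.where(v <= 50, 10.0, 1.0)  # mass concentrated low
        enc_w = quartile_encode(v, weights=w)
        enc_u = quartile_encode(v)
        assert enc_w.quartile_cutpoints[1] < enc_u.quartile_cutpoints[1]

    def test_partitions_whole_sample(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=403)
        enc = quartile_encode(v)
        counts = np.bincount(enc.quartile, minlength=5)[1:]
        assert counts.sum() == 403
        assert counts.max() - counts.min() <= 1


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # a=10 exposed cases, b=20 exposed non-cases, c=20, d=10
        y = np.array([1] * 10 + [0] * 20 + [1] * 20 + [0] * 10)
        x = np.array([1] * 30 + [0] * 30)
        res = fit_logistic(y, x.astype(float))[0]
        assert res.or_or_beta == pytest.approx((10 * 10) / (20 * 20), rel=1e-6)

    def test_constant_weights_leave_estimate_unchanged(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=400)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.5 * x - 1))))
        unw = fit_logistic(y, x)[0]
        w = fit_logistic(y, x, weights=np.full(400, 3.7))[0]
        assert w.estimate == pytest.approx(unw.estimate, abs=1e-8)

    def test_null_exposure_nominal_type_one_error(self):
        """Independent exposure: rejection rate at alpha=0.05 stays near 5%
        over 200 replicates."""
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(200):
            x = rng.normal(size=300)
            y = rng.binomial(1, 0.3, size=300)
            rejections += fit_logistic(y, x)[0].p_value < 0.05
        assert 0.03 * 200 * 0.0 <= rejections <= 0.10 * 200  # <= 2x nominal

    def test_separation_raises_model_error(self):
        from metalage.exposure import ModelError
        y = np.array([0] * 20 + [1] * 20)
        x = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(ModelError):
            fit_logistic(y, x)


class TestLinear:
    def test_recovers_slope_two(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=2000)
        y = 2.0 * x + rng.normal(0, 1e-6, size=2000)
        res = fit_linear(y, x)[0]
        assert res.or_or_beta == pytest.approx(2.0, abs=1e-4)

    def test_fixture_matches_normal_equations(self):
        # n = 20 fixture; oracle solves (X'X)^{-1} X'y directly
        rng = np.random.default_rng(15)
        x = rng.uniform(-2, 2, 20)
        z = rng.uniform(0, 1, 20)
        y = 1.5 + 0.8 * x - 0.4 * z + rng.normal(0, 0.3, 20)
        X = np.column_stack([np.ones(20), x, z])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        res = fit_linear(y, x, covariates=pd.DataFrame({"z": z}))[0]
        assert res.estimate == pytest.approx(beta_oracle[1], rel=1e-8)


class TestTrend:
    def test_monotone_risk_gives_tiny_p(self):
        rng = np.random.default_rng(16)
        v = rng.normal(size=4000)
        enc = quartile_encode(v)
        p = 1 / (1 + np.exp(-(-2.0 + 0.5 * enc.quartile)))
        y = rng.binomial(1, p)
        assert trend_test(y, enc) < 1e-3

    def test_wald_statistic_matches_manual_computation(self):
        import statsmodels.api as sm
        from scipy import stats
        rng = np.random.default_rng(17)
        v = rng.normal(size=1000)
        enc = quartile_encode(v)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.3 * enc.quartile))))
        p_pkg = trend_test(y, enc)
        score = enc.quartile.astype(float)
        fit = sm.GLM(y, sm.add_constant(score), family=sm.families.Binomial()).fit()
        z = fit.params[1] / np.sqrt(np.asarray(fit.cov_params())[1, 1])
        p_oracle = 2 * stats.norm.sf(abs(z))
        assert p_pkg == pytest.approx(p_oracle, rel=1e-8)

    def test_permuted_exposure_keeps_p_unextreme(self):
        rng = np.random.default_rng(18)
        small = 0
        for _ in range(50):
            v = rng.normal(size=400)
            y = rng.binomial(1, 0.3, size=400)
            small += trend_test(y, quartile_encode(v)) < 0.05
        assert small <= 8  # ~2.5 expected under the null


def _bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestFDR:
    def test_worked_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            fdr_adjust([0.5, 1.2])

    def test_matches_enumeration_oracle_for_all_orderings(self):
        """Exhaustive check against the step-up oracle for every permutation
        of p-value sets of size up to 6."""
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.9]
        for size in range(1, 7):
            for perm in itertools.permutations(base[:size]):
                np.testing.assert_allclose(fdr_adjust(list(perm)),
                                           _bh_oracle(list(perm)), rtol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw(self, ps):
        adj = fdr_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestCorrelation:
    def test_proportional_columns(self):
        x = np.arange(1.0, 11.0)
        c = pearson_correlation_matrix(np.column_stack([x, 2 * x]))
        assert c.iloc[0, 1] == pytest.approx(1.0)

    def test_five_point_fixture_matches_sum_formula(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        c = pearson_correlation_matrix(np.column_stack([a, b]))
        assert c.iloc[0, 1] == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_column_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            c = pearson_correlation_matrix(
                np.column_stack([np.arange(5.0), np.full(5, 2.0)]))
        assert np.isnan(c.iloc[0, 1])


class TestImputation:
    def test_median_for_continuous(self, small_cohort):
        df = small_cohort.head(3).copy()
        df.loc[df.index[1], "bmi"] = np.nan
        df["bmi"] = [1.0, np.nan, 3.0]
        out = impute_covariates(df)
        assert out["bmi"].tolist() == [1.0, 2.0, 3.0]

    def test_missing_indicator_for_categorical(self, small_cohort):
        df = small_cohort.head(4).copy()
        df.loc[df.index[2], "education"] = np.nan
        out = impute_covariates(df)
        assert out.loc[out.index[2], "education"] == "missing"
        d = design_matrix(out)
        assert "education_missing" in d.columns

    def test_identity_when_complete(self, small_cohort):
        out = impute_covariates(small_cohort)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_fully_missing_column_is_error(self, small_cohort):
        df = small_cohort.head(5).copy()
        df["pir"] = np.nan
        with pytest.raises(DataError):
            impute_covariates(df)


class TestAnalysisTables:
    def test_metal_table_shape_and_fdr_monotone(self, scored_cohort, scored_design):
        w = scored_cohort["survey_weight"].to_numpy()
        tab = metal_outcome_table(scored_cohort, "oa", "logistic",
                                  scored_design, w)
        assert len(tab) == 9 * 4  # 1 continuous + 3 quartile terms per metal
        cont = tab[tab["term"].str.endswith("_ln")]
        assert (cont["p_fdr"] >= cont["p_value"] - 1e-12).all()

    def test_configured_risk_metals_positive(self, scored_cohort, scored_design):
        """Metals given positive generating paths show OR > 1 on Ln scale."""
        tab = metal_outcome_table(scored_cohort, "oa", "logistic", scored_design,
                                  scored_cohort["survey_weight"].to_numpy())
        cont = tab.set_index("term")
        for m in ("cd", "co", "cs"):
            assert cont.loc[f"{m}_ln", "or_or_beta"] > 1.0
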