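"""Aging scores: Klemera-Doubal fit/score against closed-form oracles,
phenotypic-age transcription oracle, shrinkage and monotonicity properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metalage import (
    KlemeraDoubal,
    SimulationConfig,
    attach_aging_markers,
    compute_biological_age,
    compute_phenotypic_age,
    fit_kdm,
    generate_cohort,
)
from metalage.aging import (
    FitError,
    KDMParameters,
    PHENO_AGE_COEFFICIENT,
    PHENO_COEFFICIENTS,
    PHENO_INTERCEPT,
)
from metalage.cohort import DataError, KDM_BIOMARKERS, PHENO_BIOMARKERS


def _linear_panel(rng, n=200, m=8, jitter=1e-9):
    """Biomarkers exactly linear in age (tiny jitter keeps RMSE positive)."""
    ca = rng.uniform(20, 80, size=n)
    k = rng.uniform(-0.5, 0.8, size=m)
    k[np.abs(k) < 0.05] = 0.1
    q = rng.uniform(-5, 120, size=m)
    X = q + np.outer(ca, k) + rng.normal(0, jitter, size=(n, m))
    return X, ca, k, q


class TestFitKDM:
    def test_noise_free_recovers_generating_slopes(self):
        rng = np.random.default_rng(0)
        X, ca, k, q = _linear_panel(rng)
        params = fit_kdm(X, ca)
        np.testing.assert_allclose(params.k, k, rtol=1e-6)
        np.testing.assert_allclose(params.q, q, rtol=1e-6, atol=1e-6)

    def test_single_biomarker_matches_normal_equation_oracle(self):
        # 10-point fixture; oracle = hand-coded OLS normal equations
        ca = np.array([23.0, 31.0, 38.0, 44.0, 50.0, 55.0, 61.0, 66.0, 72.0, 79.0])
        x = np.array([4.1, 5.0, 5.2, 6.3, 6.1, 7.4, 7.2, 8.5, 8.9, 9.8])
        ca_f = np.concatenate([ca, ca, ca])  # n >= 30 for the fit
        x_f = np.concatenate([x, x + 0.05, x - 0.05])
        n = len(ca_f)
        sxx = np.sum((ca_f - ca_f.mean()) ** 2)
        k_oracle = np.sum((ca_f - ca_f.mean()) * (x_f - x_f.mean())) / sxx
        q_oracle = x_f.mean() - k_oracle * ca_f.mean()
        resid = x_f - q_oracle - k_oracle * ca_f
        s_oracle = np.sqrt(np.sum(resid**2) / (n - 2))
        params = fit_kdm(x_f[:, None], ca_f)
        assert params.k[0] == pytest.approx(k_oracle, rel=1e-10)
        assert params.q[0] == pytest.approx(q_oracle, rel=1e-10)
        assert params.s[0] == pytest.approx(s_oracle, rel=1e-10)

    def test_degenerate_age_range_is_fit_error(self):
        X = np.random.default_rng(1).normal(size=(40, 3))
        with pytest.raises(FitError):
            fit_kdm(X, np.full(40, 50.0))

    def test_small_sample_rejected(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        with pytest.raises(FitError):
            fit_kdm(X, np.linspace(20, 80, 10))

    def test_zero_variance_biomarker_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        ca = rng.uniform(20, 80, 100)
        X = np.column_stack([1 + 0.2 * ca + rng.normal(0, 1, 100), np.full(100, 7.0)])
        with pytest.warns(UserWarning, match="zero variance"):
            params = fit_kdm(X, ca)
        assert params.m == 1

    def test_parameters_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        X, ca, _, _ = _linear_panel(rng, jitter=0.5)
        params = fit_kdm(X, ca)
        path = tmp_path / "kdm.yaml"
        params.to_yaml(path)
        back = KDMParameters.from_yaml(path)
        np.testing.assert_allclose(back.k, params.k)
        assert back.s_ba2 == pytest.approx(params.s_ba2)
        ba_a = compute_biological_age(params, X, ca)
        ba_b = compute_biological_age(back, X, ca)
        np.testing.assert_allclose(ba_a, ba_b)


class TestBiologicalAge:
    def test_noise_free_participant_scores_exactly_chronological_age(self):
        """If x_j = q_j + k_j*ca for every biomarker, the corrected estimator
        collapses to ca (numerator = ca * denominator)."""
        params = KDMParameters(
            biomarker_names=("a", "b", "c"),
            k=np.array([0.2, -0.4, 1.1]), q=np.array([3.0, 90.0, -2.0]),
            s=np.array([0.7, 2.0, 1.3]), r=np.array([0.5, -0.6, 0.7]),
            r_char=0.6, s_ba2=25.0, s_ba2_raw=25.0,
            ca_min=20, ca_max=80, m=3, n=1000,
        )
        for ca in (25.0, 47.5, 79.0):
            x = params.q + params.k * ca
            ba = compute_biological_age(params, x, ca)
            assert ba[0] == pytest.approx(ca, abs=1e-10)

    def test_fixture_matches_direct_transcription(self):
        """Oracle: a one-expression transcription of the corrected estimator."""
        k = np.array([0.03, -0.01, 0.5, 0.2, 0.9, -0.3, 0.08, 0.6])
        q = np.array([-1.5, 4.8, 95.0, 160.0, 8.0, 55.0, 4.5, 0.7])
        s = np.array([0.6, 0.25, 12.0, 35.0, 4.0, 18.0, 0.45, 0.15])
        params = KDMParameters(
            biomarker_names=tuple("abcdefgh"), k=k, q=q, s=s,
            r=np.full(8, 0.3), r_char=0.5, s_ba2=40.0, s_ba2_raw=40.0,
            ca_min=20, ca_max=80, m=8, n=5000,
        )
        x = np.array([-0.9, 4.2, 120.0, 210.0, 15.0, 71.0, 5.9, 1.1])
        ca = 61.0
        oracle = (np.sum((x - q) * k / s**2) + ca / 40.0) / (
            np.sum((k / s) ** 2) + 1.0 / 40.0)
        assert compute_biological_age(params, x, ca)[0] == pytest.approx(oracle, rel=1e-12)

    def test_huge_shrinkage_variance_converges_to_uncorrected_estimate(self):
        k = np.array([0.5, -0.2])
        q = np.array([10.0, 50.0])
        s = np.array([2.0, 3.0])
        x = np.array([40.0, 38.0])
        base = KDMParameters(("a", "b"), k, q, s, np.array([0.4, -0.3]),
                             0.5, 1e12, 1e12, 20, 80, 2, 100)
        ba_e = np.sum((x - q) * k / s**2) / np.sum((k / s) ** 2)
        assert compute_biological_age(base, x, 30.0)[0] == pytest.approx(ba_e, rel=1e-6)

    def test_output_lies_between_uncorrected_estimate_and_chronological_age(self):
        """The corrected score is a precision-weighted average of BA_E and CA,
        so it can never leave the interval they span."""
        rng = np.random.default_rng(4)
        X, ca, _, _ = _linear_panel(rng, n=300, jitter=3.0)
        params = fit_kdm(X, ca)
        ba = compute_biological_age(params, X, ca)
        from metalage.aging import _ba_e
        ba_e = _ba_e(X, params.k, params.q, params.s)
        lo = np.minimum(ba_e, ca) - 1e-9
        hi = np.maximum(ba_e, ca) + 1e-9
        assert ((ba >= lo) & (ba <= hi)).all()

    def test_mean_bias_small_on_linear_training_sample(self):
        """Scoring the training sample itself: mean(BA - CA) ~ 0."""
        rng = np.random.default_rng(5)
        X, ca, _, _ = _linear_panel(rng, n=5000, jitter=5.0)
        params = fit_kdm(X, ca)
        ba = compute_biological_age(params, X, ca)
        assert abs(np.mean(ba - ca)) < 0.5

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        X, ca, _, _ = _linear_panel(rng, n=100, jitter=2.0)
        params = fit_kdm(X, ca)
        perm = rng.permutation(100)
        ba = compute_biological_age(params, X, ca)
        ba_p = compute_biological_age(params, X[perm], ca[perm])
        np.testing.assert_allclose(ba[perm], ba_p)


def _pheno_oracle(x9, ca):
    """Independent literal transcription of the printed closed form."""
    xb = (-19.907 - 0.0336 * x9[0] + 0.0095 * x9[1] + 0.1953 * x9[2]
          + 0.0954 * x9[3] - 0.0120 * x9[4] + 0.0268 * x9[5]
          + 0.3306 * x9[6] + 0.00188 * x9[7] + 0.0554 * x9[8]
          + 0.0804 * ca)
    inner = np.exp(-1.51714 * np.exp(xb) / 0.0076927)
    return 141.50 + np.log(-0.00553 * np.log(inner)) / 0.09165


class TestPhenotypicAge:
    def test_matches_literal_transcription_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x9 = np.array([
                rng.uniform(35, 52), rng.uniform(40, 130), rng.uniform(3.5, 9),
                rng.uniform(-3, 1.5), rng.uniform(15, 50), rng.uniform(78, 98),
                rng.uniform(11, 16), rng.uniform(30, 130), rng.uniform(3, 12)])
            ca = rng.uniform(20, 80)
            got = compute_phenotypic_age(x9, ca)[0]
            assert got == pytest.approx(_pheno_oracle(x9, ca), abs=1e-10)

    def test_higher_albumin_lowers_phenotypic_age(self):
        base = np.array([45.0, 80.0, 5.0, 0.0, 30.0, 88.0, 13.0, 70.0, 7.0])
        bumped = base.copy()
        bumped[0] += 1.0
        assert compute_phenotypic_age(bumped, 50.0)[0] < compute_phenotypic_age(base, 50.0)[0]

    def test_strictly_increasing_in_chronological_age(self):
        base = np.array([45.0, 80.0, 5.0, 0.0, 30.0, 88.0, 13.0, 70.0, 7.0])
        ages = np.arange(20.0, 81.0, 5.0)
        vals = [compute_phenotypic_age(base, a)[0] for a in ages]
        assert np.all(np.diff(vals) > 0)

    @given(
        j=st.integers(0, 8),
        bump=st.floats(0.1, 5.0),
        ca=st.floats(20, 80),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_each_biomarker_with_coefficient_sign(self, j, bump, ca):
        base = np.array([45.0, 80.0, 5.0, 0.0, 30.0, 88.0, 13.0, 70.0, 7.0])
        bumped = base.copy()
        bumped[j] += bump
        delta = compute_phenotypic_age(bumped, ca)[0] - compute_phenotypic_age(base, ca)[0]
        assert np.sign(delta) == np.sign(PHENO_COEFFICIENTS[j])

    def test_nonfinite_input_names_offender(self):
        bad = np.array([45.0, np.inf, 5.0, 0.0, 30.0, 88.0, 13.0, 70.0, 7.0])
        with pytest.raises(DataError):
            compute_phenotypic_age(bad, 50.0)


class TestAttachMarkers:
    def test_single_row_cohort_gains_marker_columns(self, small_cohort):
        params = fit_kdm(small_cohort[list(KDM_BIOMARKERS)],
                         small_cohort["age"].to_numpy())
        one = small_cohort.iloc[[0]]
        out = attach_aging_markers(one, params)
        assert {"biological_age", "phenotypic_age", "telomere_ts"} <= set(out.columns)
        assert len(out) == 1

    def test_recovers_latent_truth(self, scored_cohort):
        r = np.corrcoef(scored_cohort["biological_age"], scored_cohort["truth_ba"])[0, 1]
        assert r > 0.8
        r2 = np.corrcoef(scored_cohort["phenotypic_age"], scored_cohort["truth_ba"])[0, 1]
        assert r2 > 0.8

    def test_empty_cohort_rejected(self, small_cohort):
        with pytest.raises(Exception):
            attach_aging_markers(small_cohort.iloc[0:0])

    def test_model_results_interface(self, small_cohort):
        model = KlemeraDoubal(small_cohort[list(KDM_BIOMARKERS)],
                              small_cohort["age"].to_numpy())
        res = model.fit()
        assert res.fittedvalues.shape == (len(small_cohort),)
        text = res.summary()
        assert "r_char" in text and "kdm_sbp" in text
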