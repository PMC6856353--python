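"""Twin Cholesky model: expected covariance, FIML likelihood, derived
correlations, nested tests and fit indices."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import twinmap as tm
from twinmap.cholesky import CholeskyTwinModel, fit_saturated

A_EX = np.array([[0.6, 0.0], [0.3, 0.4]])
E_EX = np.array([[0.8, 0.0], [0.1, 0.5]])


class TestExpectedCovariance:
    def test_no_familial_variance_is_block_identity(self):
        S = tm.expected_covariance(np.zeros((2, 2)), None, np.eye(2), "MZ")
        assert np.allclose(S, np.eye(4))

    @pytest.mark.parametrize("zyg,cross", [
        ("MZ", [[0.36, 0.18], [0.18, 0.25]]),
        ("DZ", [[0.18, 0.09], [0.09, 0.125]]),
    ])
    def test_worked_blocks(self, zyg, cross):
        S = tm.expected_covariance(A_EX, None, E_EX, zyg)
        assert np.allclose(S[:2, :2], [[1.00, 0.26], [0.26, 0.51]])
        assert np.allclose(S[:2, 2:], cross)
        assert np.allclose(S, S.T)

    def test_mz_cross_equals_a_block_dz_half(self):
        AA = A_EX @ A_EX.T
        mz = tm.expected_covariance(A_EX, None, E_EX, "MZ")
        dz = tm.expected_covariance(A_EX, None, E_EX, "DZ")
        assert np.array_equal(mz[:2, 2:], AA)
        assert np.array_equal(dz[:2, 2:], 0.5 * AA)

    def test_nonfinite_paths_rejected(self):
        bad = A_EX.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            tm.expected_covariance(bad, None, E_EX, "MZ")


class TestFimlLoglik:
    def test_complete_data_equals_direct_density(self, reported_paths):
        A, E = reported_paths
        co = tm.simulate_bivariate_cohort(A, E, n_mz=40, n_dz=40, seed=2)
        model = tm.fit_model(co, components="AE", n_starts=2, seed=0)
        mu = np.concatenate([model.means_] * 2)
        sig = {z: tm.expected_covariance(model.a_, None, model.e_, z)
               for z in ("MZ", "DZ")}
        direct = sum(
            multivariate_normal.logpdf(co.stacked()[i], mu, sig[co.zygosity[i]])
            for i in range(co.n_pairs)
        )
        assert abs(direct - model.loglik_) < 1e-8

    def test_singleton_contributes_marginal_density(self, reported_paths):
        A, E = reported_paths
        co = tm.simulate_bivariate_cohort(A, E, n_mz=30, n_dz=30, seed=3)
        model = tm.fit_model(co, components="AE", n_starts=2, seed=0)
        # delete one co-twin; the pair's term must become the 2-D marginal
        values = co.values.copy()
        values[0, 1, :] = np.nan
        co_miss = tm.TwinCohort(values, co.zygosity)
        mu = np.concatenate([model.means_] * 2)
        sig = {z: tm.expected_covariance(model.a_, None, model.e_, z)
               for z in ("MZ", "DZ")}
        direct = multivariate_normal.logpdf(
            values[0, 0], mu[:2], sig[co.zygosity[0]][:2, :2]
        )
        for i in range(1, co.n_pairs):
            direct += multivariate_normal.logpdf(
                co.stacked()[i], mu, sig[co.zygosity[i]]
            )
        assert abs(direct - model.loglikelihood(co_miss)) < 1e-8

    def test_truth_beats_perturbed_parameters(self, reported_paths):
        """ML consistency: at 1,000 pairs the generating parameters should
        out-score a +0.2 path perturbation nearly always."""
        A, E = reported_paths
        truth = CholeskyTwinModel(components="AE")
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            co = tm.simulate_bivariate_cohort(A, E, n_mz=500, n_dz=500, seed=seed)
            stats_list = tm.cholesky.pattern_statistics(co.stacked(), co.zygosity)
            mu = np.zeros(4)
            ll_true = tm.cholesky._loglik_from_stats(
                stats_list,
                {z: tm.expected_covariance(A, None, E, z) for z in ("MZ", "DZ")},
                mu,
            )
            Ap = A + 0.2 * np.tril(np.ones((2, 2)))
            Ep = E + 0.2 * np.tril(np.ones((2, 2)))
            ll_pert = tm.cholesky._loglik_from_stats(
                stats_list,
                {z: tm.expected_covariance(Ap, None, Ep, z) for z in ("MZ", "DZ")},
                mu,
            )
            wins += ll_true >= ll_pert
        assert wins >= 0.95 * n_rep


def _derived_model(a, e, c=None):
    m = CholeskyTwinModel()
    m.n_variables_ = 2
    m.a_ = np.asarray(a, dtype=float)
    m.e_ = np.asarray(e, dtype=float)
    m.c_ = None if c is None else np.asarray(c, dtype=float)
    m._c_mat = np.zeros((2, 2)) if c is None else np.asarray(c, dtype=float)
    m._derive()
    return m


class TestDerivedQuantities:
    @pytest.mark.parametrize("a,expected", [
        ([[0.6, 0], [0.0, 0.4]], 0.0),        # no shared genetic path
        ([[0.6, 0], [0.3, 0.0]], 1.0),        # perfect genetic overlap
        ([[0.6, 0], [0.3, 0.4]], 0.6),        # 0.18 / sqrt(0.36 * 0.25)
    ])
    def test_genetic_correlation(self, a, expected):
        m = _derived_model(a, E_EX)
        assert tm.genetic_correlation(m) == pytest.approx(expected, abs=1e-12)

    def test_zero_genetic_variance_is_undefined(self):
        m = _derived_model([[0.0, 0], [0.0, 0.4]], E_EX)
        assert np.isnan(tm.genetic_correlation(m))

    def test_bivariate_heritability_worked_example(self):
        m = _derived_model(A_EX, E_EX)
        assert tm.bivariate_heritability(m) == pytest.approx(
            0.18 / np.sqrt(1.00 * 0.51), abs=1e-12)
        assert m.bivariate_environmentality_ == pytest.approx(
            0.08 / np.sqrt(0.51), abs=1e-12)
        # decomposition identity: shares sum to the implied correlation
        assert (m.bivariate_heritability_ + m.bivariate_c_
                + m.bivariate_environmentality_) == pytest.approx(
            m.implied_phenotypic_correlation_, abs=1e-6)
        assert m.implied_phenotypic_correlation_ == pytest.approx(
            0.26 / np.sqrt(0.51), abs=1e-12)

    def test_zero_cross_paths_give_zero_bivariate_heritability(self):
        m = _derived_model([[0.6, 0], [0.0, 0.4]], [[0.8, 0], [0.0, 0.5]])
        assert tm.bivariate_heritability(m) == 0.0

    def test_standardized_shares_sum_to_one(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=3, seed=0)
        assert np.allclose(fit.variance_shares_.sum(axis=1), 1.0, atol=1e-6)
        assert abs(fit.rg_) <= 1.0 and abs(fit.re_) <= 1.0


class TestFitting:
    def test_fixed_entries_stay_fixed(self, small_cohort):
        fa = np.array([[True, False], [False, True]])
        fit = tm.fit_model(small_cohort, components="AE", free_a=fa,
                           n_starts=3, seed=0)
        assert fit.a_[1, 0] == 0.0

    def test_constrained_fit_matches_unconstrained_under_true_null(self):
        A = np.diag([0.67, 0.67])
        E = np.diag([0.74, 0.74])
        co = tm.simulate_bivariate_cohort(A, E, n_mz=200, n_dz=200, seed=11)
        full = tm.fit_model(co, components="AE", n_starts=3, seed=0)
        fa = np.array([[True, False], [False, True]])
        red = tm.fit_model(co, components="AE", free_a=fa, n_starts=3, seed=0)
        chi2, df, p = tm.lr_test(full, red)
        assert df == 1
        assert p > 1e-4  # a21 = 0 in truth: no systematic likelihood gap

    def test_zero_variance_variable_rejected(self, small_cohort):
        values = small_cohort.values.copy()
        values[:, :, 0] = 1.0
        co = tm.TwinCohort(values, small_cohort.zygosity)
        with pytest.raises(ValueError):
            tm.fit_model(co, components="AE", n_starts=1)

    def test_saturated_loglik_dominates_nested_model(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=3, seed=0)
        ll_sat, _ = fit_saturated(small_cohort)
        assert ll_sat >= fit.loglik_ - 1e-4

    def test_diagonal_paths_nonnegative(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=3, seed=0)
        assert fit.a_[0, 0] >= 0 and fit.a_[1, 1] >= 0
        assert fit.e_[0, 0] > 0 and fit.e_[1, 1] > 0


class TestLrTest:
    def test_identical_models_give_zero(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=2, seed=0)
        chi2, df, p = tm.lr_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self, small_cohort):
        fa = np.array([[True, False], [False, True]])
        fe = np.array([[True, False], [False, True]])
        m1 = tm.fit_model(small_cohort, components="AE", free_a=fa,
                          n_starts=2, seed=0)
        m2 = tm.fit_model(small_cohort, components="AE", free_e=fe,
                          n_starts=2, seed=0)
        with pytest.raises(ValueError):
            tm.lr_test(m1, m2)


class TestModelDf:
    @pytest.mark.parametrize("n_free,p,groups,expected", [
        (8, 2, 2, 20),    # bivariate AE: 6 paths + 2 means
        (3, 1, 2, 7),     # univariate AE: 2 paths + 1 mean
        (28, 2, 2, 0),    # as many free parameters as group moments
    ])
    def test_counting(self, n_free, p, groups, expected):
        assert tm.model_df(n_free, p, groups) == expected

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError):
            tm.model_df(29, 2, 2)


class TestFitIndices:
    def test_well_fitting_model(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=3, seed=0)
        fi = tm.fit_indices(fit, small_cohort, n=small_cohort.n_pairs)
        assert fi.df == 20
        assert fi.chi2 >= 0.0
        assert 0.0 <= fi.p_value <= 1.0
        assert fi.rmsea >= 0.0
        # data were generated from the fitted structure: close fit expected
        assert fi.rmsea < 0.05
        if fi.cfi is not None:
            assert fi.cfi == pytest.approx(1.0, abs=0.1)
        # internal consistency of the RMSEA convention (n = families)
        n = small_cohort.n_pairs
        expect = np.sqrt(max(0.0, (fi.chi2 - fi.df) / (fi.df * (n - 1))))
        assert fi.rmsea == pytest.approx(expect, abs=1e-12)

    def test_overfit_chi2_clipped_to_cfi_one(self, small_cohort):
        fit = tm.fit_model(small_cohort, components="AE", n_starts=3, seed=0)
        fi = tm.fit_indices(fit, small_cohort)
        if fi.chi2 < fi.df and fi.cfi is not None:
            assert fi.cfi == 1.0
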