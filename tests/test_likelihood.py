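"""Likelihood engine: implied covariance, both evaluation paths, fitting."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import multivariate_normal

import latentgrm as lg
from latentgrm.likelihood import (
    LikelihoodError,
    _direct_core,
    _eigen_of,
    _param_gradient,
    _rotated_core,
)
from latentgrm.models import coefficient_matrices, canonicalize_signs
from conftest import random_psd_grm, random_structure_and_theta


class TestImpliedSigma:
    def test_univariate_even_split(self):
        rng = np.random.default_rng(0)
        G = random_psd_grm(4, rng)
        s = lg.make_structure("cholesky", 1)
        sig = lg.implied_sigma(s, [np.sqrt(0.5), np.sqrt(0.5)], G)
        np.testing.assert_allclose(sig, 0.5 * G + 0.5 * np.eye(4),
                                   atol=1e-12)

    def test_rge_zero_reduces_to_independence(self):
        rng = np.random.default_rng(1)
        G = random_psd_grm(5, rng)
        s_rge = lg.make_structure("ip", 2, nA=1, nE=1, rge=True)
        s_ind = lg.make_structure("ip", 2, nA=1, nE=1)
        base = rng.normal(0.5, 0.1, s_ind.n_params)
        theta = np.concatenate([base, [0.0]])
        np.testing.assert_allclose(
            lg.implied_sigma(s_rge, theta, G),
            lg.implied_sigma(s_ind, base, G), atol=1e-12)

    def test_scalar_rge_total_variance(self):
        # single trait, single individual, unit relatedness:
        # 0.36 + 0.64 + 2·0.5·0.6·0.8 = 1.48
        s = lg.make_structure("ip", 1, nA=1, nE=1, rge=True)
        theta = np.array([0.6, 0.0, 0.8, 0.0, 0.5])
        sig = lg.implied_sigma(s, theta, np.array([[1.0]]))
        assert sig[0, 0] == pytest.approx(1.48, abs=1e-12)

    def test_literal_convention_asymmetry_raised(self):
        # two traits with an asymmetric cross term and G != I: the
        # as-printed kernel assignment does not define a covariance
        rng = np.random.default_rng(2)
        G = random_psd_grm(4, rng)
        s = lg.make_structure("ip", 2, nA=1, nE=1, rge=True)
        theta = np.array([0.6, 0.1, 0.3, 0.3, 0.2, 0.7, 0.4, 0.4, 0.5])
        with pytest.raises(LikelihoodError, match="asymmetric"):
            lg.implied_sigma(s, theta, G, convention="literal")
        # for G = I all conventions coincide
        for conv in ("sqrt_g", "mean", "literal"):
            sig = lg.implied_sigma(s, theta, np.eye(4), convention=conv)
            np.testing.assert_allclose(sig, sig.T, atol=1e-12)


class TestLoglikDirect:
    def test_standard_normal_point(self):
        s = lg.make_structure("cholesky", 1)
        ll = lg.loglik_direct(s, [1.0, 0.0], np.zeros((1, 1)),
                              np.eye(1))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_all_missing_trait_marginalises_exactly(self):
        rng = np.random.default_rng(3)
        G = random_psd_grm(6, rng)
        s2 = lg.make_structure("cholesky", 2)
        theta2 = np.array([0.7, 0.2, 0.4, 0.8, 0.1, 0.5])
        Y = rng.normal(size=(6, 2))
        Y[:, 1] = np.nan
        s1 = lg.make_structure("cholesky", 1)
        ll2 = lg.loglik_direct(s2, theta2, Y, G)
        ll1 = lg.loglik_direct(s1, [0.7, 0.8], Y[:, :1], G)
        assert ll2 == pytest.approx(ll1, abs=1e-10)

    def test_matches_dense_textbook_density(self):
        rng = np.random.default_rng(4)
        G = random_psd_grm(6, rng)
        s = lg.make_structure("cholesky", 2)
        theta = np.array([0.7, 0.2, 0.4, 0.8, 0.1, 0.5])
        Y = rng.normal(size=(6, 2))
        sig = lg.implied_sigma(s, theta, G)
        oracle = multivariate_normal.logpdf(Y.ravel(order="F"),
                                            mean=np.zeros(12), cov=sig)
        assert lg.loglik_direct(s, theta, Y, G) == pytest.approx(
            oracle, abs=1e-10)


class TestLoglikRotated:
    def test_refuses_missing_data(self):
        s = lg.make_structure("cholesky", 1)
        Y = np.array([[1.0], [np.nan]])
        with pytest.raises(LikelihoodError, match="complete"):
            lg.loglik_rotated(s, [1.0, 0.5], Y, np.eye(2))

    def test_identity_grm_sums_identical_densities(self):
        rng = np.random.default_rng(5)
        s = lg.make_structure("cholesky", 2)
        theta = np.array([0.9, 0.3, 0.2, 0.7, 0.0, 0.6])
        Y = rng.normal(size=(5, 2))
        CG, CI, _ = coefficient_matrices(s, theta)
        per_row = sum(
            multivariate_normal.logpdf(y, mean=np.zeros(2), cov=CG + CI)
            for y in Y)
        assert lg.loglik_rotated(s, theta, Y, np.eye(5)) == pytest.approx(
            per_row, abs=1e-8)

    def test_univariate_reduces_to_greml_form(self):
        rng = np.random.default_rng(6)
        G = random_psd_grm(8, rng)
        d, U = _eigen_of(G)
        s = lg.make_structure("cholesky", 1)
        a, e = 0.8, 0.6
        y = rng.normal(size=(8, 1))
        yt = (U.T @ y).ravel()
        var = a * a * d + e * e
        expect = -0.5 * np.sum(np.log(2 * np.pi * var) + yt**2 / var)
        assert lg.loglik_rotated(s, [a, e], y, G) == pytest.approx(
            expect, abs=1e-10)

    @pytest.mark.parametrize("rge", [False, True])
    def test_agrees_with_direct_path(self, rge):
        rng = np.random.default_rng(11 + rge)
        for _ in range(10):
            s, theta = random_structure_and_theta(rng, rge=rge)
            n = int(rng.integers(5, 30))
            G = random_psd_grm(n, rng)
            scen = lg.SimulationScenario(n, 100, (0.1, 0.5), s, theta,
                                         seed=1)
            Y = lg.simulate_phenotypes(scen, G, seed=int(rng.integers(1e6)))
            ld = lg.loglik_direct(s, theta, Y, G)
            lr = lg.loglik_rotated(s, theta, Y, G)
            assert abs(ld - lr) <= 1e-8


class TestAnalyticGradients:
    @pytest.mark.parametrize("rge", [False, True])
    def test_rotated_scores_match_finite_differences(self, rge):
        rng = np.random.default_rng(21)
        s, theta = random_structure_and_theta(rng, k=3, rge=rge)
        G = random_psd_grm(10, rng)
        scen = lg.SimulationScenario(10, 100, (0.1, 0.5), s, theta, seed=2)
        Y = lg.simulate_phenotypes(scen, G, seed=3).to_numpy()
        d, U = _eigen_of(G)
        Yt = U.T @ Y

        def f(th):
            return _rotated_core(Yt, d, *coefficient_matrices(s, th),
                                 want_scores=False)[0]

        _, scores = _rotated_core(Yt, d, *coefficient_matrices(s, theta),
                                  want_scores=True)
        ana = _param_gradient(s, theta, scores)
        num = approx_fprime(theta, f, 1e-7)
        np.testing.assert_allclose(ana, num, atol=1e-4, rtol=1e-4)

    def test_direct_scores_match_finite_differences_with_missing(self):
        rng = np.random.default_rng(22)
        s, theta = random_structure_and_theta(rng, k=3, rge=True)
        G = random_psd_grm(9, rng)
        scen = lg.SimulationScenario(9, 100, (0.1, 0.5), s, theta, seed=2)
        Y = lg.simulate_phenotypes(scen, G, seed=4).to_numpy()
        Y[0, 1] = Y[5, 0] = np.nan

        def f(th):
            return _direct_core(s, th, Y, G, "sqrt_g", False)[0]

        _, scores = _direct_core(s, theta, Y, G, "sqrt_g", True)
        ana = _param_gradient(s, theta, scores)
        num = approx_fprime(theta, f, 1e-7)
        np.testing.assert_allclose(ana, num, atol=1e-4, rtol=1e-4)


class TestSignFlipInvariance:
    def test_likelihood_invariant_and_canonical_unique(self):
        rng = np.random.default_rng(31)
        s, theta = random_structure_and_theta(rng, k=3, rge=True)
        theta = canonicalize_signs(s, theta)
        G = random_psd_grm(8, rng)
        scen = lg.SimulationScenario(8, 100, (0.1, 0.5), s, theta, seed=9)
        Y = lg.simulate_phenotypes(scen, G, seed=9)
        LA, LE, PhiA, PhiE, Pc = lg.assemble_matrices(s, theta)
        LE2, Pc2 = LE.copy(), Pc.copy()
        LE2[:, 0] *= -1
        Pc2[0, :] *= -1
        flipped = s.flatten(LA, LE2, PhiA, PhiE, Pc2)
        assert lg.loglik_rotated(s, flipped, Y, G) == pytest.approx(
            lg.loglik_rotated(s, theta, Y, G), abs=1e-10)
        np.testing.assert_allclose(canonicalize_signs(s, flipped), theta,
                                   atol=1e-12)


class TestFitModel:
    def test_bivariate_cholesky_recovery_within_2se(self, medium_dataset):
        scen, grm, Y = medium_dataset
        fit = lg.fit_model(scen.structure, Y, grm,
                           lg.FitOptions(n_restarts=3, seed=1))
        assert fit.converged
        for est, tr, se in zip(fit.theta, scen.theta_true, fit.se):
            assert abs(est - tr) <= 2.5 * max(se, 0.02)

    def test_identity_grm_flags_unidentified(self, medium_dataset):
        scen, grm, Y = medium_dataset
        fit = lg.fit_model(scen.structure, Y, np.eye(len(Y)),
                           lg.FitOptions(n_restarts=1, seed=1))
        assert not fit.identified
        assert not fit.converged
        assert any("flat likelihood" in w or "not positive definite" in w
                   for w in fit.warnings)

    def test_rotated_path_refused_for_missing(self, medium_dataset):
        scen, grm, Y = medium_dataset
        Ym = Y.copy()
        Ym.iloc[0, 0] = np.nan
        with pytest.raises(LikelihoodError, match="complete"):
            lg.fit_model(scen.structure, Ym, grm,
                         lg.FitOptions(path="rotated"))

    def test_direct_path_fit_with_missing_small(self):
        s = lg.make_structure("ip", 2, nA=1, nE=1)
        theta = np.array([0.6, 0.5, 0.4, 0.4, 0.6, 0.5, 0.5, 0.6])
        gt = lg.simulate_genotypes(100, 600, seed=41)
        grm = lg.eigendecompose(lg.compute_grm(gt))
        scen = lg.SimulationScenario(100, 600, (0.05, 0.5), s, theta,
                                     missing_rate=0.15, seed=42)
        Y = lg.simulate_phenotypes(scen, grm, seed=42)
        fit = lg.fit_model(s, Y, grm, lg.FitOptions(n_restarts=2, seed=1,
                                                    compute_se=False))
        assert fit.path == "direct"
        assert fit.optimum_reached
        assert fit.n_observations == int(Y.notna().sum().sum())


class TestUnivariateH2:
    def test_recovers_moderate_heritability(self, small_grm):
        # larger sample simulated on the fly for a stable estimate
        gt = lg.simulate_genotypes(1200, 2500, seed=51)
        grm = lg.eigendecompose(lg.compute_grm(gt))
        s = lg.make_structure("cholesky", 1)
        scen = lg.SimulationScenario(1200, 2500, (0.05, 0.5), s,
                                     [np.sqrt(0.5), np.sqrt(0.5)], seed=52)
        y = lg.simulate_phenotypes(scen, grm, seed=52).iloc[:, 0]
        res = lg.fit_univariate_h2(y, grm)
        assert abs(res.h2 - 0.5) <= 2 * res.se
        assert res.p_lrt < 1e-4

    def test_pure_genetic_signal_hits_upper_boundary(self, small_grm):
        # trait proportional to the top-eigenvalue eigenvector of G
        y = small_grm.eigenvectors[:, 0] * 3.0
        res = lg.fit_univariate_h2(y, small_grm)
        assert res.h2 > 0.95

    def test_null_heritability_near_boundary(self, small_grm):
        rng = np.random.default_rng(53)
        ps = []
        for _ in range(10):
            y = rng.standard_normal(small_grm.n_individuals)
            ps.append(lg.fit_univariate_h2(y, small_grm))
        med = np.median([r.h2 for r in ps])
        assert med < 0.15
        assert np.median([r.p_lrt for r in ps]) > 0.05

    def test_missing_entries_dropped(self, small_grm):
        rng = np.random.default_rng(54)
        y = rng.standard_normal(small_grm.n_individuals)
        y[:5] = np.nan
        res = lg.fit_univariate_h2(y, small_grm)
        assert res.fit.n_individuals == small_grm.n_individuals - 5
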