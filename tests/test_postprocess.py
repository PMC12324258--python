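"""Standardised estimates, variance decomposition and fit statistics."""

import numpy as np
import pandas as pd
import pytest

import latentgrm as lg
from latentgrm.likelihood import FitResult
from latentgrm.postprocess import PostprocessError, sample_phenotypic_cov
from conftest import random_structure_and_theta


def _fake_fit(structure, theta, vcov=None, loglik=0.0, n=100):
    theta = np.asarray(theta, dtype=float)
    return FitResult(
        structure=structure, theta=theta, loglik=loglik,
        se=None if vcov is None else np.sqrt(np.diag(vcov)),
        vcov_theta=vcov, converged=True, optimum_reached=True,
        identified=True, n_individuals=n, n_observations=n * structure.k,
        gradient_norm=0.0, n_restarts_used=1,
    )


class TestStandardize:
    def test_univariate_even_split(self):
        s = lg.make_structure("cholesky", 1)
        est = lg.standardize(_fake_fit(s, [np.sqrt(0.5), np.sqrt(0.5)]))
        assert est.snp_h2.iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert est.e2.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_shared_factor_gives_unit_genetic_correlation(self):
        s = lg.make_structure("ip", 2, nA=1, nE=1)
        # both traits load only on the common A factor; specifics zero
        LA = np.array([[0.6, 0.0, 0.0], [0.5, 0.0, 0.0]])
        LE = np.array([[0.5, 0.4, 0.0], [0.5, 0.0, 0.4]])
        theta = s.flatten(LA, LE)
        est = lg.standardize(_fake_fit(s, theta))
        assert est.rg.iloc[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_rg_matches_naive_covariance_correlation(self):
        rng = np.random.default_rng(0)
        s, theta = random_structure_and_theta(rng, k=3)
        est = lg.standardize(_fake_fit(s, theta))
        LA, _, PhiA, *_ = lg.assemble_matrices(s, theta)
        sigA = LA @ PhiA @ LA.T
        sd = np.sqrt(np.diag(sigA))
        naive = sigA / np.outer(sd, sd)
        np.testing.assert_allclose(est.rg.to_numpy(), naive, atol=1e-10)

    def test_h2_plus_e2_is_one_without_rge(self):
        rng = np.random.default_rng(1)
        s, theta = random_structure_and_theta(rng, k=4)
        est = lg.standardize(_fake_fit(s, theta))
        np.testing.assert_allclose(est.snp_h2 + est.e2, 1.0, atol=1e-8)

    def test_delta_ses_propagate(self):
        s = lg.make_structure("cholesky", 1)
        vcov = np.diag([0.01**2, 0.01**2])
        est = lg.standardize(_fake_fit(s, [0.7, 0.7], vcov=vcov))
        assert est.snp_h2_se is not None
        assert 0 < est.snp_h2_se.iloc[0] < 0.05

    def test_zero_total_variance_invalid(self):
        s = lg.make_structure("cholesky", 1)
        with pytest.raises(PostprocessError, match="total variance"):
            lg.standardize(_fake_fit(s, [0.0, 0.0]))


class TestFactorialCoheritability:
    def test_single_common_factor_no_specific(self):
        s = lg.make_structure("ip", 2, nA=1, nE=1)
        LA = np.array([[0.6, 0.0, 0.0], [0.5, 0.0, 0.0]])
        LE = np.array([[0.5, 0.4, 0.0], [0.5, 0.0, 0.4]])
        theta = s.flatten(LA, LE)
        fc_h2, fc_e2, *_ = lg.factorial_coheritability(_fake_fit(s, theta))
        np.testing.assert_allclose(fc_h2.iloc[:, 0], 1.0, atol=1e-12)

    def test_split_between_common_and_specific(self):
        s = lg.make_structure("ip", 1, nA=1, nE=1)
        theta = np.array([0.6, 0.8, 0.5, 0.5])   # λA=0.6 common, λAS=0.8
        fc_h2, *_ = lg.factorial_coheritability(_fake_fit(s, theta))
        assert fc_h2.iloc[0, 0] == pytest.approx(0.36, abs=1e-12)

    def test_rejects_cholesky(self):
        s = lg.make_structure("cholesky", 2)
        with pytest.raises(PostprocessError, match="IP-family"):
            lg.factorial_coheritability(_fake_fit(s, np.full(6, 0.5)))


class TestDecomposeVarianceRge:
    def test_zero_rge_reduces_to_h2(self):
        s = lg.make_structure("ip", 1, nA=1, nE=1, rge=True)
        theta = np.array([0.6, 0.0, 0.8, 0.0, 0.0])
        shares = lg.decompose_variance_rge(_fake_fit(s, theta))
        assert shares["twice_cov_share"].iloc[0] == 0.0
        assert shares["g_related"].iloc[0] == pytest.approx(
            shares["a_share"].iloc[0])

    def test_scalar_expansion(self):
        s = lg.make_structure("ip", 1, nA=1, nE=1, rge=True)
        theta = np.array([0.6, 0.0, 0.8, 0.0, 0.5])
        shares = lg.decompose_variance_rge(_fake_fit(s, theta)).iloc[0]
        np.testing.assert_allclose(
            [shares["a_share"], shares["e_share"], shares["twice_cov_share"]],
            np.array([0.36, 0.64, 0.48]) / 1.48, atol=1e-10)
        assert shares["g_related"] + shares["e_related"] == pytest.approx(1.0)

    def test_negative_rge_sign_pattern(self):
        s = lg.make_structure("ip", 1, nA=1, nE=1, rge=True)
        theta = np.array([0.6, 0.0, 0.8, 0.0, -0.62])
        shares = lg.decompose_variance_rge(_fake_fit(s, theta)).iloc[0]
        assert shares["twice_cov_share"] < 0
        assert shares["g_related"] < shares["a_share"]

    def test_three_shares_sum_to_one(self):
        rng = np.random.default_rng(2)
        s, theta = random_structure_and_theta(rng, k=3, rge=True)
        shares = lg.decompose_variance_rge(_fake_fit(s, theta))
        np.testing.assert_allclose(
            shares[["a_share", "e_share", "twice_cov_share"]].sum(axis=1),
            1.0, atol=1e-8)


class TestInformationCriteria:
    # printed six-trait and seven-trait model-fit rows (LL, N_p, N_ind)
    def test_aic_from_printed_ip_row(self):
        assert lg.aic(-13406.46, 28) == pytest.approx(26868.92, abs=0.05)

    def test_aic_trivial_zero(self):
        assert lg.aic(0.0, 0) == 0.0

    @pytest.mark.parametrize("ll,npar,n,expect", [
        (-13397.26, 42, 6543, 27163.53),   # saturated baseline
        (-13404.18, 28, 6543, 27054.37),   # constrained rGE model
        (-9818.95, 43, 4412, 19998.76),    # seven-trait hybrid
    ])
    def test_bic_uses_individual_count(self, ll, npar, n, expect):
        assert lg.bic(ll, npar, n) == pytest.approx(expect, abs=0.05)

    def test_bic_from_fit_object(self):
        s = lg.make_structure("cholesky", 1)
        fit = _fake_fit(s, [0.7, 0.7], loglik=-100.0, n=50)
        assert lg.bic(fit) == pytest.approx(200 + 2 * np.log(50))


class TestLrt:
    def test_printed_ipc_comparison(self):
        res = lg.lrt(-13402.94, -13397.26, ddf=8)
        assert res.chi2 == pytest.approx(11.36, abs=0.05)
        assert res.p == pytest.approx(0.18, abs=0.01)

    def test_printed_constrained_rge_comparison(self):
        res = lg.lrt(-13404.18, -13397.26, ddf=14)
        assert res.chi2 == pytest.approx(13.84, abs=0.05)
        assert res.p == pytest.approx(0.46, abs=0.01)

    def test_identical_likelihoods(self):
        res = lg.lrt(-10.0, -10.0, ddf=0)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_negative_chi2_reported(self):
        with pytest.raises(PostprocessError, match="non-nested"):
            lg.lrt(-5.0, -50.0, ddf=2)


class TestSrmr:
    def test_exact_match_is_zero(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert lg.srmr(R, R) == 0.0

    def test_single_perturbed_correlation_closed_form(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        Rp = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert lg.srmr(Rp, R) == pytest.approx(np.sqrt(0.01 / 3), abs=1e-12)

    def test_saturated_fit_small_on_simulated_data(self, medium_dataset):
        scen, grm, Y = medium_dataset
        fit = lg.fit_model(scen.structure, Y, grm,
                           lg.FitOptions(n_restarts=2, seed=3,
                                         compute_se=False))
        assert lg.srmr_fit(fit, Y) < 0.05

    def test_nonpd_sample_cov_warns(self):
        s = lg.make_structure("cholesky", 2)
        fit = _fake_fit(s, [0.7, 0.3, 0.2, 0.7, 0.3, 0.2])
        Y = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="positive definite"):
            lg.srmr_fit(fit, Y)


class TestPhenotypicFitIndices:
    class _F:
        def __init__(self, chi2, df, chi2_b, df_b, n=500, srmr=0.01):
            self.chi2, self.df = chi2, df
            self.chi2_baseline, self.df_baseline = chi2_b, df_b
            self.n_obs, self.srmr = n, srmr

    def test_saturated_model_perfect_indices(self):
        idx = lg.phenotypic_fit_indices(self._F(0.0, 0, 300.0, 10))
        assert idx.cfi == 1.0 and idx.rmsea == 0.0

    def test_independence_model_as_its_own_baseline(self):
        idx = lg.phenotypic_fit_indices(self._F(300.0, 10, 300.0, 10))
        assert idx.cfi == 0.0

    def test_zero_baseline_df_undefined(self):
        with pytest.raises(PostprocessError, match="undefined"):
            lg.phenotypic_fit_indices(self._F(5.0, 2, 0.0, 0))


class TestCompareModels:
    def test_table_columns_and_baseline(self):
        s2 = lg.make_structure("cholesky", 2)
        pattern = np.array([[True], [False]])
        s_ip = lg.make_structure("ip", 2, nA=1, nE=1, pattern_A=pattern,
                                 pattern_E=pattern)
        full = _fake_fit(s2, np.full(6, 0.5), loglik=-100.0, n=80)
        nested = _fake_fit(s_ip, np.full(s_ip.n_params, 0.4),
                           loglik=-103.0, n=80)
        table = lg.compare_models({"chol": full, "ip": nested}, "chol")
        assert {"N_p", "LL", "AIC", "BIC"} <= set(table.columns)
        assert table.loc["ip", "LRT_chi2"] == pytest.approx(6.0)


def test_delta_method_h2_se_agrees_with_parametric_bootstrap():
    """snp-h2 delta-method SEs within 10% of 200 seeded parametric
    bootstrap refits on a small bivariate scenario."""
    s = lg.make_structure("cholesky", 2)
    theta = np.array([0.6, 0.2, 0.5, 0.7, 0.1, 0.6])
    gt = lg.simulate_genotypes(400, 1200, seed=61)
    grm = lg.eigendecompose(lg.compute_grm(gt))
    scen = lg.SimulationScenario(400, 1200, (0.05, 0.5), s, theta, seed=62)
    Y = lg.simulate_phenotypes(scen, grm, seed=62)
    fit = lg.fit_model(s, Y, grm, lg.FitOptions(n_restarts=2, seed=1))
    delta_se = lg.standardize(fit).snp_h2_se.to_numpy()
    boot_scen = lg.SimulationScenario(400, 1200, (0.05, 0.5), s, fit.theta,
                                      seed=0)
    h2s = []
    for r in range(200):
        Yb = lg.simulate_phenotypes(boot_scen, grm, seed=5000 + r)
        fb = lg.fit_model(s, Yb, grm,
                          lg.FitOptions(n_restarts=1, seed=r,
                                        compute_se=False, start=fit.theta))
        h2s.append(lg.standardize(fb).snp_h2.to_numpy())
    boot_se = np.std(np.array(h2s), axis=0, ddof=1)
    np.testing.assert_allclose(delta_se, boot_se, rtol=0.10)


def test_pairwise_complete_sample_covariance():
    Y = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan],
                      "b": [2.0, np.nan, 4.0, 1.0]})
    S = sample_phenotypic_cov(Y)
    assert S.shape == (2, 2)
    assert np.isfinite(S).all()
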