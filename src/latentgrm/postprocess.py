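"""Standardised GRM-SEM summaries and model-fit statistics.

Per trait j the model decomposes the phenotypic variance as

    V_j = a_j + e_j + 2 c_j,

with a_j = [ΛA ΦA ΛAᵀ]_jj the genomic variance, e_j = [ΛE ΦE ΛEᵀ]_jj the
residual variance and c_j = [ΛE Φcov ΛAᵀ]_jj the gene-environment
covariance (zero without rGE).  SNP-h² = a_j/V_j, e² = e_j/V_j, and the
signed share 2c_j/V_j completes the decomposition; g-related and
e-related shares (a_j+c_j)/V_j and (e_j+c_j)/V_j sum to one.  Standard
errors are delta-method propagations of the parameter covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelStructure, assemble_matrices, coefficient_matrices


class PostprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# delta method
# ---------------------------------------------------------------------------

def delta_method_se(fun, theta, vcov, h: float = 1e-6) -> np.ndarray:
    """SEs of fun(theta) (vector-valued) by central-difference Jacobian."""
    theta = np.asarray(theta, dtype=float)
    f0 = np.asarray(fun(theta), dtype=float)
    J = np.zeros((f0.size, theta.size))
    for i in range(theta.size):
        step = h * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        J[:, i] = (np.asarray(fun(tp)) - np.asarray(fun(tm))) / (2.0 * step)
    var = np.einsum("ij,jk,ik->i", J, vcov, J)
    return np.sqrt(np.maximum(var, 0.0))


def _cov2corr(C: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.maximum(np.diag(C), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = C / np.outer(sd, sd)
    R[~np.isfinite(R)] = np.nan
    np.fill_diagonal(R, np.where(sd > 0, 1.0, np.nan))
    return R


def _variance_parts(structure: ModelStructure, theta):
    LA, LE, PhiA, PhiE, Pc = assemble_matrices(structure, theta)
    sigA = LA @ PhiA @ LA.T
    sigE = LE @ PhiE @ LE.T
    M = LE @ Pc @ LA.T if structure.rge_enabled else np.zeros_like(sigA)
    a = np.diag(sigA).copy()
    e = np.diag(sigE).copy()
    c = np.diag(M).copy()
    V = a + e + 2.0 * c
    return LA, LE, sigA, sigE, a, e, c, V


# ---------------------------------------------------------------------------
# standardised estimates
# ---------------------------------------------------------------------------

@dataclass
class StandardizedEstimates:
    """Per-trait and per-pair standardised summaries of a converged fit."""

    trait_names: list[str]
    snp_h2: pd.Series
    e2: pd.Series
    shares: pd.DataFrame              # a, e, 2cov, g-related, e-related
    rg: pd.DataFrame
    re: pd.DataFrame
    loadings_A: pd.DataFrame          # standardised-trait scale
    loadings_E: pd.DataFrame
    fc_h2: pd.DataFrame | None        # factorial co-heritability
    fc_e2: pd.DataFrame | None
    snp_h2_se: pd.Series | None = None
    e2_se: pd.Series | None = None
    loadings_A_se: pd.DataFrame | None = None
    loadings_E_se: pd.DataFrame | None = None
    fc_h2_se: pd.DataFrame | None = None
    fc_e2_se: pd.DataFrame | None = None


def _col_names(structure, side: str):
    if side == "A":
        if structure.a_is_cholesky:
            return [f"F{c + 1}" for c in range(structure.k)]
        common = (structure.factor_names_A
                  or [f"A{f + 1}" for f in range(structure.nA)])
        return list(common) + [f"AS_{t}" for t in structure.trait_names]
    if structure.e_is_cholesky:
        return [f"F{c + 1}" for c in range(structure.k)]
    common = (structure.factor_names_E
              or [f"E{f + 1}" for f in range(structure.nE)])
    return list(common) + [f"ES_{t}" for t in structure.trait_names]


def standardize(fit, sample_var=None) -> StandardizedEstimates:
    """Standardised variance decomposition and loadings for a fitted model.

    ``sample_var`` optionally replaces the model-implied per-trait total
    variance used to put loadings on the standardised-trait scale.
    """
    s = fit.structure
    theta = fit.theta
    LA, LE, sigA, sigE, a, e, c, V = _variance_parts(s, theta)
    if (V <= 0).any():
        bad = [s.trait_names[j] for j in np.where(V <= 0)[0]]
        raise PostprocessError(f"non-positive total variance for {bad}")
    Vuse = np.asarray(sample_var, float) if sample_var is not None else V
    sd = np.sqrt(Vuse)
    tn = s.trait_names

    shares = pd.DataFrame({
        "a_share": a / V,
        "e_share": e / V,
        "twice_cov_share": 2.0 * c / V,
        "g_related": (a + c) / V,
        "e_related": (e + c) / V,
    }, index=tn)
    est = StandardizedEstimates(
        trait_names=tn,
        snp_h2=pd.Series(a / V, index=tn, name="snp_h2"),
        e2=pd.Series(e / V, index=tn, name="e2"),
        shares=shares,
        rg=pd.DataFrame(_cov2corr(sigA), index=tn, columns=tn),
        re=pd.DataFrame(_cov2corr(sigE), index=tn, columns=tn),
        loadings_A=pd.DataFrame(LA / sd[:, None], index=tn,
                                columns=_col_names(s, "A")),
        loadings_E=pd.DataFrame(LE / sd[:, None], index=tn,
                                columns=_col_names(s, "E")),
        fc_h2=None, fc_e2=None,
    )
    if not s.a_is_cholesky:
        fc = (LA[:, :s.nA] ** 2) / np.where(a > 0, a, np.nan)[:, None]
        est.fc_h2 = pd.DataFrame(fc, index=tn,
                                 columns=_col_names(s, "A")[:s.nA])
    if not s.e_is_cholesky:
        fc = (LE[:, :s.nE] ** 2) / np.where(e > 0, e, np.nan)[:, None]
        est.fc_e2 = pd.DataFrame(fc, index=tn,
                                 columns=_col_names(s, "E")[:s.nE])

    if fit.vcov_theta is not None:
        def h2_fun(th):
            *_, aa, ee, cc, VV = _variance_parts(s, th)
            return np.concatenate([aa / VV, ee / VV])

        ses = delta_method_se(h2_fun, theta, fit.vcov_theta)
        est.snp_h2_se = pd.Series(ses[:s.k], index=tn)
        est.e2_se = pd.Series(ses[s.k:], index=tn)

        def load_fun(th):
            LA_, LE_, *_, VV = _variance_parts(s, th)
            sd_ = np.sqrt(VV) if sample_var is None else sd
            return np.concatenate([(LA_ / sd_[:, None]).ravel(),
                                   (LE_ / sd_[:, None]).ravel()])

        ses = delta_method_se(load_fun, theta, fit.vcov_theta)
        nA_ = s.k * s.ncol_A
        est.loadings_A_se = pd.DataFrame(
            ses[:nA_].reshape(s.k, s.ncol_A), index=tn,
            columns=_col_names(s, "A"))
        est.loadings_E_se = pd.DataFrame(
            ses[nA_:].reshape(s.k, s.ncol_E), index=tn,
            columns=_col_names(s, "E"))

        if not s.a_is_cholesky:
            def fcA_fun(th):
                LA_, _, _, _, aa, *_ = _variance_parts(s, th)
                return ((LA_[:, :s.nA] ** 2)
                        / np.where(aa > 0, aa, np.nan)[:, None]).ravel()
            ses = delta_method_se(fcA_fun, theta, fit.vcov_theta)
            est.fc_h2_se = pd.DataFrame(ses.reshape(s.k, s.nA), index=tn,
                                        columns=est.fc_h2.columns)
        if not s.e_is_cholesky:
            def fcE_fun(th):
                _, LE_, _, _, _, ee, *_ = _variance_parts(s, th)
                return ((LE_[:, :s.nE] ** 2)
                        / np.where(ee > 0, ee, np.nan)[:, None]).ravel()
            ses = delta_method_se(fcE_fun, theta, fit.vcov_theta)
            est.fc_e2_se = pd.DataFrame(ses.reshape(s.k, s.nE), index=tn,
                                        columns=est.fc_e2.columns)
    return est


def factorial_coheritability(fit):
    """fcSNP-h² and fce²: the share of a trait's genomic (residual)
    variance explained by each latent common factor, λ²_{jf}/a_j and
    λ²_{jf}/e_j, with delta-method SEs."""
    s = fit.structure
    if s.a_is_cholesky or s.e_is_cholesky:
        raise PostprocessError(
            "factorial co-heritability is defined for IP-family structures "
            "with common factors on both sides"
        )
    est = standardize(fit)
    return est.fc_h2, est.fc_e2, est.fc_h2_se, est.fc_e2_se


def decompose_variance_rge(fit) -> pd.DataFrame:
    """Per-trait A, E and signed 2Cov(A,E) variance shares, plus the
    combined G-related and E-related representations (Fig-style output).

    The two representations are consistent: g_related + e_related = 1.
    """
    return standardize(fit).shares


# ---------------------------------------------------------------------------
# information criteria, LRT, SRMR
# ---------------------------------------------------------------------------

def _ll_np(obj_or_ll, n_params=None):
    if n_params is None:
        return float(obj_or_ll.loglik), int(obj_or_ll.n_params)
    return float(obj_or_ll), int(n_params)


def aic(fit_or_loglik, n_params: int | None = None) -> float:
    """AIC = −2·LL + 2·N_p."""
    ll, p = _ll_np(fit_or_loglik, n_params)
    return -2.0 * ll + 2.0 * p


def bic(fit_or_loglik, n_params_or_n=None, n_individuals: int | None = None) -> float:
    """BIC = −2·LL + N_p·ln(N_ind); the sample size is the number of
    individuals, not the number of non-missing observations."""
    if n_individuals is None:
        ll, p = _ll_np(fit_or_loglik)
        n = int(n_params_or_n if n_params_or_n is not None
                else fit_or_loglik.n_individuals)
    else:
        ll, p = _ll_np(fit_or_loglik, n_params_or_n)
        n = int(n_individuals)
    return -2.0 * ll + p * np.log(n)


@dataclass
class LRTResult:
    chi2: float
    ddf: int
    p: float


def lrt(fit_nested, fit_full, ddf: int | None = None,
        tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of a nested against a fuller model.

    Accepts FitResult-like objects, or two log-likelihoods with an
    explicit ``ddf``.  A chi-square below −tol indicates non-nested or
    non-converged fits and is raised.
    """
    if ddf is None:
        ll0, p0 = _ll_np(fit_nested)
        ll1, p1 = _ll_np(fit_full)
        ddf = p1 - p0
    else:
        ll0, ll1 = float(fit_nested), float(fit_full)
    if ddf < 0:
        raise PostprocessError("models are not nested (ddf < 0)")
    chi2 = 2.0 * (ll1 - ll0)
    if chi2 < -tol * max(1.0, abs(ll1)):
        raise PostprocessError(
            f"negative LRT chi-square ({chi2:.4g}): fits are non-nested "
            "or not converged"
        )
    chi2 = max(chi2, 0.0)
    if ddf == 0:
        p = 1.0 if chi2 <= tol else 0.0
    else:
        p = float(stats.chi2.sf(chi2, ddf))
    return LRTResult(chi2=float(chi2), ddf=int(ddf), p=p)


def srmr(implied_cov, sample_cov) -> float:
    """Standardised root mean square residual, lower triangle including
    the diagonal: residuals (s_ij − σ̂_ij)/(sd_i·sd_j) with sample SDs."""
    S = np.asarray(sample_cov, dtype=float)
    Sig = np.asarray(implied_cov, dtype=float)
    k = S.shape[0]
    sd = np.sqrt(np.diag(S))
    E = (S - Sig) / np.outer(sd, sd)
    tril = np.tril_indices(k)
    return float(np.sqrt(np.mean(E[tril] ** 2)))


def sample_phenotypic_cov(Y) -> np.ndarray:
    """Pairwise-complete sample covariance (ML denominators)."""
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
    S = df.cov(min_periods=2, ddof=0).to_numpy()
    return S


def srmr_fit(fit, Y, convention: str = "sqrt_g") -> float:
    """SRMR of a GRM-SEM fit against the sample phenotypic covariance.

    The model-implied total covariance per individual takes the kernel
    diagonals as 1, i.e. C_G + C_I + C_X.
    """
    CG, CI, CX = coefficient_matrices(fit.structure, fit.theta, convention)
    CI = CI + CX
    S = sample_phenotypic_cov(Y)
    if np.linalg.eigvalsh(S).min() <= 0:
        import warnings as _w
        _w.warn("sample phenotypic covariance is not positive definite; "
                "SRMR computed on correlations regardless", RuntimeWarning)
    return srmr(CG + CI, S)


# ---------------------------------------------------------------------------
# phenotypic (CFA) fit indices
# ---------------------------------------------------------------------------

@dataclass
class PhenotypicFitIndices:
    cfi: float
    tli: float
    rmsea: float
    srmr: float


def phenotypic_fit_indices(cfa_fit, baseline_fit=None) -> PhenotypicFitIndices:
    """CFI, TLI, RMSEA and SRMR for a phenotypic factor model.

    ``cfa_fit`` needs ``chi2``, ``df``, ``n_obs`` and ``srmr`` attributes;
    ``baseline_fit`` (independence model) needs ``chi2`` and ``df`` — when
    omitted, the cfa_fit must carry ``chi2_baseline``/``df_baseline``.
    """
    chi2, df = float(cfa_fit.chi2), int(cfa_fit.df)
    n = int(cfa_fit.n_obs)
    if baseline_fit is not None:
        chi2_b, df_b = float(baseline_fit.chi2), int(baseline_fit.df)
    else:
        chi2_b, df_b = float(cfa_fit.chi2_baseline), int(cfa_fit.df_baseline)
    if df_b == 0:
        raise PostprocessError("baseline model has zero degrees of freedom; "
                               "incremental indices are undefined")
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if d == 0 else 1.0 - d / max(d_b, d)
    if df == 0:
        tli = 1.0
        rmsea = 0.0
    else:
        denom = chi2_b / df_b - 1.0
        tli = ((chi2_b / df_b - chi2 / df) / denom) if denom > 0 else 1.0
        rmsea = float(np.sqrt(d / (df * (n - 1))))
    return PhenotypicFitIndices(
        cfi=float(cfi), tli=float(tli), rmsea=rmsea,
        srmr=float(getattr(cfa_fit, "srmr", np.nan)),
    )


# ---------------------------------------------------------------------------
# model comparison tables
# ---------------------------------------------------------------------------

def compare_models(fits: dict, baseline: str, Y=None,
                   n_individuals: int | None = None) -> pd.DataFrame:
    """Fit-comparison table (N_p, LL, AIC, BIC, SRMR, Δdf, LRT-ΔX², LRT-P)
    with every model tested against the named baseline (the saturated
    Cholesky in the data-driven pipeline)."""
    base = fits[baseline]
    rows = []
    for name, fit in fits.items():
        n_ind = n_individuals or fit.n_individuals
        row = {
            "model": name,
            "N_p": fit.n_params,
            "LL": fit.loglik,
            "AIC": aic(fit),
            "BIC": bic(fit.loglik, fit.n_params, n_ind),
        }
        if Y is not None:
            row["SRMR"] = srmr_fit(fit, Y)
        if name != baseline and fit.n_params <= base.n_params:
            try:
                res = lrt(fit, base)
                row.update({"ddf": res.ddf, "LRT_chi2": res.chi2,
                            "LRT_p": res.p})
            except PostprocessError:
                row.update({"ddf": np.nan, "LRT_chi2": np.nan,
                            "LRT_p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
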