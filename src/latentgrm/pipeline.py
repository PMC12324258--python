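"""Data-driven stepwise model building.

The pipeline mirrors the hybrid covariance-modelling strategy: fit the
saturated Cholesky; predict the latent genomic structure by PCA (Kaiser
count, Cattell scree elbow) and ML exploratory factor analysis of the
Cholesky-derived genetic correlation matrix; fit the hybrid IPC; predict
the latent residual structure from the IPC-derived residual correlation
and covariance matrices; fit the IP model; confirm factor independence
with bifactor variants; extend the best IP with gene-environment
correlations between structurally matched factor pairs (starting values
from the IP fit); constrain near-zero specific genomic loadings; and
select the best admissible model (SRMR ≤ 0.08) by AIC.  Every automatic
decision is appended to a replayable log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import promax

from . import postprocess as post
from .likelihood import FitOptions, FitResult, fit_model
from .models import carry_theta, constrain_small_loadings, make_structure
from .postprocess import srmr


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# factor-count prediction and EFA patterns
# ---------------------------------------------------------------------------

@dataclass
class FactorCountPrediction:
    eigenvalues: np.ndarray
    n_kaiser: int
    n_cattell: int
    chosen: int
    candidates: list[int]
    degenerate: bool


def predict_n_factors(corr_matrix) -> FactorCountPrediction:
    """Kaiser criterion (eigenvalues > 1) and automated Cattell scree test.

    The scree elbow is taken at the maximum acceleration (second
    difference) of the eigenvalue sequence, with the factor count one
    before the elbow.  The Kaiser count is primary; when the two
    disagree, both candidates are returned for downstream comparison.
    """
    R = np.asarray(corr_matrix, dtype=float)
    w = np.sort(linalg.eigvalsh(R))[::-1]
    if w.min() < -1e-6:
        raise PipelineError(
            f"input matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    k = w.size
    n_kaiser = int((w > 1.0).sum())
    if k >= 3:
        accel = w[:-2] - 2.0 * w[1:-1] + w[2:]
        n_cattell = int(np.argmax(accel)) + 1
    else:
        n_cattell = max(n_kaiser, 1)
    degenerate = n_kaiser == 0
    candidates = sorted({n for n in (n_kaiser, n_cattell) if n >= 1})
    if not candidates:
        candidates = [1]
    return FactorCountPrediction(
        eigenvalues=w, n_kaiser=n_kaiser, n_cattell=n_cattell,
        chosen=n_kaiser if n_kaiser >= 1 else candidates[0],
        candidates=candidates, degenerate=degenerate,
    )


@dataclass
class EFAPattern:
    mask: np.ndarray            # k × n_factors freed-loading mask
    loadings: np.ndarray        # rotated pattern loadings
    n_factors: int
    unassigned: list[int]       # traits with no freed common loading
    log: list[str]


def efa_pattern(matrix, n_factors: int, loading_threshold: float = 0.3,
                rotation: str = "promax") -> EFAPattern:
    """ML exploratory factor analysis with oblique rotation; frees the
    loadings whose rotated magnitude reaches the threshold.

    A Heywood case (non-positive uniqueness) triggers a logged retry with
    one factor fewer.  Traits left without any freed common loading keep
    only their specific term (reported in ``unassigned``).
    """
    if n_factors < 1:
        raise PipelineError("n_factors must be >= 1")
    M = np.asarray(matrix, dtype=float)
    k = M.shape[0]
    sd = np.sqrt(np.maximum(np.diag(M), 1e-12))
    R = M / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    log: list[str] = []
    nf = min(n_factors, k - 1)
    while True:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fa = Factor(corr=R, n_factor=nf, method="ml",
                            smc=True).fit(maxiter=200)
            if np.any(fa.uniqueness < 1e-6):
                raise PipelineError("Heywood case")
            break
        except Exception as err:       # Heywood or non-convergence
            log.append(f"EFA with {nf} factors failed ({err}); retrying "
                       f"with {nf - 1}")
            nf -= 1
            if nf < 1:
                raise PipelineError(
                    "exploratory factor analysis failed for every factor "
                    f"count up to {n_factors}"
                ) from err
    L = np.asarray(fa.loadings)
    if nf > 1 and rotation == "promax":
        L = promax(L)[0]
    # orient each factor so its dominant loading is positive
    for f in range(nf):
        if L[np.argmax(np.abs(L[:, f])), f] < 0:
            L[:, f] *= -1.0
    mask = np.abs(L) >= loading_threshold
    unassigned = [j for j in range(k) if not mask[j].any()]
    if unassigned:
        log.append(f"traits with no freed common loading: {unassigned}")
    return EFAPattern(mask=mask, loadings=L, n_factors=nf,
                      unassigned=unassigned, log=log)


# ---------------------------------------------------------------------------
# rGE evidence
# ---------------------------------------------------------------------------

@dataclass
class RgeEvidence:
    supported: bool
    aic_improves: bool
    lrt: post.LRTResult
    wald: pd.DataFrame
    all_intervals_exclude_zero: bool


def rge_evidence(ip_fit: FitResult, ip_rge_fit: FitResult,
                 alpha: float = 0.05) -> RgeEvidence:
    """Verdict on gene-environment correlation.

    Supported iff the rGE model fits better (AIC improves or LRT
    p < alpha) *and* every estimated rGE's Wald interval excludes zero;
    the components are reported separately.
    """
    res = post.lrt(ip_fit, ip_rge_fit)
    aic_improves = post.aic(ip_rge_fit) < post.aic(ip_fit)
    names = ip_rge_fit.structure.param_names()
    rows = []
    zcrit = float(-_norm_ppf(alpha / 2.0))
    for i, name in enumerate(names):
        if not name.startswith("rGE"):
            continue
        est = ip_rge_fit.theta[i]
        se = (ip_rge_fit.se[i] if ip_rge_fit.se is not None else np.nan)
        lo, hi = est - zcrit * se, est + zcrit * se
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        rows.append({"name": name, "estimate": est, "se": se, "z": z,
                     "p_wald": 2.0 * _norm_sf(abs(z)) if np.isfinite(z)
                     else np.nan,
                     "ci_low": lo, "ci_high": hi,
                     "excludes_zero": bool(np.isfinite(lo) and
                                           (lo > 0 or hi < 0))})
    wald = pd.DataFrame(rows)
    all_nonzero = bool(len(wald) > 0 and wald["excludes_zero"].all())
    supported = bool((aic_improves or res.p < alpha) and all_nonzero)
    return RgeEvidence(supported=supported, aic_improves=aic_improves,
                       lrt=res, wald=wald,
                       all_intervals_exclude_zero=all_nonzero)


def _norm_ppf(q):
    from scipy.stats import norm
    return norm.ppf(q)


def _norm_sf(q):
    from scipy.stats import norm
    return float(norm.sf(q))


# ---------------------------------------------------------------------------
# the stepwise pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineOptions:
    fit: FitOptions = field(default_factory=FitOptions)
    efa_threshold: float = 0.3
    constrain_threshold: float = 0.05
    srmr_max: float = 0.08
    rge_pairs: str = "matched"
    fit_bifactor: bool = True
    alpha: float = 0.05


@dataclass
class PipelineState:
    stage: str
    fits: dict
    decision_log: list
    matrices: dict
    nA: int | None = None
    nE: int | None = None
    final_model: str | None = None
    comparison: pd.DataFrame | None = None
    rge: RgeEvidence | None = None

    def log(self, stage: str, **info):
        self.stage = stage
        entry = {"stage": stage}
        entry.update(info)
        self.decision_log.append(entry)


def _safe_corr(C: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.maximum(np.diag(C), 1e-12))
    R = C / np.outer(sd, sd)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    # project marginally indefinite matrices back to PSD
    w, V = linalg.eigh(R)
    if w.min() < 0:
        R = (V * np.maximum(w, 1e-9)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def _match_factor_pairs(pattern_E: np.ndarray, pattern_A: np.ndarray):
    """Pair each residual factor with the genomic factor whose loading
    pattern it overlaps most (greedy on Jaccard similarity)."""
    nE, nA = pattern_E.shape[1], pattern_A.shape[1]
    J = np.zeros((nE, nA))
    for e_f in range(nE):
        for a_f in range(nA):
            inter = (pattern_E[:, e_f] & pattern_A[:, a_f]).sum()
            union = (pattern_E[:, e_f] | pattern_A[:, a_f]).sum()
            J[e_f, a_f] = inter / union if union else 0.0
    pairs = []
    used_e, used_a = set(), set()
    for _ in range(min(nE, nA)):
        best, best_val = None, -1.0
        for e_f in range(nE):
            for a_f in range(nA):
                if e_f in used_e or a_f in used_a:
                    continue
                if J[e_f, a_f] > best_val:
                    best, best_val = (e_f, a_f), J[e_f, a_f]
        if best is None or best_val <= 0:
            break
        pairs.append(best)
        used_e.add(best[0])
        used_a.add(best[1])
    return pairs


def run_grmsem_pipeline(Y, grm, options: PipelineOptions | None = None
                        ) -> PipelineState:
    """Run the full data-driven model-building sequence on prepared
    phenotypes and a pruned GRM; halts with diagnostics if any stage's
    fit does not converge."""
    opts = options or PipelineOptions()
    Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
    traits = list(Ydf.columns.astype(str))
    k = len(traits)
    state = PipelineState(stage="init", fits={}, decision_log=[],
                          matrices={})

    def fit_named(name, structure, start=None):
        fo = FitOptions(**{**opts.fit.__dict__})
        if start is not None:
            fo.start = start
            fo.n_restarts = 1
        fit = fit_model(structure, Ydf, grm, fo)
        state.fits[name] = fit
        if not fit.optimum_reached:
            raise PipelineError(
                f"stage '{name}' did not converge "
                f"(gradient_norm={fit.gradient_norm:.3g}, "
                f"warnings={fit.warnings})"
            )
        if not fit.identified:
            state.log(f"{name}:identification", warnings=fit.warnings)
        return fit

    # (1) saturated Cholesky baseline
    chol = fit_named("cholesky", make_structure("cholesky", k,
                                                trait_names=traits))
    state.log("cholesky", loglik=chol.loglik, n_params=chol.n_params)

    # (2) genomic structure from the Cholesky-derived rg matrix -> IPC
    est = post.standardize(chol)
    rg = _safe_corr(est.rg.to_numpy())
    state.matrices["genetic_corr"] = rg
    pfA = predict_n_factors(rg)
    state.log("predict_nA", n_kaiser=pfA.n_kaiser, n_cattell=pfA.n_cattell,
              candidates=pfA.candidates, eigenvalues=pfA.eigenvalues.tolist())
    ipc_by_nA = {}
    patterns_A = {}
    for nA in pfA.candidates:
        pat = efa_pattern(rg, nA, opts.efa_threshold)
        patterns_A[nA] = pat
        struct = make_structure("ipc", k, nA=pat.n_factors,
                                pattern_A=pat.mask, trait_names=traits)
        ipc_by_nA[nA] = fit_named(f"ipc_nA{pat.n_factors}", struct)
    nA = min(ipc_by_nA, key=lambda n: post.aic(ipc_by_nA[n]))
    ipc = ipc_by_nA[nA]
    pattern_A = patterns_A[nA].mask
    nA = patterns_A[nA].n_factors
    state.nA = nA
    state.log("ipc", chosen_nA=nA,
              aic={f"nA={n}": post.aic(f) for n, f in ipc_by_nA.items()})

    # (3) residual structure from IPC-derived residual matrices -> IP
    _, LE_raw, _, _, _ = ipc.structure.assemble(ipc.theta)
    sigE = LE_raw @ LE_raw.T
    state.matrices["residual_cov"] = sigE
    state.matrices["residual_corr"] = _safe_corr(sigE)
    pfE = predict_n_factors(_safe_corr(sigE))
    state.log("predict_nE", n_kaiser=pfE.n_kaiser, n_cattell=pfE.n_cattell,
              candidates=pfE.candidates, eigenvalues=pfE.eigenvalues.tolist())
    ip_by_nE = {}
    patterns_E = {}
    for nE in pfE.candidates:
        pat = efa_pattern(sigE, nE, opts.efa_threshold)
        patterns_E[nE] = pat
        struct = make_structure("ip", k, nA=nA, nE=pat.n_factors,
                                pattern_A=pattern_A, pattern_E=pat.mask,
                                trait_names=traits)
        ip_by_nE[nE] = fit_named(f"ip_nA{nA}_nE{pat.n_factors}", struct)
    nE = min(ip_by_nE, key=lambda n: post.aic(ip_by_nE[n]))
    ip = ip_by_nE[nE]
    pattern_E = patterns_E[nE].mask
    nE = patterns_E[nE].n_factors
    state.nE = nE
    state.log("ip", chosen_nE=nE,
              aic={f"nE={n}": post.aic(f) for n, f in ip_by_nE.items()})

    # (4) bifactor checks of factor independence
    if opts.fit_bifactor and nA >= 2:
        # one general genomic factor plus the identified group factors
        bfa = make_structure("bifactor_a", k, nA=nA + 1, nE=nE,
                             pattern_A=pattern_A,
                             pattern_E=pattern_E, trait_names=traits)
        try:
            fit_named("bifactor_A", bfa)
            state.log("bifactor_A",
                      aic_ip=post.aic(ip),
                      aic_bifactor=post.aic(state.fits["bifactor_A"]),
                      independent=post.aic(ip)
                      <= post.aic(state.fits["bifactor_A"]))
        except PipelineError as err:
            state.log("bifactor_A", failed=str(err))
    if opts.fit_bifactor and nE >= 2:
        bfe = make_structure("bifactor_e", k, nA=nA, nE=nE + 1,
                             pattern_A=pattern_A,
                             pattern_E=pattern_E, trait_names=traits)
        try:
            fit_named("bifactor_E", bfe)
            state.log("bifactor_E",
                      aic_ip=post.aic(ip),
                      aic_bifactor=post.aic(state.fits["bifactor_E"]),
                      independent=post.aic(ip)
                      <= post.aic(state.fits["bifactor_E"]))
        except PipelineError as err:
            state.log("bifactor_E", failed=str(err))

    # (5) rGE extension of the best IP, warm-started from the IP optimum
    pairs = (_match_factor_pairs(pattern_E, pattern_A)
             if opts.rge_pairs == "matched" else
             [(e, a) for e in range(nE) for a in range(nA)])
    rge_struct = make_structure("ip", k, nA=nA, nE=nE,
                                pattern_A=pattern_A, pattern_E=pattern_E,
                                rge=True, rge_pairs=pairs,
                                trait_names=traits)
    start = carry_theta(ip.structure, ip.theta, rge_struct)
    ip_rge = fit_named("ip_rge", rge_struct, start=start)
    state.rge = rge_evidence(ip, ip_rge, opts.alpha)
    state.log("rge", pairs=pairs, supported=state.rge.supported,
              lrt_p=state.rge.lrt.p,
              estimates=state.rge.wald["estimate"].tolist())

    # (6) constrain near-zero specific genomic loadings, refit
    con_struct = constrain_small_loadings(rge_struct, ip_rge,
                                          opts.constrain_threshold,
                                          parts="A")
    n_con = rge_struct.n_params - con_struct.n_params
    if n_con > 0:
        start = carry_theta(rge_struct, ip_rge.theta, con_struct)
        fit_named("ip_rge_con", con_struct, start=start)
        state.log("constrain", n_constrained=n_con)
    else:
        state.log("constrain", n_constrained=0)

    # (7) final comparison and selection
    comparison = post.compare_models(state.fits, baseline="cholesky", Y=Ydf)
    state.comparison = comparison
    admissible = comparison[(comparison["SRMR"] <= opts.srmr_max)]
    candidates = [m for m in admissible.index
                  if not m.startswith("bifactor")]
    final = min(candidates, key=lambda m: comparison.loc[m, "AIC"])
    state.final_model = final
    state.log("select", final=final,
              aic=float(comparison.loc[final, "AIC"]),
              srmr=float(comparison.loc[final, "SRMR"]))
    return state


# ---------------------------------------------------------------------------
# phenotypic split-half EFA / CFA
# ---------------------------------------------------------------------------

@dataclass
class CFAFit:
    loadings: np.ndarray
    uniqueness: np.ndarray
    factor_corr: np.ndarray
    pattern: np.ndarray
    correlated: bool
    loglik: float
    n_params: int
    n_obs: int
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    srmr: float
    implied: np.ndarray
    sample: np.ndarray
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def fit_phenotypic_cfa(S, n_obs: int, pattern_mask, correlated: bool = True
                       ) -> CFAFit:
    """ML confirmatory factor analysis of a covariance matrix.

    Σ(θ) = Λ Φ Λᵀ + Ψ with Λ free per the pattern mask, diagonal Ψ > 0
    and (optionally) free factor correlations; fitted by minimising the
    ML discrepancy F = log|Σ| + tr(SΣ⁻¹) − log|S| − k.
    """
    from scipy import optimize

    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    mask = np.asarray(pattern_mask, dtype=bool)
    nf = mask.shape[1]
    free = np.argwhere(mask)
    n_load = len(free)
    n_corr = nf * (nf - 1) // 2 if (correlated and nf > 1) else 0
    n_params = n_load + k + n_corr
    sign_S, logdet_S = np.linalg.slogdet(S)
    if sign_S <= 0:
        raise PipelineError("sample covariance is not positive definite")
    tri = np.triu_indices(nf, 1)

    def build(x):
        L = np.zeros((k, nf))
        L[free[:, 0], free[:, 1]] = x[:n_load]
        psi = x[n_load:n_load + k] ** 2 + 1e-8
        Phi = np.eye(nf)
        if n_corr:
            vals = np.tanh(x[n_load + k:])
            Phi[tri] = vals
            Phi[(tri[1], tri[0])] = vals
        return L, psi, Phi

    def discrepancy(x):
        L, psi, Phi = build(x)
        Sig = L @ Phi @ L.T + np.diag(psi)
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            return 1e6
        return logdet + np.trace(np.linalg.solve(Sig, S)) - logdet_S - k

    sd = np.sqrt(np.diag(S))
    x0 = np.concatenate([
        np.repeat(0.6, n_load) * sd[free[:, 0]],
        0.6 * sd,
        np.zeros(n_corr),
    ])
    res = optimize.minimize(discrepancy, x0, method="L-BFGS-B",
                            jac="3-point",
                            options={"maxiter": 2000, "ftol": 1e-12})
    L, psi, Phi = build(res.x)
    # orient factors positively
    for f in range(nf):
        if L[np.argmax(np.abs(L[:, f])), f] < 0:
            L[:, f] *= -1.0
            Phi[f, :] *= -1.0
            Phi[:, f] *= -1.0
            np.fill_diagonal(Phi, 1.0)
    Sig = L @ Phi @ L.T + np.diag(psi)
    F = discrepancy(res.x)
    n = int(n_obs)
    loglik = -0.5 * n * (k * np.log(2 * np.pi) + np.linalg.slogdet(Sig)[1]
                         + np.trace(np.linalg.solve(Sig, S)))
    chi2 = max((n - 1) * F, 0.0)
    df = k * (k + 1) // 2 - n_params
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = max((n - 1) * F_b, 0.0)
    df_b = k * (k - 1) // 2
    return CFAFit(
        loadings=L, uniqueness=psi, factor_corr=Phi, pattern=mask,
        correlated=correlated, loglik=float(loglik), n_params=n_params,
        n_obs=n, chi2=float(chi2), df=int(df), chi2_baseline=float(chi2_b),
        df_baseline=int(df_b), srmr=srmr(Sig, S), implied=Sig, sample=S,
        converged=bool(res.success),
    )


@dataclass
class SplitHalfReport:
    n_factors: FactorCountPrediction
    efa: EFAPattern
    cfa_correlated: CFAFit
    cfa_uncorrelated: CFAFit
    indices: pd.DataFrame
    half_assignment: np.ndarray
    preferred_by_aic: str
    preferred_by_bic: str


def split_half_phenotypic_sem(Y, seed=None, efa_threshold: float = 0.3
                              ) -> SplitHalfReport:
    """Phenotypic EFA on one half, CFA on the other.

    The split is deterministic given the seed and stratified by per-row
    missingness count so both halves are balanced for missingness.  EFA
    (with PCA factor-count prediction) runs on half 1; half 2 receives a
    correlated-factor CFA of the implied simple structure and an
    uncorrelated variant keeping the thresholded cross-loadings.
    """
    Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
    n, k = Ydf.shape
    if n < 200:
        raise PipelineError("split-half analysis needs n >= 200")
    rng = np.random.default_rng(seed)
    miss = Ydf.isna().sum(axis=1).to_numpy()
    half = np.zeros(n, dtype=int)
    for count in np.unique(miss):
        idx = np.where(miss == count)[0]
        idx = rng.permutation(idx)
        half[idx[1::2]] = 1
    Y1, Y2 = Ydf.iloc[half == 0], Ydf.iloc[half == 1]

    R1 = Y1.corr(min_periods=2).to_numpy()
    if not np.isfinite(R1).all():
        raise PipelineError(
            "a covariance entry has no complete pairs in half 1"
        )
    pf = predict_n_factors(_safe_corr(R1))
    nP = max(pf.chosen, 1)
    efa = efa_pattern(_safe_corr(R1), nP, efa_threshold)

    S2 = Y2.cov(min_periods=2, ddof=0).to_numpy()
    if not np.isfinite(S2).all():
        raise PipelineError(
            "a covariance entry has no complete pairs in half 2"
        )
    n2 = int(Y2.notna().all(axis=1).sum() if Y2.isna().any().any()
             else len(Y2))
    # correlated variant: simple structure on the primary factor
    primary = np.zeros_like(efa.mask)
    for j in range(k):
        primary[j, int(np.argmax(np.abs(efa.loadings[j])))] = True
    cfa_corr = fit_phenotypic_cfa(S2, n2, primary, correlated=True)
    # uncorrelated variant: keep thresholded cross-loadings
    mask_u = efa.mask.copy()
    for j in range(k):
        if not mask_u[j].any():
            mask_u[j, int(np.argmax(np.abs(efa.loadings[j])))] = True
    cfa_unc = fit_phenotypic_cfa(S2, n2, mask_u, correlated=False)

    rows = []
    for name, fit in (("correlated", cfa_corr), ("uncorrelated", cfa_unc)):
        idxs = post.phenotypic_fit_indices(fit)
        rows.append({"model": name, "N_p": fit.n_params,
                     "LL": fit.loglik, "AIC": fit.aic, "BIC": fit.bic,
                     "SRMR": fit.srmr, "CFI": idxs.cfi, "TLI": idxs.tli,
                     "RMSEA": idxs.rmsea})
    indices = pd.DataFrame(rows).set_index("model")
    return SplitHalfReport(
        n_factors=pf, efa=efa, cfa_correlated=cfa_corr,
        cfa_uncorrelated=cfa_unc, indices=indices, half_assignment=half,
        preferred_by_aic=indices["AIC"].idxmin(),
        preferred_by_bic=indices["BIC"].idxmin(),
    )
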