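"""Gaussian likelihood of GRM-SEM models and its maximisation.

The model implies, for the stacked phenotype vector y = vec(Y) (trait-major,
i.e. trait blocks of n individuals),

    ΣV = C_G ⊗ G + C_I ⊗ I_n + C_X ⊗ G^{1/2},

where C_G, C_I and the gene-environment cross term C_X are the k×k kernel
coefficient matrices assembled from a
:class:`~latentgrm.models.ModelStructure`.  Two evaluation paths are
provided:

* a *rotated* path for complete data, exploiting the eigendecomposition
  G = U D Uᵀ: the rows of Ỹ = Uᵀ Y are independent with covariance
  Σᵢ = dᵢ·C_G + C_I + √dᵢ·C_X, reducing the cost from O((nk)³) to O(nk³);
* a *direct* path evaluating the multivariate-normal density of the
  observed (non-missing) subvector of y — full-information treatment of
  missingness by subsetting, at dense O((nk)³) cost.

Both paths share analytic score computations: with Wᵢ = Σᵢ⁻¹ − qᵢqᵢᵀ
(qᵢ = Σᵢ⁻¹ỹᵢ), the gradient of the log-likelihood reduces to inner
products of S_G = Σᵢ dᵢWᵢ, S_I = ΣᵢWᵢ and S_H = Σᵢ√dᵢWᵢ with the
derivatives of the coefficient matrices, which are linear in the loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .models import (
    ModelStructure,
    ParameterVector,
    assemble_matrices,
    coefficient_matrices,
    canonicalize_signs,
    make_structure,
)

LOG2PI = np.log(2.0 * np.pi)


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# raw <-> natural parameter scale (correlations through tanh)
# ---------------------------------------------------------------------------

def _to_raw(structure: ModelStructure, theta_nat: np.ndarray) -> np.ndarray:
    raw = np.array(theta_nat, dtype=float)
    corr = structure.is_corr_param()
    raw[corr] = np.arctanh(np.clip(raw[corr], -0.999999, 0.999999))
    return raw


def _to_nat(structure: ModelStructure, theta_raw: np.ndarray) -> np.ndarray:
    nat = np.array(theta_raw, dtype=float)
    corr = structure.is_corr_param()
    nat[corr] = np.tanh(nat[corr])
    return nat


def _raw_bounds(structure: ModelStructure):
    bounds = []
    for (lo, hi), c in zip(structure.param_bounds(), structure.is_corr_param()):
        bounds.append((-7.0, 7.0) if c else (lo, hi))
    return bounds


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------

def _sqrt_psd(G):
    d, U = linalg.eigh(G)
    return (U * np.sqrt(np.maximum(d, 0.0))) @ U.T


def implied_sigma(structure, theta, G, convention: str = "sqrt_g"):
    """Full nk×nk phenotypic covariance (trait-major stacking).

    ΣV = C_G⊗G + C_I⊗I + C_X⊗G^{1/2} under the default joint-normal
    (``sqrt_g``) rGE convention.  Under ``literal`` the rGE cross term
    enters the G kernel unsymmetrised; a resulting asymmetry beyond
    1e-10 is raised as an error rather than silently symmetrised.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    CG, CI, CX = coefficient_matrices(structure, theta, convention)
    sigma = np.kron(CG, G) + np.kron(CI, np.eye(n))
    if np.any(CX):
        sigma += np.kron(CX, _sqrt_psd(G))
    asym = np.max(np.abs(sigma - sigma.T))
    if asym > 1e-10:
        raise LikelihoodError(
            f"implied covariance asymmetric (max |Σ−Σᵀ| = {asym:.3g}); "
            "the literal per-kernel rGE convention does not define a valid "
            "covariance for this G"
        )
    return 0.5 * (sigma + sigma.T)


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------

def _as_array(Y):
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float)
    return np.asarray(Y, dtype=float)


def _grm_parts(G):
    """Accept an ndarray or a GRMatrix; return (values, eigen or None)."""
    if hasattr(G, "values") and hasattr(G, "individual_ids"):
        eig = None
        if getattr(G, "eigenvalues", None) is not None:
            eig = (G.eigenvalues, G.eigenvectors)
        return np.asarray(G.values, dtype=float), eig
    return np.asarray(G, dtype=float), None


def loglik_direct(structure, theta, Y, G, convention: str = "sqrt_g"):
    """Log-likelihood of the observed subvector of vec(Y), mean zero.

    Missing entries (NaN) are handled by full-information subsetting of
    the implied covariance.  Cost is O((n_obs)³) dense.
    """
    Y = _as_array(Y)
    Gv, _ = _grm_parts(G)
    n, k = Y.shape
    y = Y.ravel(order="F")          # trait-major stacking
    obs = np.isfinite(y)
    if not obs.any():
        raise LikelihoodError("no observed phenotype entries")
    sigma = implied_sigma(structure, theta, Gv, convention)
    sub = sigma[np.ix_(obs, obs)]
    try:
        cf = linalg.cho_factor(sub, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    q = linalg.cho_solve(cf, y[obs], check_finite=False)
    return -0.5 * (obs.sum() * LOG2PI + logdet + float(y[obs] @ q))


def loglik_rotated(structure, theta, Y, G, convention: str = "sqrt_g"):
    """Fast complete-data log-likelihood via the eigendecomposition of G.

    Refuses missing entries; callers with missing data must use
    :func:`loglik_direct`.
    """
    Y = _as_array(Y)
    if not np.isfinite(Y).all():
        raise LikelihoodError(
            "rotated likelihood path requires complete data; use the "
            "direct path for phenotypes with missing entries"
        )
    d, U = _eigen_of(G)
    Ytil = U.T @ Y
    CG, CI, CX = coefficient_matrices(structure, theta, convention)
    ll, _ = _rotated_core(Ytil, d, CG, CI, CX, want_scores=False)
    return ll


def _eigen_of(G):
    Gv, eig = _grm_parts(G)
    if eig is not None:
        return eig
    d, U = linalg.eigh(Gv)
    order = np.argsort(d)[::-1]
    return d[order], U[:, order]


def _rotated_core(Ytil, d, CG, CI, CX, want_scores: bool):
    """Batched per-eigenvalue Gaussian densities and score matrices."""
    n, k = Ytil.shape
    rd = np.sqrt(np.maximum(d, 0.0))
    A = d[:, None, None] * CG[None, :, :] + CI[None, :, :]
    if np.any(CX):
        A = A + rd[:, None, None] * CX[None, :, :]
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdet = 2.0 * np.sum(np.log(np.einsum("ijj->ij", L)))
    q = np.linalg.solve(A, Ytil[:, :, None])[:, :, 0]
    quad = np.einsum("ij,ij->", Ytil, q)
    ll = -0.5 * (n * k * LOG2PI + logdet + quad)
    if not want_scores:
        return ll, None
    P = np.linalg.inv(A)
    W = P - q[:, :, None] * q[:, None, :]
    SG = np.einsum("i,ijk->jk", d, W)
    SI = W.sum(axis=0)
    SH = np.einsum("i,ijk->jk", rd, W)
    return ll, (SG, SI, SH)


def _direct_core(structure, theta, Y, Gv, convention, want_scores: bool,
                 sqrtG=None):
    n, k = Y.shape
    y = Y.ravel(order="F")
    obs = np.isfinite(y)
    CG, CI, CX = coefficient_matrices(structure, theta, convention)
    sigma = np.kron(CG, Gv) + np.kron(CI, np.eye(n))
    has_cross = bool(np.any(CX))
    if has_cross:
        if sqrtG is None:
            sqrtG = _sqrt_psd(Gv)
        sigma += np.kron(CX, sqrtG)
    asym = np.max(np.abs(sigma - sigma.T))
    if asym > 1e-10:
        raise LikelihoodError(
            f"implied covariance asymmetric (max |Σ−Σᵀ| = {asym:.3g})")
    sub = sigma[np.ix_(obs, obs)]
    try:
        cf = linalg.cho_factor(sub, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, None
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    q = linalg.cho_solve(cf, y[obs], check_finite=False)
    ll = -0.5 * (obs.sum() * LOG2PI + logdet + float(y[obs] @ q))
    if not want_scores:
        return ll, None
    P = linalg.cho_solve(cf, np.eye(obs.sum()), check_finite=False)
    Wobs = P - np.outer(q, q)
    W = np.zeros((n * k, n * k))
    W[np.ix_(obs, obs)] = Wobs
    W4 = W.reshape(k, n, k, n)
    SG = np.einsum("aibj,ij->ab", W4, Gv)
    SI = np.einsum("aibi->ab", W4)
    if has_cross:
        SH = np.einsum("aibj,ij->ab", W4, sqrtG)
    else:
        SH = np.zeros_like(SG)
    return ll, (SG, SI, SH)


def _param_gradient(structure, theta_nat, scores,
                    convention: str = "sqrt_g"):
    """Gradient of the log-likelihood w.r.t. the natural parameters."""
    SG, SI, SH = scores
    LA, LE, PhiA, PhiE, Pc = assemble_matrices(structure, theta_nat)
    GA = 2.0 * SG @ LA @ PhiA
    GE = 2.0 * SI @ LE @ PhiE
    if structure.rge_enabled:
        # effective cross-score: 2·S_H for the G^{1/2} kernel, S_G+S_I
        # when the cross term is folded into the G and I kernels
        T = 2.0 * SH if convention == "sqrt_g" else SG + SI
        GA = GA + T @ LE @ Pc
        GE = GE + T @ LA @ Pc.T
        GPc = LE.T @ T @ LA
    else:
        GPc = None
    GPhiA = LA.T @ SG @ LA
    GPhiE = LE.T @ SI @ LE
    grad = np.empty(structure.n_params)
    for idx, (part, j, c) in enumerate(structure._free_positions()):
        if part == "A":
            g = GA[j, c]
        elif part == "E":
            g = GE[j, c]
        elif part == "phiA":
            g = 2.0 * GPhiA[j, c]
        elif part == "phiE":
            g = 2.0 * GPhiE[j, c]
        else:
            g = GPc[j, c]
        grad[idx] = -0.5 * g
    return grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimiser settings for :func:`fit_model`.

    ``n_restarts`` quasi-Newton runs start from the base start values
    perturbed multiplicatively by N(1, perturb_sd²); ``tol`` bounds the
    projected gradient norm of the mean log-likelihood at convergence.
    """

    n_restarts: int = 5
    seed: int | None = None
    tol: float = 1e-6
    maxiter: int = 2000
    convention: str = "sqrt_g"
    compute_se: bool = True
    path: str = "auto"            # auto | rotated | direct
    start: np.ndarray | None = None
    perturb_sd: float = 0.1
    # rGE likelihoods are multimodal in the sign of each correlation;
    # seed every combination of ±0.5 in addition to the base start
    rge_sign_grid: bool = True


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model structure."""

    structure: ModelStructure
    theta: np.ndarray
    loglik: float
    se: np.ndarray | None
    vcov_theta: np.ndarray | None
    converged: bool
    optimum_reached: bool
    identified: bool
    n_individuals: int
    n_observations: int
    gradient_norm: float
    n_restarts_used: int
    warnings: list = field(default_factory=list)
    path: str = "rotated"

    @property
    def n_params(self) -> int:
        return self.structure.n_params

    @property
    def parameters(self) -> ParameterVector:
        return ParameterVector.for_structure(self.structure, self.theta)

    @property
    def param_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "name": self.structure.param_names(),
            "estimate": self.theta,
        })
        tab["se"] = self.se if self.se is not None else np.nan
        return tab

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "theta": self.theta.tolist(),
            "names": self.structure.param_names(),
            "loglik": float(self.loglik),
            "se": None if self.se is None else self.se.tolist(),
            "converged": bool(self.converged),
            "optimum_reached": bool(self.optimum_reached),
            "identified": bool(self.identified),
            "n_individuals": int(self.n_individuals),
            "n_observations": int(self.n_observations),
            "gradient_norm": float(self.gradient_norm),
            "n_restarts_used": int(self.n_restarts_used),
            "warnings": list(self.warnings),
            "path": self.path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            structure=ModelStructure.from_dict(d["structure"]),
            theta=np.asarray(d["theta"], dtype=float),
            loglik=d["loglik"],
            se=None if d.get("se") is None else np.asarray(d["se"]),
            vcov_theta=None,
            converged=d["converged"],
            optimum_reached=d.get("optimum_reached", d["converged"]),
            identified=d.get("identified", d["converged"]),
            n_individuals=d["n_individuals"],
            n_observations=d["n_observations"],
            gradient_norm=d["gradient_norm"],
            n_restarts_used=d["n_restarts_used"],
            warnings=d.get("warnings", []),
            path=d.get("path", "rotated"),
        )


def default_start(structure: ModelStructure, Y) -> np.ndarray:
    """Moment-based starting values: split the sample phenotypic covariance
    evenly into A and E parts and project each onto the structure."""
    Y = _as_array(Y)
    S = pd.DataFrame(Y).cov(min_periods=2).to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    k = structure.k
    S = S + 1e-3 * np.mean(np.diag(S)) * np.eye(k)

    def side_start(mask, n_common, is_chol):
        half = S / 2.0
        L = np.zeros(mask.shape)
        if is_chol:
            try:
                L[:, :] = linalg.cholesky(half, lower=True)
            except linalg.LinAlgError:
                L[:, :] = np.diag(np.sqrt(np.maximum(np.diag(half), 1e-3)))
            return L * mask
        w, V = linalg.eigh(half)
        order = np.argsort(w)[::-1]
        w, V = np.maximum(w[order], 0.0), V[:, order]
        for f in range(n_common):
            col = V[:, f] * np.sqrt(w[f])
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            L[:, f] = col
        common = L[:, :n_common] * mask[:, :n_common]
        spec2 = np.maximum(np.diag(half) - np.sum(common**2, axis=1), 0.05)
        L[:, :n_common] = common
        L[:, n_common:] = np.diag(np.sqrt(spec2))
        return L * mask

    LA = side_start(structure.lambdaA_mask, structure.nA,
                    structure.a_is_cholesky)
    LE = side_start(structure.lambdaE_mask, structure.nE,
                    structure.e_is_cholesky)
    PhiA = np.eye(structure.ncol_A)
    PhiE = np.eye(structure.ncol_E)
    Pc = np.zeros((structure.ncol_E, structure.ncol_A))
    return structure.flatten(LA, LE, PhiA, PhiE, Pc)


def fit_model(structure: ModelStructure, Y, G,
              options: FitOptions | None = None) -> FitResult:
    """Maximise the GRM-SEM likelihood by multi-start quasi-Newton (L-BFGS-B
    with analytic gradients); standard errors from the inverse observed
    information (finite differences of the analytic score at the optimum)."""
    opts = options or FitOptions()
    Y = _as_array(Y)
    n, k = Y.shape
    if k != structure.k:
        raise LikelihoodError(
            f"phenotype matrix has {k} traits, structure expects {structure.k}"
        )
    Gv, _ = _grm_parts(G)
    if Gv.shape != (n, n):
        raise LikelihoodError("GRM dimensions do not match the phenotypes")
    complete = bool(np.isfinite(Y).all())
    path = opts.path
    if path == "auto":
        path = "rotated" if complete else "direct"
    if path == "rotated" and not complete:
        raise LikelihoodError(
            "rotated path requires complete data; use path='direct'"
        )
    n_obs = int(np.isfinite(Y).sum())
    scale = 1.0 / n_obs     # optimise the mean log-likelihood per observation

    if path == "rotated":
        d, U = _eigen_of(G)
        Ytil = U.T @ Y

        def evaluate(theta_nat, want_scores):
            CG, CI, CX = coefficient_matrices(structure, theta_nat,
                                              opts.convention)
            return _rotated_core(Ytil, d, CG, CI, CX, want_scores)
    else:
        sqrtG = (_sqrt_psd(Gv)
                 if structure.rge_enabled and opts.convention == "sqrt_g"
                 else None)

        def evaluate(theta_nat, want_scores):
            return _direct_core(structure, theta_nat, Y, Gv,
                                opts.convention, want_scores, sqrtG=sqrtG)

    corr = structure.is_corr_param()

    def nll_and_grad(theta_raw):
        nat = _to_nat(structure, theta_raw)
        ll, scores = evaluate(nat, want_scores=True)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta_raw)
        g_nat = _param_gradient(structure, nat, scores, opts.convention)
        g_raw = g_nat.copy()
        g_raw[corr] *= (1.0 - nat[corr] ** 2)      # tanh chain rule
        return -ll * scale, -g_raw * scale

    base = opts.start if opts.start is not None else default_start(structure, Y)
    base = np.asarray(base, dtype=float)
    rng = np.random.default_rng(opts.seed)
    bounds = _raw_bounds(structure)
    nonneg = structure.is_nonneg_param()

    starts = [base]
    for _ in range(max(opts.n_restarts - 1, 0)):
        pert = base * rng.normal(1.0, opts.perturb_sd, size=base.shape)
        pert[corr] = np.clip(base[corr] + rng.normal(0, 0.05, corr.sum()),
                             -0.9, 0.9)
        pert[nonneg] = np.abs(pert[nonneg])
        starts.append(pert)
    if structure.rge_enabled and opts.rge_sign_grid:
        rge_idx = [i for i, p in enumerate(structure._free_positions())
                   if p[0] == "rge"]
        if rge_idx and len(rge_idx) <= 4:
            from itertools import product
            for signs in product((0.5, -0.5), repeat=len(rge_idx)):
                var = base.copy()
                var[rge_idx] = signs
                starts.append(var)

    best = None
    for start_nat in starts:
        x0 = _to_raw(structure, start_nat)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            nll_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": 1e-12,
                     "gtol": opts.tol},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta_nat = canonicalize_signs(structure, _to_nat(structure, best.x))
    theta_raw = _to_raw(structure, theta_nat)
    ll, scores = evaluate(theta_nat, want_scores=True)
    if scores is not None:
        g_nat = _param_gradient(structure, theta_nat, scores,
                                opts.convention)
        g_raw = g_nat.copy()
        g_raw[corr] *= (1.0 - theta_nat[corr] ** 2)
        grad_norm = float(np.max(np.abs(g_raw))) * scale
    else:
        grad_norm = np.inf

    # bound-activity: parameters pinned at a box bound are expected to
    # have one-sided gradients and flat Hessian directions
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    active_lo = theta_raw - lo < 1e-6
    active_hi = hi - theta_raw < 1e-6
    interior = ~(active_lo | active_hi)

    warns: list[str] = []
    se = vcov = None
    hess_pd = True
    if opts.compute_se and np.isfinite(ll):
        H = _numerical_hessian(nll_and_grad, theta_raw)
        Hint = H[np.ix_(interior, interior)]
        if Hint.size:
            eigvals = linalg.eigvalsh(Hint)
            hess_pd = eigvals.min() > 1e-10 * max(eigvals.max(), 1.0)
        if not hess_pd:
            warns.append(
                "observed information is singular or not positive definite "
                "over the interior parameters (flat likelihood direction; "
                "model may be unidentified)"
            )
        full_eigs = linalg.eigvalsh(H)
        if full_eigs.min() > 1e-10 * max(full_eigs.max(), 1.0):
            vcov_raw = np.linalg.inv(H) * scale
        else:
            vcov_raw = np.linalg.pinv(H) * scale
        J = np.ones(structure.n_params)
        J[corr] = 1.0 - theta_nat[corr] ** 2
        vcov = vcov_raw * np.outer(J, J)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        at_bound = [structure.param_names()[i]
                    for i in np.where(~interior)[0]]
        if at_bound:
            warns.append(
                f"parameters at a bound (SEs not boundary-corrected): "
                f"{at_bound}")

    # projected gradient of the scaled objective: at an active bound only
    # the descent-feasible component counts
    if scores is not None:
        g = -g_raw * scale          # gradient of the scaled nll
        pg_vec = g.copy()
        pg_vec[active_lo] = np.minimum(g[active_lo], 0.0)
        pg_vec[active_hi] = np.maximum(g[active_hi], 0.0)
        pg = float(np.max(np.abs(pg_vec)))
        grad_norm = pg
    else:
        pg = np.inf
    pg_opt = np.max(np.abs(best.jac)) if np.size(best.jac) else np.inf
    optimum_reached = bool(best.success and np.isfinite(ll)
                           and min(pg, pg_opt) <= 10 * opts.tol)
    return FitResult(
        structure=structure,
        theta=theta_nat,
        loglik=float(ll),
        se=se,
        vcov_theta=vcov,
        converged=bool(optimum_reached and hess_pd),
        optimum_reached=optimum_reached,
        identified=bool(hess_pd),
        n_individuals=n,
        n_observations=n_obs,
        gradient_norm=grad_norm,
        n_restarts_used=len(starts),
        warnings=warns,
        path=path,
    )


def _numerical_hessian(fun_grad, x, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    p = x.size
    H = np.zeros((p, p))
    for i in range(p):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# univariate SNP heritability
# ---------------------------------------------------------------------------

@dataclass
class UnivariateH2:
    h2: float
    se: float
    p_lrt: float
    sigma_a2: float
    sigma_e2: float
    loglik: float
    loglik_null: float
    fit: FitResult


def fit_univariate_h2(y, G, options: FitOptions | None = None) -> UnivariateH2:
    """ML variance-component fit of a single trait (k=1 Cholesky).

    The LRT p-value compares against the residual-only model using the
    50:50 χ²₀/χ²₁ boundary mixture.
    """
    y = np.asarray(y, dtype=float).ravel()
    Gv, _ = _grm_parts(G)
    keep = np.isfinite(y)
    if keep.sum() < 2:
        raise LikelihoodError("need at least 2 non-missing individuals")
    y = y[keep]
    Gs = Gv[np.ix_(keep, keep)]
    n = y.size
    structure = make_structure("cholesky", k=1, trait_names=["trait"])
    opts = options or FitOptions(n_restarts=3)
    sd = float(np.std(y))
    # boundary optima (h2 near 0 or 1) need boundary-adjacent starts
    fit = None
    for start in ([sd * 0.6, sd * 0.8], [sd, sd * 0.05], [sd * 0.05, sd]):
        o = FitOptions(**{**opts.__dict__, "start": np.asarray(start)})
        cand = fit_model(structure, y[:, None], Gs, o)
        if fit is None or cand.loglik > fit.loglik + 1e-9:
            fit = cand
    a, e = fit.theta
    v = a * a + e * e
    h2 = a * a / v
    se = np.nan
    if fit.vcov_theta is not None:
        grad = np.array([2 * a * e * e / v**2, -2 * e * a * a / v**2])
        se = float(np.sqrt(max(grad @ fit.vcov_theta @ grad, 0.0)))
    # residual-only null: σ̂² = mean(y²) in closed form
    s2 = float(np.mean(y**2))
    ll0 = -0.5 * n * (LOG2PI + np.log(s2) + 1.0)
    chi2 = max(2.0 * (fit.loglik - ll0), 0.0)
    p = 0.5 * stats.chi2.sf(chi2, 1) if chi2 > 0 else 1.0
    return UnivariateH2(
        h2=float(h2), se=se, p_lrt=float(p),
        sigma_a2=float(a * a), sigma_e2=float(e * e),
        loglik=float(fit.loglik), loglik_null=float(ll0), fit=fit,
    )
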