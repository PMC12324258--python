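"""Declarative factor-model structures for GRM-SEM.

A model structure describes how the k×k genomic (ΣA) and residual (ΣE)
covariance matrices are parameterised through factor loading matrices:

* ``cholesky`` — ΛA and ΛE are k×k lower-triangular (saturated baseline).
* ``ip`` — Independent Pathway: nA common genomic factors plus k
  trait-specific genomic factors (AS), and likewise nE common residual
  factors plus k specific residual factors (ES).
* ``ipc`` / ``cip`` — hybrids: IP genomic part with Cholesky residual part,
  and vice versa.
* ``bifactor_a`` / ``bifactor_e`` — one general factor loading on every
  trait plus group factors, on the genomic or residual side, used to test
  the independence of identified factors.

IP-family structures may additionally free gene-environment correlations
(rGE) between common genomic and common residual factors; specific factors
never correlate across the A/E divide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

KINDS = ("cholesky", "ip", "ipc", "cip", "bifactor_a", "bifactor_e")

# loading-matrix entries live on an unbounded scale; correlations are
# estimated through a tanh bijection, so natural bounds are open (-1, 1)
LOADING_BOUND = 5.0
CORR_BOUND = 0.999999


class ModelSpecError(ValueError):
    pass


def _pattern_to_mask(pattern, k: int, n_factors: int) -> np.ndarray:
    """Convert a trait->factor membership pattern to a k×n boolean mask."""
    if pattern is None:
        return np.ones((k, n_factors), dtype=bool)
    pattern = np.asarray(pattern)
    if pattern.dtype == bool and pattern.shape == (k, n_factors):
        return pattern.copy()
    raise ModelSpecError(
        f"loading pattern must be a {k}×{n_factors} boolean mask"
    )


def pattern_from_groups(groups, k: int) -> np.ndarray:
    """Build a k×n_factors mask from a list of per-factor trait-index lists."""
    mask = np.zeros((k, len(groups)), dtype=bool)
    for f, members in enumerate(groups):
        for j in members:
            mask[j, f] = True
    return mask


@dataclass
class ModelStructure:
    """Free-parameter bookkeeping for one GRM-SEM model family.

    ``lambdaA_mask`` is k×(nA+k) for IP-like genomic parts (common block
    followed by the diagonal specific block) and k×k lower-triangular for
    Cholesky parts; ``lambdaE_mask`` likewise.  ``rge_mask`` frees entries
    of the common-factor block of Φcov(A,E) (nE×nA).  ``fixed_values`` maps
    masked-out positions, e.g. ``("A", j, c)``, to constants (used by the
    λAS<threshold constraint step).
    """

    kind: str
    k: int
    nA: int
    nE: int
    lambdaA_mask: np.ndarray
    lambdaE_mask: np.ndarray
    rge_enabled: bool = False
    rge_mask: np.ndarray | None = None
    phiA_free: np.ndarray | None = None
    phiE_free: np.ndarray | None = None
    fixed_values: dict = field(default_factory=dict)
    trait_names: list[str] | None = None
    factor_names_A: list[str] | None = None
    factor_names_E: list[str] | None = None

    # -- derived geometry ------------------------------------------------
    @property
    def a_is_cholesky(self) -> bool:
        return self.kind in ("cholesky", "cip")

    @property
    def e_is_cholesky(self) -> bool:
        return self.kind in ("cholesky", "ipc")

    @property
    def ncol_A(self) -> int:
        return self.k if self.a_is_cholesky else self.nA + self.k

    @property
    def ncol_E(self) -> int:
        return self.k if self.e_is_cholesky else self.nE + self.k

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ModelSpecError(f"unknown model kind {self.kind!r}")
        self.lambdaA_mask = np.asarray(self.lambdaA_mask, dtype=bool)
        self.lambdaE_mask = np.asarray(self.lambdaE_mask, dtype=bool)
        if self.lambdaA_mask.shape != (self.k, self.ncol_A):
            raise ModelSpecError("lambdaA_mask has the wrong shape")
        if self.lambdaE_mask.shape != (self.k, self.ncol_E):
            raise ModelSpecError("lambdaE_mask has the wrong shape")
        if self.rge_enabled:
            if self.a_is_cholesky or self.e_is_cholesky:
                raise ModelSpecError(
                    "rGE requires common factors on both the A and E side "
                    "(IP-family structures)"
                )
            if self.rge_mask is None:
                self.rge_mask = np.zeros((self.nE, self.nA), dtype=bool)
            self.rge_mask = np.asarray(self.rge_mask, dtype=bool)
            if self.rge_mask.shape != (self.nE, self.nA):
                raise ModelSpecError("rge_mask must be nE×nA")
        if self.trait_names is None:
            self.trait_names = [f"trait{j + 1}" for j in range(self.k)]
        self._check_identified()

    def _check_identified(self):
        fixed_nonzero_A = np.zeros(self.k, dtype=bool)
        fixed_nonzero_E = np.zeros(self.k, dtype=bool)
        for (part, j, _c), v in self.fixed_values.items():
            if v != 0.0:
                (fixed_nonzero_A if part == "A" else fixed_nonzero_E)[j] = True
        has_A = self.lambdaA_mask.any(axis=1) | fixed_nonzero_A
        has_E = self.lambdaE_mask.any(axis=1) | fixed_nonzero_E
        orphan = ~(has_A | has_E)
        if orphan.any():
            bad = [self.trait_names[j] for j in np.where(orphan)[0]]
            raise ModelSpecError(
                f"unidentified trait(s) with no free loading in either the "
                f"genomic or the residual part: {bad}"
            )

    # -- parameter layout ------------------------------------------------
    def _free_positions(self):
        """Ordered free positions: λA, λE, ΦA corr, ΦE corr, rGE."""
        pos = []
        for j, c in np.argwhere(self.lambdaA_mask):
            pos.append(("A", int(j), int(c)))
        for j, c in np.argwhere(self.lambdaE_mask):
            pos.append(("E", int(j), int(c)))
        if self.phiA_free is not None:
            for i, j in np.argwhere(np.triu(self.phiA_free, 1)):
                pos.append(("phiA", int(i), int(j)))
        if self.phiE_free is not None:
            for i, j in np.argwhere(np.triu(self.phiE_free, 1)):
                pos.append(("phiE", int(i), int(j)))
        if self.rge_enabled:
            for e, a in np.argwhere(self.rge_mask):
                pos.append(("rge", int(e), int(a)))
        return pos

    @property
    def n_params(self) -> int:
        return len(self._free_positions())

    def param_names(self) -> list[str]:
        names = []
        tn = self.trait_names
        fA = self.factor_names_A or [f"A{f + 1}" for f in range(self.nA)]
        fE = self.factor_names_E or [f"E{f + 1}" for f in range(self.nE)]
        for part, j, c in self._free_positions():
            if part == "A":
                if self.a_is_cholesky:
                    names.append(f"lA_{tn[j]}_F{c + 1}")
                elif c < self.nA:
                    names.append(f"lA_{tn[j]}_{fA[c]}")
                else:
                    names.append(f"lAS_{tn[j]}")
            elif part == "E":
                if self.e_is_cholesky:
                    names.append(f"lE_{tn[j]}_F{c + 1}")
                elif c < self.nE:
                    names.append(f"lE_{tn[j]}_{fE[c]}")
                else:
                    names.append(f"lES_{tn[j]}")
            elif part == "phiA":
                names.append(f"rg_{fA[j]}_{fA[c]}")
            elif part == "phiE":
                names.append(f"re_{fE[j]}_{fE[c]}")
            else:
                names.append(f"rGE_{fE[j]}_{fA[c]}")
        return names

    def is_corr_param(self) -> np.ndarray:
        """Boolean per parameter: True for correlation-type parameters."""
        return np.array(
            [p[0] in ("phiA", "phiE", "rge") for p in self._free_positions()]
        )

    def is_nonneg_param(self) -> np.ndarray:
        """Sign-identification constraints: Cholesky diagonals and specific
        loadings are kept non-negative."""
        out = []
        for part, j, c in self._free_positions():
            if part == "A":
                out.append((self.a_is_cholesky and j == c)
                           or (not self.a_is_cholesky and c >= self.nA))
            elif part == "E":
                out.append((self.e_is_cholesky and j == c)
                           or (not self.e_is_cholesky and c >= self.nE))
            else:
                out.append(False)
        return np.array(out, dtype=bool)

    def param_bounds(self) -> list[tuple[float, float]]:
        bounds = []
        corr = self.is_corr_param()
        nonneg = self.is_nonneg_param()
        for i in range(self.n_params):
            if corr[i]:
                bounds.append((-CORR_BOUND, CORR_BOUND))
            elif nonneg[i]:
                bounds.append((0.0, LOADING_BOUND))
            else:
                bounds.append((-LOADING_BOUND, LOADING_BOUND))
        return bounds

    # -- matrix assembly -------------------------------------------------
    def assemble(self, theta):
        return assemble_matrices(self, theta)

    def flatten(self, LA, LE, PhiA=None, PhiE=None, Phicov=None) -> np.ndarray:
        """Inverse of :func:`assemble_matrices` over the free masks."""
        theta = []
        for part, j, c in self._free_positions():
            if part == "A":
                theta.append(LA[j, c])
            elif part == "E":
                theta.append(LE[j, c])
            elif part == "phiA":
                theta.append(PhiA[j, c])
            elif part == "phiE":
                theta.append(PhiE[j, c])
            else:
                theta.append(Phicov[j, c])
        return np.asarray(theta, dtype=float)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "k": self.k,
            "nA": self.nA,
            "nE": self.nE,
            "lambdaA_mask": self.lambdaA_mask.astype(int).tolist(),
            "lambdaE_mask": self.lambdaE_mask.astype(int).tolist(),
            "rge_enabled": self.rge_enabled,
            "trait_names": list(self.trait_names),
        }
        if self.rge_enabled:
            d["rge_mask"] = self.rge_mask.astype(int).tolist()
        if self.phiA_free is not None:
            d["phiA_free"] = self.phiA_free.astype(int).tolist()
        if self.phiE_free is not None:
            d["phiE_free"] = self.phiE_free.astype(int).tolist()
        if self.fixed_values:
            d["fixed_values"] = [
                {"part": p, "row": j, "col": c, "value": float(v)}
                for (p, j, c), v in sorted(self.fixed_values.items())
            ]
        if self.factor_names_A:
            d["factor_names_A"] = list(self.factor_names_A)
        if self.factor_names_E:
            d["factor_names_E"] = list(self.factor_names_E)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        fixed = {}
        for item in d.get("fixed_values", []):
            fixed[(item["part"], item["row"], item["col"])] = item["value"]
        return cls(
            kind=d["kind"],
            k=d["k"],
            nA=d["nA"],
            nE=d["nE"],
            lambdaA_mask=np.asarray(d["lambdaA_mask"], dtype=bool),
            lambdaE_mask=np.asarray(d["lambdaE_mask"], dtype=bool),
            rge_enabled=d.get("rge_enabled", False),
            rge_mask=(np.asarray(d["rge_mask"], dtype=bool)
                      if "rge_mask" in d else None),
            phiA_free=(np.asarray(d["phiA_free"], dtype=bool)
                       if "phiA_free" in d else None),
            phiE_free=(np.asarray(d["phiE_free"], dtype=bool)
                       if "phiE_free" in d else None),
            fixed_values=fixed,
            trait_names=d.get("trait_names"),
            factor_names_A=d.get("factor_names_A"),
            factor_names_E=d.get("factor_names_E"),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelStructure":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ParameterVector:
    """Free parameters of one structure, with labels and natural bounds."""

    theta: np.ndarray
    names: list[str]
    bounds: list[tuple[float, float]]

    @classmethod
    def for_structure(cls, structure: ModelStructure, theta) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (structure.n_params,):
            raise ModelSpecError(
                f"theta has length {theta.size}, structure has "
                f"{structure.n_params} free parameters"
            )
        return cls(theta, structure.param_names(), structure.param_bounds())


def make_structure(
    kind: str,
    k: int,
    nA: int | None = None,
    nE: int | None = None,
    pattern_A=None,
    pattern_E=None,
    rge: bool = False,
    rge_pairs="matched",
    free_factor_corr_A: bool = False,
    free_factor_corr_E: bool = False,
    trait_names=None,
    factor_names_A=None,
    factor_names_E=None,
) -> ModelStructure:
    """Construct a model structure for one family.

    ``pattern_A`` / ``pattern_E`` give the trait→common-factor membership
    (k×n boolean mask, or a list of per-factor trait-index lists) for
    IP-like parts; Cholesky parts ignore them.  ``rge_pairs`` is either
    ``"matched"`` (one rGE per structurally matched factor pair, the
    default), ``"full"`` (the whole common block of Φcov), or an explicit
    list of (e_factor, a_factor) pairs.
    """
    kind = kind.lower()
    if kind not in KINDS:
        raise ModelSpecError(f"unknown model kind {kind!r}")
    if isinstance(pattern_A, (list, tuple)):
        pattern_A = pattern_from_groups(pattern_A, k)
    if isinstance(pattern_E, (list, tuple)):
        pattern_E = pattern_from_groups(pattern_E, k)

    def ip_mask(pattern, n, general=False):
        common = _pattern_to_mask(pattern, k, n - 1 if general else n)
        if general:
            common = np.hstack([np.ones((k, 1), dtype=bool), common])
        return np.hstack([common, np.eye(k, dtype=bool)])

    chol_mask = np.tril(np.ones((k, k), dtype=bool))

    if kind == "cholesky":
        nA = nE = k
        maskA, maskE = chol_mask, chol_mask.copy()
    elif kind == "ip":
        if not (nA and nE and 1 <= nA <= k and 1 <= nE <= k):
            raise ModelSpecError("ip requires 1 <= nA, nE <= k")
        maskA, maskE = ip_mask(pattern_A, nA), ip_mask(pattern_E, nE)
    elif kind == "ipc":
        if not (nA and 1 <= nA <= k):
            raise ModelSpecError("ipc requires 1 <= nA <= k")
        nE = k
        maskA, maskE = ip_mask(pattern_A, nA), chol_mask
    elif kind == "cip":
        if not (nE and 1 <= nE <= k):
            raise ModelSpecError("cip requires 1 <= nE <= k")
        nA = k
        maskA, maskE = chol_mask, ip_mask(pattern_E, nE)
    elif kind == "bifactor_a":
        # one general A factor on all traits + group factors + specifics
        if nA is None:
            nA = 1 + (pattern_A.shape[1] if pattern_A is not None else 1)
        if not (nE and 1 <= nE <= k):
            raise ModelSpecError("bifactor_a requires an E-side factor count")
        maskA = ip_mask(pattern_A, nA, general=True)
        maskE = ip_mask(pattern_E, nE)
    else:  # bifactor_e
        if nE is None:
            nE = 1 + (pattern_E.shape[1] if pattern_E is not None else 1)
        if not (nA and 1 <= nA <= k):
            raise ModelSpecError("bifactor_e requires an A-side factor count")
        maskA = ip_mask(pattern_A, nA)
        maskE = ip_mask(pattern_E, nE, general=True)

    rge_mask = None
    if rge:
        rge_mask = np.zeros((nE, nA), dtype=bool)
        if isinstance(rge_pairs, str) and rge_pairs == "matched":
            for f in range(min(nA, nE)):
                rge_mask[f, f] = True
        elif isinstance(rge_pairs, str) and rge_pairs == "full":
            rge_mask[:, :] = True
        else:
            for e_f, a_f in rge_pairs:
                rge_mask[e_f, a_f] = True

    phiA_free = None
    if free_factor_corr_A and kind in ("ip", "ipc", "bifactor_e"):
        phiA_free = np.ones((nA, nA), dtype=bool) & ~np.eye(nA, dtype=bool)
    phiE_free = None
    if free_factor_corr_E and kind in ("ip", "cip", "bifactor_a"):
        phiE_free = np.ones((nE, nE), dtype=bool) & ~np.eye(nE, dtype=bool)

    return ModelStructure(
        kind=kind, k=k, nA=nA, nE=nE,
        lambdaA_mask=maskA, lambdaE_mask=maskE,
        rge_enabled=rge, rge_mask=rge_mask,
        phiA_free=phiA_free, phiE_free=phiE_free,
        trait_names=list(trait_names) if trait_names is not None else None,
        factor_names_A=factor_names_A, factor_names_E=factor_names_E,
    )


def count_parameters(structure: ModelStructure) -> int:
    """Number of free parameters N_p (loadings + factor correlations + rGE)."""
    return structure.n_params


def assemble_matrices(structure: ModelStructure, theta):
    """Realise (ΛA, ΛE, ΦA, ΦE, Φcov) from the free-parameter vector.

    ΦA and ΦE carry unit diagonals (unit factor variances); Φcov is the
    (nE+k)×(nA+k) gene-environment covariance block, nonzero only among
    common factors, and identically zero when rGE is disabled.
    """
    s = structure
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (s.n_params,):
        raise ModelSpecError(
            f"theta has length {theta.size}, expected {s.n_params}"
        )
    LA = np.zeros((s.k, s.ncol_A))
    LE = np.zeros((s.k, s.ncol_E))
    PhiA = np.eye(s.ncol_A)
    PhiE = np.eye(s.ncol_E)
    Phicov = np.zeros((s.ncol_E, s.ncol_A))
    for (part, j, c), v in s.fixed_values.items():
        if part == "A":
            LA[j, c] = v
        elif part == "E":
            LE[j, c] = v
    for (part, j, c), v in zip(s._free_positions(), theta):
        if part == "A":
            LA[j, c] = v
        elif part == "E":
            LE[j, c] = v
        elif part == "phiA":
            PhiA[j, c] = PhiA[c, j] = v
        elif part == "phiE":
            PhiE[j, c] = PhiE[c, j] = v
        else:
            Phicov[j, c] = v
    return LA, LE, PhiA, PhiE, Phicov


def coefficient_matrices(structure, theta, convention: str = "sqrt_g"):
    """Kernel coefficient matrices (C_G, C_I, C_X) with

        ΣV = C_G ⊗ G + C_I ⊗ I + C_X ⊗ K_cross .

    Without rGE, C_G = ΛA ΦA ΛAᵀ, C_I = ΛE ΦE ΛEᵀ and C_X = 0.  With rGE
    the cross term M = ΛE Φcov ΛAᵀ enters according to the convention:

    * ``sqrt_g`` (default) — C_X = M + Mᵀ under the kernel G^{1/2}: the
      joint-normal model in which genetic factor scores are N(0, G),
      residual scores N(0, I), and each pair correlates per individual
      (Cov(g_f, e_h) = rGE·G^{1/2}); every trait pair's covariance then
      follows a·d + e + 2c·√d across the GRM eigenvalue spectrum, which
      separates the three components.
    * ``mean`` — (M+Mᵀ)/2 folded into both C_G and C_I (cross kernel
      (G+I)/2); C_X = 0.
    * ``literal`` — M into C_G and Mᵀ into C_I exactly as the augmented
      matrix algebra is printed; C_X = 0 and ΣV is asymmetric whenever M
      is asymmetric and G ≠ I.

    All conventions coincide for G = I or rGE = 0 and share the per-trait
    variance decomposition a + e + 2c.
    """
    LA, LE, PhiA, PhiE, Phicov = assemble_matrices(structure, theta)
    CG = LA @ PhiA @ LA.T
    CI = LE @ PhiE @ LE.T
    CX = np.zeros_like(CG)
    if structure.rge_enabled:
        M = LE @ Phicov @ LA.T
        if convention == "sqrt_g":
            CX = M + M.T
        elif convention in ("mean", "symmetric"):
            Msym = 0.5 * (M + M.T)
            CG = CG + Msym
            CI = CI + Msym
        elif convention == "literal":
            CG = CG + M
            CI = CI + M.T
        else:
            raise ModelSpecError(f"unknown kernel convention {convention!r}")
    return CG, CI, CX


def constrain_small_loadings(
    structure: ModelStructure,
    fit,
    threshold: float = 0.05,
    parts: str = "AE",
) -> ModelStructure:
    """Fix to zero every free *specific* loading estimated below threshold.

    ``fit`` is a FitResult (or anything with ``.theta``) estimated under
    ``structure``.  Returns a new structure whose parameter count has
    dropped by the number of constrained loadings.
    """
    theta = np.asarray(getattr(fit, "theta", fit), dtype=float)
    maskA = structure.lambdaA_mask.copy()
    maskE = structure.lambdaE_mask.copy()
    fixed = dict(structure.fixed_values)
    for (part, j, c), v in zip(structure._free_positions(), theta):
        if part == "A" and "A" in parts and not structure.a_is_cholesky \
                and c >= structure.nA and abs(v) < threshold:
            maskA[j, c] = False
            fixed[("A", j, c)] = 0.0
        if part == "E" and "E" in parts and not structure.e_is_cholesky \
                and c >= structure.nE and abs(v) < threshold:
            maskE[j, c] = False
            fixed[("E", j, c)] = 0.0
    return replace(
        structure, lambdaA_mask=maskA, lambdaE_mask=maskE, fixed_values=fixed
    )


def carry_theta(old: ModelStructure, theta_old, new: ModelStructure,
                fill: float = 0.0) -> np.ndarray:
    """Map a parameter vector between two structures by shared positions."""
    values = dict(zip(old._free_positions(), np.asarray(theta_old, float)))
    return np.array([values.get(p, fill) for p in new._free_positions()])


def canonicalize_signs(structure: ModelStructure, theta) -> np.ndarray:
    """Map theta to the identified sign representative.

    The likelihood is invariant to flipping all loadings of any common
    factor (together with that factor's rGE row/column) and to flipping
    any specific loading or Cholesky column.  The representative keeps
    Cholesky diagonals and specific loadings non-negative and, for each
    common factor, its largest-magnitude loading positive.
    """
    s = structure
    LA, LE, PhiA, PhiE, Phicov = assemble_matrices(s, theta)

    def fix_side(L, n_common, is_chol, Phi, cov, cov_axis):
        if is_chol:
            for c in range(s.k):
                if L[c, c] < 0:
                    L[:, c] *= -1.0
            return
        for f in range(n_common):
            col = L[:, f]
            if col[np.argmax(np.abs(col))] < 0:
                L[:, f] *= -1.0
                Phi[f, :] *= -1.0
                Phi[:, f] *= -1.0
                np.fill_diagonal(Phi, 1.0)
                if cov is not None:
                    if cov_axis == 0:
                        cov[f, :] *= -1.0
                    else:
                        cov[:, f] *= -1.0
        # specific loadings: sign-free, keep non-negative
        L[:, n_common:] = np.abs(L[:, n_common:])

    fix_side(LA, s.nA, s.a_is_cholesky, PhiA,
             Phicov if s.rge_enabled else None, 1)
    fix_side(LE, s.nE, s.e_is_cholesky, PhiE,
             Phicov if s.rge_enabled else None, 0)
    return s.flatten(LA, LE, PhiA, PhiE, Phicov)
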