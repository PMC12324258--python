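"""Phenotype preparation: reverse coding, covariate adjustment, normalisation.

Traits are aligned so that higher scores mean more difficulties, then put
through a double residualisation: OLS residuals on the covariates, a
rank-based inverse-normal transform of those residuals (Blom offset
(r − 3/8)/(n + 1/4), average ranks for ties), and a second residualisation
on the same covariates so that the rank transform cannot re-introduce
covariate effects.  Missing entries are never imputed; they propagate as
NaN to the likelihood engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """n×k trait table (NaN = missing) with a transformation log."""

    values: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise PhenotypeError("duplicate individual IDs")

    @property
    def individual_ids(self) -> list:
        return list(self.values.index)

    @property
    def trait_labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class CovariateTable:
    """n×c design columns (age, age², sex, interactions, ancestry PCs, ...)."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise PhenotypeError("duplicate individual IDs")
        nunique = self.values.nunique(dropna=True)
        if (nunique <= 1).any():
            bad = list(nunique.index[nunique <= 1])
            raise PhenotypeError(f"constant covariate column(s): {bad}")

    @property
    def individual_ids(self) -> list:
        return list(self.values.index)


def reverse_code(scores, max_ref: float | None = None):
    """Monotone-decreasing recode so high scores mean more difficulty.

    Implemented as negation (max_ref − x when a reference maximum is
    given); rank-equivalent to any max−x scheme since the subsequent
    transform uses only ranks.  Missing values are preserved.
    """
    if isinstance(scores, pd.Series):
        return (max_ref - scores) if max_ref is not None else -scores
    scores = np.asarray(scores, dtype=float)
    return (max_ref - scores) if max_ref is not None else -scores


def rank_inverse_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    obs = np.isfinite(x)
    n = int(obs.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(x[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_full_rank(X: np.ndarray, names) -> None:
    D = _design(X)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # locate offending columns by pivoted QR on the non-intercept part
        _, _, piv = linalg.qr(D, pivoting=True, mode="economic")
        redundant = sorted(piv[rank:])
        bad = [("intercept" if j == 0 else str(names[j - 1]))
               for j in redundant]
        raise PhenotypeError(
            f"rank-deficient covariate design; redundant column(s): {bad}"
        )


def _residualise(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    D = _design(X)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def double_residual_rank_transform(y, covariates=None) -> pd.Series | np.ndarray:
    """Covariate-residualise → inverse-normal transform → residualise again.

    ``covariates`` may be a CovariateTable, a DataFrame, an array or None.
    Only rows complete for the trait and all covariates are transformed;
    other rows stay missing.
    """
    is_series = isinstance(y, pd.Series)
    index = y.index if is_series else None
    name = y.name if is_series else None
    yv = np.asarray(y, dtype=float).ravel()

    if covariates is None:
        Xv = np.empty((yv.size, 0))
        names = []
    else:
        if isinstance(covariates, CovariateTable):
            covariates = covariates.values
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            Xv = covariates.to_numpy(dtype=float)
        else:
            Xv = np.asarray(covariates, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            names = [f"x{j + 1}" for j in range(Xv.shape[1])]
        if Xv.shape[0] != yv.size:
            raise PhenotypeError("covariates and trait have different lengths")

    complete = np.isfinite(yv) & np.isfinite(Xv).all(axis=1)
    nc = int(complete.sum())
    if nc <= Xv.shape[1] + 2:
        raise PhenotypeError(
            f"only {nc} complete cases for {Xv.shape[1]} covariates"
        )
    _check_full_rank(Xv[complete], names)

    out = np.full_like(yv, np.nan)
    resid1 = _residualise(yv[complete], Xv[complete])
    # a numerically perfect fit leaves only rounding noise; rank-transforming
    # that noise would fabricate variation, so treat it as exact ties
    scale = np.std(yv[complete])
    if scale > 0 and np.std(resid1) < 1e-10 * scale:
        resid1 = np.zeros_like(resid1)
    z = rank_inverse_normal(resid1)
    out[complete] = _residualise(z, Xv[complete])
    if is_series:
        return pd.Series(out, index=index, name=name)
    return out


def transform_table(
    pheno: PhenotypeTable | pd.DataFrame,
    covariates: CovariateTable | pd.DataFrame | None = None,
    reverse: list[str] = (),
) -> PhenotypeTable:
    """Apply reverse coding and the double residual rank transform per trait.

    Covariates are aligned to the phenotype rows by individual ID; traits
    listed in ``reverse`` are negated before transformation.
    """
    df = pheno.values.copy() if isinstance(pheno, PhenotypeTable) else pheno.copy()
    log = list(pheno.transform_log) if isinstance(pheno, PhenotypeTable) else []
    cov_df = None
    if covariates is not None:
        cov_df = (covariates.values if isinstance(covariates, CovariateTable)
                  else covariates)
        cov_df = cov_df.reindex(df.index)
    for trait in reverse:
        if trait not in df.columns:
            raise PhenotypeError(f"unknown trait to reverse-code: {trait}")
        df[trait] = reverse_code(df[trait])
        log.append(f"reverse_code:{trait}")
    for trait in df.columns:
        df[trait] = double_residual_rank_transform(df[trait], cov_df)
        log.append(f"double_residual_rank_transform:{trait}")
    return PhenotypeTable(df, transform_log=log)


def read_phenotype_table(path, id_column: str | None = None,
                         sep: str | None = None) -> pd.DataFrame:
    """Read a delimited phenotype/covariate table indexed by individual ID."""
    df = pd.read_csv(path, sep=sep, engine="python")
    if id_column is None:
        id_column = df.columns[0]
    return df.set_index(id_column)
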