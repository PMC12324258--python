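"""Genetic relationship matrices: construction, pruning, storage, spectra.

The GRM entry for individuals j and l is the average over markers of the
standardised cross-product

    (x_ij − 2p_i)(x_il − 2p_i) / (2 p_i (1 − p_i)),

with p_i the in-sample alternate-allele frequency of marker i and the
average taken only over markers non-missing for both individuals
(pairwise-complete, mirroring PLINK ``--make-grm``).  Diagonal entries are
1 + inbreeding in expectation for outbred samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class GRMError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Additive dosages in {0, 1, 2} (NaN = missing), individuals × markers."""

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    chromosomes: list | None = None
    positions: np.ndarray | None = None
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GRMError("genotype values must be 2-D")
        n, m = self.values.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise GRMError("ID lists do not match the genotype dimensions")
        if len(set(self.individual_ids)) != n:
            raise GRMError("duplicate individual IDs")
        if len(set(self.marker_ids)) != m:
            raise GRMError("duplicate marker IDs")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise GRMError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-marker alternate-allele frequency from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0) / 2.0


@dataclass
class GRMatrix:
    """Symmetric n×n relatedness with IDs and an optional eigendecomposition."""

    values: np.ndarray
    individual_ids: list[str]
    n_markers_per_pair: np.ndarray | None = None
    eigenvalues: np.ndarray | None = field(default=None, repr=False)
    eigenvectors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise GRMError("GRM must be square")
        if len(self.individual_ids) != n:
            raise GRMError("ID list does not match the GRM dimension")
        if np.isfinite(self.values).all() and \
                np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise GRMError("GRM is not symmetric")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def subset(self, ids) -> "GRMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        sub = self.values[np.ix_(idx, idx)]
        npairs = (None if self.n_markers_per_pair is None
                  else self.n_markers_per_pair[np.ix_(idx, idx)])
        return GRMatrix(sub, [self.individual_ids[i] for i in idx], npairs)


def compute_grm(genotypes: GenotypeMatrix) -> GRMatrix:
    """Standardised-dosage GRM with pairwise-complete marker exclusion.

    Monomorphic markers (in-sample frequency 0 or 1) are dropped; an input
    with no polymorphic marker, or a pair of individuals sharing no
    non-missing marker, is an error.
    """
    X = genotypes.values
    freqs = genotypes.allele_freqs
    poly = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    if not poly.any():
        raise GRMError("no usable markers: all markers are monomorphic")
    X = X[:, poly]
    p = freqs[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - 2.0 * p) / denom
    observed = np.isfinite(Z)
    if observed.all():
        counts = np.full((X.shape[0], X.shape[0]), X.shape[1], dtype=float)
        values = (Z @ Z.T) / X.shape[1]
    else:
        Zf = np.where(observed, Z, 0.0)
        counts = observed.astype(float) @ observed.T.astype(float)
        if (counts == 0).any():
            bad = np.argwhere(counts == 0)
            pairs = [(genotypes.individual_ids[i],
                      genotypes.individual_ids[j]) for i, j in bad[:5]]
            raise GRMError(
                f"pair(s) with zero shared non-missing markers: {pairs}"
            )
        values = (Zf @ Zf.T) / counts
    values = 0.5 * (values + values.T)
    return GRMatrix(values, list(genotypes.individual_ids),
                    n_markers_per_pair=counts.astype(int))


def prune_related(grm: GRMatrix, cutoff: float = 0.05) -> list[str]:
    """Greedy removal of related individuals.

    Repeatedly drops the individual participating in the most
    above-cutoff pairs (ties broken by input order) until no retained
    off-diagonal exceeds the cutoff.  Deterministic; near-minimal loss.
    """
    if cutoff <= 0:
        raise GRMError("cutoff must be positive")
    n = grm.n_individuals
    adj = (grm.values > cutoff)
    np.fill_diagonal(adj, False)
    keep = np.ones(n, dtype=bool)
    while True:
        degrees = (adj & keep[None, :] & keep[:, None]).sum(axis=1)
        degrees[~keep] = 0
        if degrees.max(initial=0) == 0:
            break
        keep[int(np.argmax(degrees))] = False   # argmax: first index on ties
    if keep.sum() < 2:
        raise GRMError(
            f"fewer than 2 individuals remain at relatedness cutoff {cutoff}"
        )
    return [grm.individual_ids[i] for i in np.where(keep)[0]]


def eigendecompose(grm: GRMatrix) -> GRMatrix:
    """Attach the eigendecomposition (eigenvalues descending).

    Warns if the GRM has eigenvalues below −1e-8 (not PSD); raises on
    non-finite entries.
    """
    if not np.isfinite(grm.values).all():
        raise GRMError("GRM contains non-finite entries")
    d, U = linalg.eigh(grm.values)
    order = np.argsort(d)[::-1]
    d, U = d[order], U[:, order]
    if d.min() < -1e-8:
        warnings.warn(
            f"GRM is not positive semi-definite (min eigenvalue {d.min():.3g})",
            RuntimeWarning, stacklevel=2,
        )
    grm.eigenvalues = d
    grm.eigenvectors = U
    return grm


# ---------------------------------------------------------------------------
# GCTA binary GRM interchange (float32 lower triangle)
# ---------------------------------------------------------------------------

def write_grm_gcta(grm: GRMatrix, prefix: str) -> None:
    """Write .grm.bin / .grm.N.bin / .grm.id (GCTA binary dialect)."""
    n = grm.n_individuals
    tril = np.tril_indices(n)
    grm.values[tril].astype("<f4").tofile(f"{prefix}.grm.bin")
    npairs = (grm.n_markers_per_pair if grm.n_markers_per_pair is not None
              else np.ones((n, n)))
    np.asarray(npairs, dtype=float)[tril].astype("<f4").tofile(
        f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_gcta(prefix: str) -> GRMatrix:
    """Read a GCTA binary GRM; raises on byte-count mismatch."""
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1] if len(parts) > 1 else parts[0])
    n = len(ids)
    n_rec = n * (n + 1) // 2
    raw = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if raw.size != n_rec:
        raise GRMError(
            f"corrupt GRM file: {prefix}.grm.bin holds {raw.size} records, "
            f"expected n(n+1)/2 = {n_rec} for n = {n}"
        )
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = raw
    values = values + np.tril(values, -1).T
    try:
        rawN = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
        npairs = None
        if rawN.size == n_rec:
            npairs = np.zeros((n, n))
            npairs[np.tril_indices(n)] = rawN
            npairs = npairs + np.tril(npairs, -1).T
    except FileNotFoundError:
        npairs = None
    return GRMatrix(values, ids, n_markers_per_pair=npairs)


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam (SNP-major, 2-bit codes)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of the A1 allele; 01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK .bed/.bim/.fam into additive A1-dosages."""
    fam, bim = [], []
    with open(f"{prefix}.fam") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                fam.append(parts[1])
    chroms, positions, alleles = [], [], []
    with open(f"{prefix}.bim") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                bim.append(parts[1])
                chroms.append(parts[0])
                positions.append(int(parts[3]))
                alleles.append((parts[4], parts[5]))
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise GRMError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_marker = (n + 3) // 4
    if data.size != bytes_per_marker * m:
        raise GRMError(
            f"corrupt bed file: {data.size} data bytes, expected "
            f"{bytes_per_marker * m}"
        )
    data = data.reshape(m, bytes_per_marker)
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    values = _CODE_TO_DOSAGE[codes].T       # individuals × markers
    return GenotypeMatrix(values, fam, bim, chromosomes=chroms,
                          positions=np.asarray(positions), alleles=alleles)


def write_plink(genotypes: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK .bed/.bim/.fam (dosage = A1-allele count)."""
    n, m = genotypes.n_individuals, genotypes.n_markers
    with open(f"{prefix}.fam", "w") as fh:
        for iid in genotypes.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for i, mid in enumerate(genotypes.marker_ids):
            chrom = (genotypes.chromosomes[i]
                     if genotypes.chromosomes is not None else "1")
            pos = (int(genotypes.positions[i])
                   if genotypes.positions is not None else i + 1)
            a1, a2 = (genotypes.alleles[i]
                      if genotypes.alleles is not None else ("A", "G"))
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\t{a1}\t{a2}\n")
    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        X = genotypes.values
        codes = np.full((m, n), 1, dtype=np.uint8)      # missing
        for dose, code in dosage_to_code.items():
            codes[(X.T == dose)] = code
        pad = (-n) % 4
        if pad:
            codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
        packed = (codes.reshape(m, -1, 4)
                  << (np.arange(4) * 2)[None, None, :]).sum(axis=2)
        fh.write(packed.astype(np.uint8).tobytes())
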