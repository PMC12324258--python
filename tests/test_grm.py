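"""Genetic relationship matrices: estimator, pruning, file formats, spectra."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import latentgrm as lg
from latentgrm.grm import GenotypeMatrix, GRMatrix, GRMError


def _gm(values, ids=None, markers=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GenotypeMatrix(
        values,
        ids or [f"i{j}" for j in range(n)],
        markers or [f"s{j}" for j in range(m)],
    )


class TestComputeGrm:
    def test_two_individuals_opposite_homozygotes(self):
        # dosages (0,2) and (2,0), both frequencies 0.5: standardised
        # cross-products are ±2 exactly
        g = lg.compute_grm(_gm([[0, 2], [2, 0]]))
        np.testing.assert_allclose(g.values, [[2, -2], [-2, 2]], atol=1e-12)

    def test_constant_heterozygote_marker_gives_zero(self):
        g = lg.compute_grm(_gm([[1, 0], [1, 2], [1, 1]]))
        # first marker contributes zero-centred dosages for everyone
        g1 = lg.compute_grm(_gm([[0], [2], [1]]))
        np.testing.assert_allclose(2 * g.values, g1.values, atol=1e-12)

    def test_duplicate_genotype_row(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(4, 50)).astype(float)
        X[3] = X[0]
        g = lg.compute_grm(_gm(X))
        assert g.values[0, 3] == pytest.approx(g.values[0, 0], rel=1e-12)
        assert g.values[0, 3] == pytest.approx(g.values[3, 3], rel=1e-12)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(GRMError, match="monomorphic"):
            lg.compute_grm(_gm([[0, 2], [0, 2], [0, 2]]))

    def test_no_shared_markers_rejected(self):
        X = np.array([[0.0, np.nan], [np.nan, 2.0], [1.0, 1.0]])
        with pytest.raises(GRMError, match="zero shared"):
            lg.compute_grm(_gm(X))

    def test_pairwise_complete_marker_counts(self):
        X = np.array([[0.0, np.nan, 1.0], [2.0, 1.0, np.nan], [1.0, 1.0, 0.0]])
        g = lg.compute_grm(_gm(X))
        assert g.n_markers_per_pair[0, 1] == 1
        assert g.n_markers_per_pair[0, 0] == 2

    def test_invariant_to_marker_order(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(6, 40)).astype(float)
        perm = rng.permutation(40)
        g1 = lg.compute_grm(_gm(X))
        g2 = lg.compute_grm(_gm(X[:, perm],
                                markers=[f"s{j}" for j in perm]))
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_allele_relabeling(self, seed):
        # counting the other allele (x -> 2-x) leaves the GRM unchanged
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(5, 30)).astype(float)
        freqs = X.mean(axis=0) / 2
        X = X[:, (freqs > 0) & (freqs < 1)]
        if X.shape[1] == 0:
            return
        g1 = lg.compute_grm(_gm(X))
        g2 = lg.compute_grm(_gm(2.0 - X))
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-10)

    def test_dosage_validation(self):
        with pytest.raises(GRMError, match="dosages"):
            _gm([[0, 3], [1, 1]])


class TestPruneRelated:
    def _grm(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        return GRMatrix(values, ids or [f"i{j}" for j in range(len(values))])

    def test_unrelated_sample_untouched(self):
        G = np.eye(4) + 0.01
        np.fill_diagonal(G, 1.0)
        assert lg.prune_related(self._grm(G), 0.05) == ["i0", "i1", "i2", "i3"]

    def test_single_related_pair_drops_first_member(self):
        G = np.eye(3)
        G[0, 1] = G[1, 0] = 0.30
        assert lg.prune_related(self._grm(G), 0.05) == ["i1", "i2"]

    def test_star_pattern_drops_only_hub(self):
        G = np.eye(5)
        for j in (1, 2, 3):
            G[0, j] = G[j, 0] = 0.2
        assert lg.prune_related(self._grm(G), 0.05) == ["i1", "i2", "i3", "i4"]

    def test_near_minimal_vs_exhaustive_cover(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            G = np.eye(n)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.25:
                    G[i, j] = G[j, i] = 0.2
            grm = self._grm(G)
            try:
                kept = lg.prune_related(grm, 0.05)
            except GRMError:
                continue
            idx = [grm.individual_ids.index(i) for i in kept]
            # postcondition: retained subgraph has no above-cutoff pair
            assert all(G[i, j] <= 0.05
                       for i, j in itertools.combinations(idx, 2))
            # near-minimal: within one of the exhaustive minimum cover
            edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
                     if G[i, j] > 0.05]
            best = n
            for r in range(n + 1):
                if any(all(i in drop or j in drop for i, j in edges)
                       for drop in itertools.combinations(range(n), r)):
                    best = r
                    break
            assert n - len(kept) <= best + 1

    def test_too_aggressive_cutoff_reported(self):
        G = np.full((3, 3), 0.5)
        np.fill_diagonal(G, 1.0)
        with pytest.raises(GRMError, match="fewer than 2"):
            lg.prune_related(self._grm(G), 0.05)


class TestGctaRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 10))
        G = GRMatrix(A @ A.T / 10, ["a", "b", "c"])
        lg.write_grm_gcta(G, str(tmp_path / "g"))
        back = lg.read_grm_gcta(str(tmp_path / "g"))
        assert back.individual_ids == ["a", "b", "c"]
        assert np.max(np.abs(back.values - G.values)) <= 1e-6

    def test_single_individual(self, tmp_path):
        G = GRMatrix(np.array([[1.02]]), ["solo"])
        lg.write_grm_gcta(G, str(tmp_path / "g"))
        back = lg.read_grm_gcta(str(tmp_path / "g"))
        assert back.values[0, 0] == pytest.approx(1.02, abs=1e-6)

    def test_truncated_file_detected(self, tmp_path):
        G = GRMatrix(np.eye(3), ["a", "b", "c"])
        lg.write_grm_gcta(G, str(tmp_path / "g"))
        path = tmp_path / "g.grm.bin"
        path.write_bytes(path.read_bytes()[:-4])
        with pytest.raises(GRMError, match="corrupt"):
            lg.read_grm_gcta(str(tmp_path / "g"))


class TestPlinkRoundTrip:
    def test_bed_round_trip_with_missing(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, size=(7, 11)).astype(float)
        X[2, 3] = np.nan
        gt = _gm(X)
        lg.write_plink(gt, str(tmp_path / "p"))
        back = lg.read_plink(str(tmp_path / "p"))
        assert back.individual_ids == gt.individual_ids
        assert back.marker_ids == gt.marker_ids
        np.testing.assert_array_equal(np.isnan(back.values),
                                      np.isnan(X))
        np.testing.assert_allclose(np.nan_to_num(back.values),
                                   np.nan_to_num(X))

    def test_bad_magic_rejected(self, tmp_path):
        lg.write_plink(_gm([[0, 1], [2, 1]]), str(tmp_path / "p"))
        (tmp_path / "p.bed").write_bytes(b"\x00\x00\x00junk")
        with pytest.raises(GRMError, match="bed"):
            lg.read_plink(str(tmp_path / "p"))


class TestEigendecompose:
    def test_identity_grm(self):
        g = lg.eigendecompose(GRMatrix(np.eye(4), list("abcd")))
        np.testing.assert_allclose(g.eigenvalues, np.ones(4), atol=1e-12)

    def test_rank_one_all_ones(self):
        n, scale = 5, 0.3
        g = lg.eigendecompose(GRMatrix(np.full((n, n), scale),
                                       [str(i) for i in range(n)]))
        assert g.eigenvalues[0] == pytest.approx(n * scale, abs=1e-10)
        np.testing.assert_allclose(g.eigenvalues[1:], 0, atol=1e-10)

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(5, 20))
        G = GRMatrix(A @ A.T / 20, [str(i) for i in range(5)])
        g = lg.eigendecompose(G)
        recon = (g.eigenvectors * g.eigenvalues) @ g.eigenvectors.T
        assert np.max(np.abs(recon - G.values)) <= 1e-10

    def test_indefinite_grm_warns(self):
        vals = np.array([[1.0, 0.99, -0.99],
                         [0.99, 1.0, 0.99],
                         [-0.99, 0.99, 1.0]])
        with pytest.warns(RuntimeWarning, match="positive semi-definite"):
            lg.eigendecompose(GRMatrix(vals, list("abc")))

    def test_nonfinite_rejected(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(GRMError, match="non-finite"):
            lg.eigendecompose(GRMatrix(vals, list("ab")))
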