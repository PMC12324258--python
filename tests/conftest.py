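import numpy as np
import pytest

import latentgrm as lg


@pytest.fixture(scope="session")
def small_grm():
    """Eigendecomposed GRM from 60 simulated individuals, 400 markers."""
    gt = lg.simulate_genotypes(60, 400, seed=11)
    return lg.eigendecompose(lg.compute_grm(gt))


@pytest.fixture(scope="session")
def medium_dataset():
    """Complete-data draw from a k=2 Cholesky truth, n=600 (shared)."""
    structure = lg.make_structure("cholesky", 2, trait_names=["t1", "t2"])
    theta = np.array([0.6, 0.2, 0.5, 0.7, 0.1, 0.6])
    gt = lg.simulate_genotypes(600, 1500, seed=21)
    grm = lg.eigendecompose(lg.compute_grm(gt))
    scen = lg.SimulationScenario(600, 1500, (0.05, 0.5), structure, theta,
                                 seed=22)
    Y = lg.simulate_phenotypes(scen, grm, seed=22)
    return scen, grm, Y


def random_psd_grm(n, rng, m=None):
    """Standardised-Gram PSD matrix resembling a GRM."""
    m = m or 4 * n
    Z = rng.standard_normal((n, m))
    Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    return Z @ Z.T / m


def random_structure_and_theta(rng, k=None, rge=False):
    """A random small IP structure with admissible parameters."""
    k = k or int(rng.integers(2, 5))
    nA = int(rng.integers(1, min(k, 2) + 1))
    nE = int(rng.integers(1, min(k, 2) + 1))
    s = lg.make_structure("ip", k, nA=nA, nE=nE, rge=rge,
                          rge_pairs="matched")
    theta = rng.normal(0.45, 0.1, s.n_params)
    theta[s.is_nonneg_param()] = np.abs(theta[s.is_nonneg_param()])
    corr = s.is_corr_param()
    theta[corr] = rng.uniform(-0.6, 0.6, corr.sum())
    return s, theta
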