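import numpy as np
import pytest

from rguc_kit.aflp_io import BandMatrix
from rguc_kit.synthetic_data import SimConfig, simulate_band_matrix, simulate_climate


@pytest.fixture
def toy_bm() -> BandMatrix:
    """Two populations of two individuals, two loci (hand-checkable)."""
    values = np.array([[1, 1], [1, 0], [0, 0], [0, 1]])
    return BandMatrix(values, ["a1", "a2", "b1", "b2"], ["L1", "L2"], ["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic dataset shared by read-only tests."""
    cfg = SimConfig(seed=7, n_loci=120, n_per_pop=20, pops_per_cluster=(4, 4, 3),
                    n_adaptive_loci=0)
    bm, pf, truth = simulate_band_matrix(cfg)
    return cfg, bm, pf, truth


@pytest.fixture(scope="session")
def small_sim_with_climate():
    cfg = SimConfig(seed=13, n_loci=40, n_per_pop=10, pops_per_cluster=(3, 3, 2),
                    rare_fraction=0.2, n_adaptive_loci=6, beta=3.0)
    bm, pf, truth = simulate_band_matrix(cfg)
    stack, cov = simulate_climate(cfg, pf)
    return cfg, bm, pf, truth, stack, cov
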