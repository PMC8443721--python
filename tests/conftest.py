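import numpy as np
import pytest

from clonalscape.genotype_io import GenotypeMatrix
from clonalscape.synthdata import SimConfig, simulate_population


def make_matrix(calls, chrom="chr1", pos=None, sample_ids=None):
    """Build a GenotypeMatrix from a plain nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    return GenotypeMatrix(np.array([chrom] * n_sites, dtype=object),
                          np.asarray(pos, dtype=np.int64),
                          np.array(["A"] * n_sites, dtype=object),
                          np.array(["G"] * n_sites, dtype=object),
                          calls, sample_ids)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-condition simulation shared across tests."""
    cfg = SimConfig(seed=1)
    g, meta, truth = simulate_population(cfg)
    return cfg, g, meta, truth


@pytest.fixture(scope="session")
def random_matrix():
    """A 400-site x 20-sample random matrix with missing calls."""
    rng = np.random.default_rng(42)
    calls = rng.choice([0, 1, 2, -1], size=(400, 20),
                       p=[0.4, 0.3, 0.25, 0.05]).astype(np.int8)
    return make_matrix(calls, pos=np.sort(
        rng.choice(np.arange(1, 500_000), size=400, replace=False)))
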