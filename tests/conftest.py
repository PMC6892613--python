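import numpy as np
import pandas as pd
import pytest

from rrqtl import simdata, genotypes
from rrqtl.pipeline import PipelineConfig, simulate_experiment


def std(y):
    y = np.asarray(y, float)
    return (y - y.mean()) / y.std()


@pytest.fixture(scope="session")
def small_panel():
    return simdata.simulate_panel(64, 600, n_chroms=4, seed=7)


@pytest.fixture(scope="session")
def small_experiment():
    """Four crosses x 120 segregants x 600 markers with 6 planted QTL."""
    return simulate_experiment(
        n_strains=64, n_markers=600, n_chroms=4, n_parents=4, n_progeny=120,
        n_qtl=6, h2_additive=0.4, repeatability=0.8, n_replicates=2,
        seed_panel=7, seed_meiosis=8, seed_effects=9, seed_phenotypes=10,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def single_cross_matrix(n=200, m=120, n_chroms=4, seed=0, maf=0.5):
    """A one-cross GenotypeMatrix with independent-ish markers for unit tests."""
    exp = simulate_experiment(
        n_strains=32, n_markers=m, n_chroms=n_chroms, n_parents=3,
        n_progeny=n, n_qtl=1, seed_panel=seed, seed_meiosis=seed + 1,
        seed_effects=seed + 2, seed_phenotypes=seed + 3,
    )
    cid = exp.design.cross_ids[0]
    return exp.G.subset_cross(cid)
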