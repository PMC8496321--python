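import numpy as np
import pandas as pd
import pytest

from mtgp import (
    GenotypeMatrix,
    MCMCSettings,
    ModelSpec,
    PhenotypeTable,
    SimulationConfig,
    compute_grm,
    simulate_dataset,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_geno():
    """5 lines x 4 markers exercising each QC rule.

    Columns: m1 polymorphic/clean, m2 heterozygote-heavy, m3 monomorphic,
    m4 60% missing.
    """
    X = np.array(
        [
            [0, 1, 0, np.nan],
            [2, 1, 0, np.nan],
            [0, 1, 0, 2],
            [2, 0, 0, np.nan],
            [0, 2, 0, 0],
        ]
    )
    return GenotypeMatrix(X, [f"l{i}" for i in range(5)], ["m1", "m2", "m3", "m4"])


@pytest.fixture(scope="session")
def small_dataset():
    """Two-cycle, two-trait dataset used by several model/CV tests."""
    cfg = SimulationConfig(
        n_train_lines=120,
        n_test_lines=40,
        n_markers=400,
        n_traits=2,
        sigma_T=np.array([[0.5, 0.2], [0.2, 0.5]]),
        sigma_TE=np.zeros((2, 2)),
        residual_cov=0.5 * np.eye(2),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def fast_mcmc():
    return MCMCSettings(n_iter=600, burn_in=200, thin=2, seed=7)


def single_env_phenotypes(y, lines, trait="T1", env="cycle1"):
    return PhenotypeTable(
        pd.DataFrame({"line": lines, "env": env, "trait": trait, "value": y})
    )
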