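import numpy as np
import pandas as pd
import pytest

from hostcomp import simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared by fast tests."""
    cfg = simulate.SimConfig(
        n_genes=400,
        n_secretory_genes=80,
        n_mito_genes=10,
        n_rproteins=4,
        replicates_per_condition=2,
        n_planted_outliers=5,
        outlier_lfc=9.0,
        seed=11,
    )
    return simulate.simulate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def null_counts(rng):
    """2000-gene NB count matrix with no condition effect (alpha=0.2, 3+3)."""
    g, m = 2000, 6
    mu = np.exp(rng.uniform(np.log(20), np.log(2000), g))
    lam = rng.gamma(1 / 0.2, mu[:, None] * 0.2, (g, m))
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=[f"g{i:04d}" for i in range(g)],
        columns=[f"s{j}" for j in range(m)],
    )
    groups = np.array(["A"] * 3 + ["B"] * 3)
    return counts, groups
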