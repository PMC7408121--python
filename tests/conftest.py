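import numpy as np
import pandas as pd
import pytest

import omicspair as op


@pytest.fixture(scope="session")
def small_cfg():
    return op.SimConfig(n_genes=120, n_metabolites=40, n_samples=40,
                        group_sizes=(12, 28), n_planted=10, delta_slope=1.5,
                        noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return op.simulate_dataset(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_matrix():
    return op.OmicsMatrix(
        ["f1", "f2", "f3"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        "raw_abundance",
    )


@pytest.fixture()
def random_pair_instance(rng):
    """50 genes x 20 metabolites x 40 samples of unstructured noise."""
    n = 40
    genes = op.OmicsMatrix([f"g{i}" for i in range(50)], [f"s{j}" for j in range(n)],
                           rng.normal(size=(50, n)), "adjusted")
    mets = op.OmicsMatrix([f"m{i}" for i in range(20)], [f"s{j}" for j in range(n)],
                          rng.normal(size=(20, n)), "adjusted")
    p = np.zeros(n)
    p[rng.choice(n, 18, replace=False)] = 1.0
    return genes, mets, p


def naive_ols(X: np.ndarray, y: np.ndarray):
    """Independent normal-equations OLS oracle (tests only)."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    return beta, se, dof


@pytest.fixture()
def meta_table():
    n = 24
    rng = np.random.default_rng(3)
    return op.SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "breed": ["a"] * 12 + ["b"] * 12,
        "fe_group": rng.permutation(["high", "low"] * 12),
        "pen": rng.permutation([f"pen{i % 8 + 1}" for i in range(n)]),
        "batch": rng.permutation(["batch1", "batch2"] * 12),
        "rin": rng.normal(8, 0.5, n),
        "slaughter_age_days": rng.normal(150, 5, n),
        "sampling_age_days": rng.normal(140, 5, n),
    }))
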