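"""Shared fixtures: small deterministic tables and one reusable fit."""

import numpy as np
import pandas as pd
import pytest

import cbbcomp as cb

# light MCMC settings for unit tests that need a posterior but not
# publication-grade precision
FAST_CFG = dict(chains=2, warmup_iters=200, sampling_iters=300)


@pytest.fixture(scope="session")
def small_table():
    """3 samples x 2 groups, all pairs present."""
    counts = np.array([[10, 20, 30], [90, 80, 70]])
    return cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                         group_ids=["A", "B"],
                         sample_ids=["s1", "s2", "s3"])


@pytest.fixture(scope="session")
def two_condition_table():
    """Deterministic 6-group x 8-sample table with a condition covariate."""
    rng = np.random.default_rng(7)
    counts = rng.integers(20, 400, size=(6, 8))
    table = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                          group_ids=[f"G{i}" for i in range(6)],
                          sample_ids=[f"S{i}" for i in range(8)])
    table.covariates = pd.DataFrame(
        {"condition": ["A"] * 4 + ["B"] * 4,
         "age": np.linspace(30, 65, 8)},
        index=pd.Index(table.sample_ids, name="sample"))
    return table


@pytest.fixture(scope="session")
def sim_dataset():
    """Simulated intercept-only dataset with known truth."""
    return cb.simulate_scbb_dataset(n_groups=8, n_samples=10,
                                    cells_per_sample=2000, seed=42)


@pytest.fixture(scope="session")
def fitted(sim_dataset):
    """One reusable fit of the simulated dataset (light settings)."""
    table, truth = sim_dataset
    model = cb.CompositionModel(table)
    return model.fit(cb.McmcConfig(seed=1, **FAST_CFG))
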