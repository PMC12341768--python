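import numpy as np
import pandas as pd
import pytest

import methaging as ma


@pytest.fixture(scope="session")
def small_cohort():
    """A small blood-like cohort reused by read-only tests."""
    config = ma.SimulationConfig(n_samples=30, n_sites=400, frac_age_associated=0.1, seed=101)
    return ma.simulate_training_cohort(config)


@pytest.fixture(scope="session")
def gene_records():
    return ma.make_gene_records(20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_site_table(rng):
    """A random per-sample site table in the parser-facing layout."""
    n = 50
    positions = np.sort(rng.choice(100_000, n, replace=False)) + 1
    coverage = rng.integers(1, 60, n)
    meth_reads = rng.binomial(coverage, rng.uniform(0, 1, n))
    return pd.DataFrame(
        {
            "chrom": np.where(positions % 2 == 0, "chr1", "chr2"),
            "pos": positions,
            "meth_frac": meth_reads / coverage,
            "coverage": coverage,
        }
    )
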