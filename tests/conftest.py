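import numpy as np
import pandas as pd
import pytest

from metbiom.io import TraitTable
from metbiom.simulate import SimulationConfig, TraitSpec, simulate_met


def make_table(g=4, y=2, r=2, traits=("A", "B"), seed=0, scale=1.0, mean=10.0):
    """Small random balanced table for oracle tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(g):
        for yj in range(y):
            for rk in range(1, r + 1):
                for t in traits:
                    rows.append(
                        (f"g{gi}", f"e{yj}", rk, t, mean + scale * rng.standard_normal())
                    )
    return TraitTable(
        pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    )


@pytest.fixture
def small_table():
    return make_table(g=6, y=3, r=2, traits=("A", "B", "C"), seed=42)


@pytest.fixture
def single_env_table():
    return make_table(g=6, y=1, r=3, traits=("A",), seed=7)


@pytest.fixture(scope="session")
def recovery_table():
    """One large single-trait MET with known components for recovery checks."""
    cfg = SimulationConfig(
        n_genotypes=500,
        n_environments=3,
        n_replicates=2,
        traits=[TraitSpec("X", grand_mean=50.0, sigma2_g=100.0, sigma2_e=25.0)],
        seed=123,
    )
    table, ledger = simulate_met(cfg)
    return table, ledger
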