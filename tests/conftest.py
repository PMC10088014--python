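import numpy as np
import pandas as pd
import pytest

from lfqdea.data import AnalysisConfig, QuantTable
from lfqdea.simulate import SimParams, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """Small default-design spike-in run (shared, read-only)."""
    return simulate_experiment(SimParams(n_background=120, n_spike=30, seed=7))


@pytest.fixture(scope="session")
def small_sim_nodrop():
    return simulate_experiment(SimParams(n_background=80, n_spike=20,
                                         dropout=False, seed=11))


@pytest.fixture
def two_group_config():
    return AnalysisConfig(sample_col="sample", group_cols=("group",),
                          protein_col="protein", response_col="abundance",
                          log_transformed=True)


def make_two_group_table(n_proteins=10, n_per_group=4, delta=0.0, sigma=0.5,
                         seed=0, config=None):
    """Protein-level log2 table with two groups shifted by delta."""
    rng = np.random.default_rng(seed)
    cfg = config or AnalysisConfig(sample_col="sample", group_cols=("group",),
                                   protein_col="protein",
                                   response_col="abundance",
                                   log_transformed=True)
    rows = []
    for i in range(n_proteins):
        for g, shift in (("ctrl", 0.0), ("trt", delta)):
            for r in range(n_per_group):
                rows.append((f"P{i:03d}", f"{g}{r+1}", g,
                             20.0 + shift + sigma * rng.standard_normal()))
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    return QuantTable(df, cfg)


@pytest.fixture
def two_group_table():
    return make_two_group_table(n_proteins=10, seed=3)
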