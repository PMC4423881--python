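import numpy as np
import pandas as pd
import pytest

import noisecorr as nc


@pytest.fixture
def small_meta() -> nc.ReplicateMeta:
    return nc.ReplicateMeta(pd.DataFrame({
        "replicate_id": ["m1", "m2", "p1", "p2"],
        "experiment_id": ["mrnaA", "mrnaB", "protA", "protB"],
        "technology_id": ["rnaseq", "array", "ms", "ms"],
        "molecule_type": ["mRNA", "mRNA", "protein", "protein"],
    }))


@pytest.fixture
def small_matrix(small_meta) -> nc.ExpressionMatrix:
    rng = np.random.default_rng(0)
    values = rng.normal(0.0, 1.0, (10, 4))
    return nc.ExpressionMatrix(
        [f"g{i}" for i in range(10)], small_meta.replicate_ids,
        values, np.ones_like(values, dtype=bool), log_scale=True,
    )


@pytest.fixture(scope="session")
def toy_table() -> pd.DataFrame:
    return nc.simulate_toy_model(nc.ToyModelParams())


@pytest.fixture(scope="session")
def fig3_sim() -> nc.NoisyReplicates:
    """One reliability-0.7, correlation-0.9 simulated transcriptome/proteome."""
    return nc.simulate_noisy_replicates(
        nc.SimulationConfig(n_genes=5000, rho_true=0.9, reliability=0.7, seed=7)
    )
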