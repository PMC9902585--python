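import numpy as np
import pandas as pd
import pytest

from miscreen import (
    ReceptorEffect,
    SimulationConfig,
    cpm_normalize,
    score_activity,
    simulate_bulk,
)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small dataset with planted programs and receptors, shared read-only."""
    effects = (
        ReceptorEffect("both", -1, 0.5),
        ReceptorEffect("both", +1, 0.5),
        ReceptorEffect("emt", -1, 0.5),
        ReceptorEffect("cycle", +1, 0.5),
    )
    cfg = SimulationConfig(
        n_genes=320, n_samples=300, n_program_genes_emt=25,
        n_program_genes_cycle=25, receptor_effects=effects, seed=123,
    )
    return simulate_bulk(cfg)


@pytest.fixture(scope="session")
def planted_cpm(planted_dataset):
    return cpm_normalize(planted_dataset.matrix)


@pytest.fixture(scope="session")
def planted_scores(planted_dataset, planted_cpm):
    truth = planted_dataset.truth
    emt = score_activity(
        planted_cpm, list(truth.index[truth.label == "program_emt"]), "EMT"
    )
    cyc = score_activity(
        planted_cpm, list(truth.index[truth.label == "program_cycle"]), "mitotic"
    )
    return emt, cyc


@pytest.fixture()
def null_matrix():
    """Counts with no structure at all: same NB law for every gene."""
    rng = np.random.default_rng(7)
    counts = rng.negative_binomial(5, 0.05, size=(120, 80))
    return pd.DataFrame(
        counts,
        index=[f"N{i:04d}" for i in range(120)],
        columns=[f"S{j:03d}" for j in range(80)],
    )
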