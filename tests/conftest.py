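import numpy as np
import pandas as pd
import pytest

from orthoexpress import CountMatrix, SimulationConfig, simulate_counts


def make_count_matrix(counts, taxa=None):
    """Small CountMatrix from a 2-D array; samples named s0, s1, ..."""
    counts = np.asarray(counts)
    n_loci, n_samples = counts.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if taxa is None:
        taxa = ["A"] * n_samples
    samples = pd.DataFrame(
        {"taxon": taxa, "replicate": list(range(1, n_samples + 1))},
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountMatrix(
        pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n_loci)], columns=sample_ids
        ),
        samples,
    )


@pytest.fixture
def null_sim():
    """1000 no-effect NB loci, 6 replicates x 4 taxa, dispersion 0.1."""
    cfg = SimulationConfig(n_loci=1000, seed=11, phenotype_fractions={})
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
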