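import numpy as np
import pandas as pd
import pytest

from retinova import qc, simulate


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=11,
        n_genes=900,
        n_samples_per_group=10,
        n_de_genes=60,
        de_lfc=1.0,
        module_spec=((120, 0.8, 0.6), (100, 0.8, 0.0)),
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Counts, metadata and ground truth for a small planted simulation."""
    counts, meta, truth = simulate.gen_counts(small_cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def normalized(small_dataset):
    counts, meta, _ = small_dataset
    filtered = qc.filter_low_counts(counts)
    factors = qc.size_factors_median_of_ratios(filtered)
    norm = qc.remove_batch(qc.stabilize(filtered, factors), meta)
    return norm, filtered, factors, meta
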