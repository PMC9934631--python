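import numpy as np
import pandas as pd
import pytest

from stimqtl.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(n_donors=24, n_variants=800, n_peaks=60,
                           n_genes=40, gwas_n=500, n_gwas_loci=4, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def peaks_frame(tiny_dataset):
    peaks = tiny_dataset.features.peaks
    return pd.DataFrame({
        "feature_id": [p.name for p in peaks],
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
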