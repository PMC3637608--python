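import numpy as np
import pytest

from paralogasym.pipeline import run_full_analysis
from paralogasym.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-pair synthetic dataset with full genomic realization."""
    return simulate_dataset(SimulationConfig(n_pairs=40, seed=11))


@pytest.fixture(scope="session")
def small_report(small_dataset):
    ds = small_dataset
    return run_full_analysis(ds.cds, ds.genomic, ds.annotations, ds.manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
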