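import numpy as np
import pytest

from regfine.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A desk-scale configuration for fast simulation tests."""
    return SimulationConfig(seed=11, n_cases=300, n_controls=300,
                            n_genes=200, n_correlated=20, de_size=20,
                            de_overlap=5, n_peaks=20, n_tss=20,
                            chrom_len=200_000)
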