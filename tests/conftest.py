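import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from haplobin import simdip


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_diploid():
    """A 2 x 60 kb SNV-only diploid shared by read-binning tests."""
    config = simdip.DiploidSimConfig(
        n_chromosomes=2, chrom_length=60_000, snv_rate=0.05,
        indel_rate=0.0, pav_rate=0.0, seed=11,
    )
    hap1, hap2, truth = simdip.simulate_diploid(config)
    return config, hap1, hap2, truth


@pytest.fixture(scope="session")
def mixed_diploid():
    """A diploid carrying SNVs, small indels and PAVs."""
    config = simdip.DiploidSimConfig(
        n_chromosomes=2, chrom_length=80_000, snv_rate=0.01,
        indel_rate=0.001, indel_max_len=10,
        pav_rate=3e-5, pav_len_range=(50, 300), seed=7,
    )
    hap1, hap2, truth = simdip.simulate_diploid(config)
    return config, hap1, hap2, truth
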