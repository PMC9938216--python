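import numpy as np
import pytest

from silamnet import SynthConfig


@pytest.fixture
def small_cfg() -> SynthConfig:
    """Small, fast configuration used across generator tests."""
    return SynthConfig(
        seed=11,
        n_proteins=200,
        n_replicates_per_genotype=4,
        n_genes_universe=1000,
        set_sizes=[50, 50],
        query_size=100,
        graph_n=40,
        graph_m=2,
        hub_extra_degree=10,
        n_rois=20,
        duration_s=120.0,
        cohort_sizes={"WT": 12, "DUP": 12},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
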