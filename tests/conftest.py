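import numpy as np
import pytest

import pleioscan as ps
from pleioscan import assoc


@pytest.fixture(scope="session")
def small_panel() -> ps.GenotypePanel:
    """Two-chromosome panel with moderate block LD, 500 samples."""
    specs = [
        ps.LDBlockSpec(n_blocks=20, snps_per_block=5, block_span_bp=20_000,
                       within_block_r2=0.3, chrom="1"),
        ps.LDBlockSpec(n_blocks=20, snps_per_block=5, block_span_bp=20_000,
                       within_block_r2=0.6, chrom="2"),
    ]
    return ps.simulate_genotypes(specs, 500, seed=101)


@pytest.fixture(scope="session")
def small_grm(small_panel) -> assoc.GRM:
    return assoc.compute_grm(small_panel)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
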