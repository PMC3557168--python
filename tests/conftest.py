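import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_site  # noqa: E402

from rrlsnp import ReferenceGenome, SimConfig, simulate_experiment  # noqa: E402


@pytest.fixture
def small_reference():
    return ReferenceGenome(
        [
            ("c1", "ACGTACGTACGTACGTACGT"),  # 20 bp
            ("c2", "GGGGCCCCAAAATTTT"),  # 16 bp, homopolymer-rich
        ]
    )


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def recoverable_experiment():
    """Error-free, constant-depth simulation whose truth set is fully
    recoverable by construction (fragment-restricted, non-homopolymer,
    spaced implants)."""
    cfg = SimConfig(
        genome_length=150_000,
        n_contigs=2,
        snp_density=1.5e-3,
        mean_depth=10.0,
        depth_dispersion=0.0,
        base_error_rate=0.0,
        n_genotypes=2,
        seed=11,
    )
    return simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
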