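import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from msapkit import (
    BandMatrixPair,
    SampleSheet,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def toy_pair() -> tuple[BandMatrixPair, SampleSheet]:
    """4 individuals x 4 loci covering all four band patterns.

    Locus columns are built so the first locus shows every (hpa, msp)
    combination across individuals.
    """
    individuals = ["A1", "A2", "B1", "B2"]
    loci = ["L1", "L2", "L3", "L4"]
    hpa = np.array(
        [
            [1, 1, 0, 1],
            [0, 1, 0, 1],
            [1, 0, 1, 1],
            [0, 0, 1, 1],
        ]
    )
    msp = np.array(
        [
            [1, 1, 1, 1],
            [1, 1, 1, 1],
            [0, 0, 0, 1],
            [0, 0, 0, 1],
        ]
    )
    pair = BandMatrixPair(loci=loci, individuals=individuals, hpa=hpa, msp=msp)
    sheet = SampleSheet(populations={"A1": "popA", "A2": "popA", "B1": "popB", "B2": "popB"})
    return pair, sheet


@pytest.fixture
def small_simulation():
    """A small two-population dataset with clean (error-free) scoring."""
    config = SimulationConfig(
        n_populations=2,
        sizes=(12, 12),
        n_loci=80,
        msl_fraction=0.5,
        methylation_means=(0.45, 0.65),
        divergence_f=0.15,
        scoring_error_rate=0.0,
        type_iv_extra_rate=0.2,
        seed=42,
    )
    return simulate_dataset(config)
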