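import numpy as np
import pytest

from triodx import SimConfig, analyze_cohort, simulate_cohort
from triodx.cohortsim import CnvParams


@pytest.fixture(scope="session")
def cohort500():
    """Seed-fixed 500-family cohort with noise-free genotypes, including
    planted clinvar/secondary/carrier events; shared across the suite."""
    return simulate_cohort(SimConfig(n_families=500, seed=7))


@pytest.fixture(scope="session")
def run500(cohort500):
    return analyze_cohort(cohort500)


@pytest.fixture(scope="session")
def cohort_small():
    return simulate_cohort(
        SimConfig(
            n_families=80,
            seed=13,
            cnv=CnvParams(n_events=4, jitter_sd=50.0, min_length=20_000),
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
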