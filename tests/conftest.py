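import numpy as np
import pytest

from cdascan import DOMINANT, PhenotypeVector
from cdascan.simulate import preset_spec, sample_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def strong_cohort():
    """Small associated cohort drawn from the strong-signal protocol."""
    g, pheno, params = sample_cohort(preset_spec("strong", m=5, n=400, seed=11))
    return g, pheno, params


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with phenotype-independent structure only."""
    g, pheno, params = sample_cohort(preset_spec("null", m=6, n=300, seed=12))
    return g, pheno, params
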