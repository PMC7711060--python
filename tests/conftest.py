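import numpy as np
import pytest

from methex.promoters import classify_all
from methex.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_classes(cohort):
    biotypes = {g.gene_id: g.biotype for g in cohort.genes}
    classes, summary = classify_all(cohort.promoters, biotypes)
    return classes, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
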