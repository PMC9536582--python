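import numpy as np
import pytest

from asrc.task import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic participants with 60 probes each (fast fixture)."""
    cfg = CohortConfig(n_participants=6, n_probes=60)
    datasets, truth = generate_cohort(cfg, seed=11)
    return datasets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
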