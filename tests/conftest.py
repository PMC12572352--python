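import numpy as np
import pytest

from rarpipe import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three participants, two visits, full retention; deterministic."""
    cfg = SimulationConfig(
        n_participants=3,
        visit_labels=("6w", "6m"),
        retention_per_visit=(1.0, 1.0),
        visit_days_since_treatment=(42, 183),
        seed=1,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
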