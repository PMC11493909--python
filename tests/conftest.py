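import numpy as np
import pandas as pd
import pytest

from dogchange.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort (72 dogs, 12 re-enrolled controls)."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def six_dog_scores():
    """Hand-constructed long-format scores for one component, six dogs.

    Baselines 0..10, range 10 -> percentage 0.1; baseline median 5, second
    median 6 -> experience effect 1; thresholds (0, 2).
    """
    baselines = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
    seconds = [0.5, 1.0, 6.5, 5.5, 9.05, 12.0]
    rows = []
    for i, (b, s) in enumerate(zip(baselines, seconds)):
        rows.append({"dog_id": f"d{i}", "occasion": 1, "component": "c", "value": b})
        rows.append({"dog_id": f"d{i}", "occasion": 2, "component": "c", "value": s})
    return pd.DataFrame(rows)
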