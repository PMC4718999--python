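import numpy as np
import pytest

from saccart.maps import SaccartModel
from saccart.scenarios import gen_binary_patterns, gen_target_schedule
from saccart.trial import train_saccart

TRAINED_SEED = 1


@pytest.fixture(scope="session")
def trained_model() -> SaccartModel:
    """SACCART model trained on the default 200-trial colocated schedule."""
    model = SaccartModel()
    schedule = gen_target_schedule(n_trials=200, pairing="colocated", seed=TRAINED_SEED)
    train_saccart(model, schedule)
    return model


@pytest.fixture(scope="session")
def control_model() -> SaccartModel:
    """Control model trained with independently drawn cue positions."""
    model = SaccartModel()
    schedule = gen_target_schedule(
        n_trials=200, pairing="independent", seed=TRAINED_SEED
    )
    train_saccart(model, schedule)
    return model


@pytest.fixture(scope="session")
def binary_patterns() -> list[np.ndarray]:
    """20 random binary patterns of dimension 25 with moderate overlap."""
    return gen_binary_patterns(n=20, d=25, overlap=0.4, seed=11)
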