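import numpy as np
import pytest

import hystnet as hn


@pytest.fixture(scope="session")
def short_session():
    """A 30-s-per-condition labeled session, shared across tests."""
    return hn.make_session("default", condition_minutes=0.5, n_trials=6, seed=5)


@pytest.fixture(scope="session")
def ar1_data():
    """Long scalar AR(1) sample with a = 0.5."""
    model = hn.MVARModel(np.array([[[0.5]]]), np.eye(1), 128.0)
    return model, hn.simulate_mvar(model, 10_000, seed=1)
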