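import numpy as np
import pytest

from stroopdmc import dmc_core, synthetic_data


@pytest.fixture(scope="session")
def base_params() -> dmc_core.DMCParams:
    return dmc_core.DMCParams(a=85.0, mu_c=0.5, zeta=20.0, alpha=2.0, tau=50.0, ter=300.0, sr=30.0)


@pytest.fixture(scope="session")
def session_frame(base_params):
    """One simulated sham session (practice + 600 main trials)."""
    return synthetic_data.simulate_session(base_params, "sham", seed=42, participant="s00")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
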