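import numpy as np
import pytest

import ssakit as sk


@pytest.fixture(scope="session")
def id_model():
    """Immigration-death fixture model (ksyn=10, kd=0.2, mRNA0=50)."""
    return sk.build_fixture("immigration_death").model


@pytest.fixture(scope="session")
def id_long(id_model):
    """A long exact immigration-death run shared across statistics tests."""
    return sk.simulate_direct(
        id_model, sk.SolverSettings(end=4 * 10**5, mode="steps", seed=7)
    )


@pytest.fixture(scope="session")
def two_state_bursty():
    return sk.build_fixture("two_state_gene", "bursty").model


def make_trajectory(times, states, fired, propensities=None, n_reactions=2,
                    exact=True, species=("A",)):
    """Hand-build a small trajectory for definition-level tests."""
    times = np.asarray(times, dtype=float)
    states = np.asarray(states, dtype=np.int64)
    if states.ndim == 1:
        states = states[:, None]
    if propensities is None:
        propensities = np.zeros((len(times), n_reactions))
    return sk.Trajectory(
        times=times,
        states=states,
        propensities=np.asarray(propensities, dtype=float),
        fired=np.asarray(fired, dtype=np.int64),
        species_names=list(species),
        reaction_names=[f"R{j}" for j in range(n_reactions)],
        exact=exact,
    )
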