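import numpy as np
import pytest

import polyconf as pc


@pytest.fixture(scope="session")
def standard_regions():
    return pc.builtin_region_set("standard_literature")


@pytest.fixture(scope="session")
def three_state_spec():
    """Markov generator at the default study conditions (32 residues, 0.1 ns)."""
    return pc.GeneratorSpec(
        states={"alphaR": (0.3, 1.0), "PPII": (0.45, 2.0), "beta": (0.25, 1.5)},
        n_frames=2000, n_residues=32, dt=0.1, emission_jitter=10.0, seed=7)


@pytest.fixture(scope="session")
def markov_states(three_state_spec):
    return pc.markov_state_trajectory(three_state_spec)


@pytest.fixture(scope="session")
def emitted_trajectory(markov_states, standard_regions, three_state_spec):
    return pc.emit_dihedrals(markov_states, standard_regions, three_state_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_state_matrix(rng, n_frames=500, n_monomers=30, n_states=3):
    """Uniform random label matrix used by the brute-force oracle tests."""
    codes = rng.integers(0, n_states, size=(n_frames, n_monomers))
    alphabet = tuple(f"s{k}" for k in range(n_states))
    times = 0.1 * np.arange(n_frames)
    return pc.StateTrajectory(times=times, codes=codes, alphabet=alphabet)
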