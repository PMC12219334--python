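import numpy as np
import pytest

from foldswitch.synth import (EnsembleSpec, make_backbone,
                              make_two_state_ensemble)


@pytest.fixture(scope="session")
def helix30():
    return make_backbone("helix", 30)


@pytest.fixture(scope="session")
def hairpin30():
    return make_backbone("hairpin", 30)


@pytest.fixture(scope="session")
def small_ensemble():
    """40-member two-state ensemble with labels, cheap enough for unit tests."""
    spec = EnsembleSpec(n_members=40, fraction_state_a=0.5,
                        fraction_decoy=0.1, noise_sd=0.3, length=40, seed=11)
    return make_two_state_ensemble(spec)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2 ** 31))).as_matrix()
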