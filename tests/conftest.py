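import numpy as np
import pytest

import enmrisk as er


@pytest.fixture(scope="session")
def grid20():
    return er.GridSpec(20, 20)


@pytest.fixture(scope="session")
def stack20(grid20):
    return er.make_env_stack(grid20, 3, corr_length=3, seed=11)


@pytest.fixture(scope="session")
def species():
    return er.VirtualSpecies({"var1": er.GaussianResponse(0.5, 1.0),
                              "var2": er.GaussianResponse(-0.3, 1.2)},
                             name="focal")


@pytest.fixture(scope="session")
def bench():
    """Mid-sized benchmark landscape: stack, species, truth, occurrences."""
    grid = er.GridSpec(60, 60)
    stack = er.make_env_stack(grid, 3, corr_length=6, seed=7)
    vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.5, 1.0),
                            "var2": er.GaussianResponse(-0.3, 1.2)})
    suit = er.true_suitability(vs, stack)
    occ = er.sample_occurrences(vs, stack, 200, seed=8)
    occ = er.split_train_test(occ, 0.5, seed=9)
    return {"grid": grid, "stack": stack, "species": vs, "suit": suit, "occ": occ}


def random_binary_pair(rng, shape=(15, 15), p=0.3):
    g = er.GridSpec(*shape)
    a = er.BinaryMap(g, (rng.random(shape) < p).astype(np.uint8))
    b = er.BinaryMap(g, (rng.random(shape) < p).astype(np.uint8))
    return a, b
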