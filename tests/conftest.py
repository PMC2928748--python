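import pytest

from metevo import ModelParams, initial_network, sample_world
from metevo.evolution import evolve


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def world(params):
    return sample_world(3, params)


@pytest.fixture(scope="session")
def ancestor(world, params):
    return initial_network(world, params)


@pytest.fixture(scope="session")
def evolved_m1(ancestor, params):
    """A full greedy walk to a local optimum under the minimal medium M1."""
    net, traj = evolve(ancestor, "M1", params)
    assert traj.terminated
    return net, traj


@pytest.fixture(scope="session")
def tiny_params():
    """A hand-checkable universe: 2 groups, 4 metabolites, 2 biomass targets."""
    return ModelParams(n_groups=2, n_biomass=2)


@pytest.fixture(scope="session")
def tiny_world(tiny_params):
    return sample_world(11, tiny_params)


@pytest.fixture(scope="session")
def tiny_ancestor(tiny_world, tiny_params):
    return initial_network(tiny_world, tiny_params)
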