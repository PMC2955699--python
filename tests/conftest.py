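import pytest

from coevonet import SimConfig, parse_topology, simulate_dataset


@pytest.fixture(scope="session")
def worked_example_pair():
    """The two 5-species topologies of the published worked example."""
    return parse_topology("((1,3),(2,4,5))"), parse_topology("((1,2),(5,(3,4)))")


@pytest.fixture(scope="session")
def small_dataset():
    """A small uncoupled synthetic dataset shared by pipeline tests."""
    cfg = SimConfig(n_proteins=24, target_mean_degree=3.0, coupling_rho=0.0, seed=42)
    return simulate_dataset(cfg)
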