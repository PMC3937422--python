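import numpy as np
import pytest

from plankweb import (
    FlowNetwork,
    ScenarioConfig,
    generate_seasonal_scenario,
    lake_topology_fixture,
)


def make_net(nodes, flows, imports=None, exports=None, respiration=None,
             storage_in=None, storage_out=None, element="C", phase="Summer"):
    """Small literal flow network: flows as {(src, dst): value}."""
    net = FlowNetwork.empty(element, phase, nodes)
    for (a, b), v in flows.items():
        net.T[net.index(a), net.index(b)] = v
    for attr, vals in (("imports", imports), ("exports", exports),
                       ("respiration", respiration), ("storage_in", storage_in),
                       ("storage_out", storage_out)):
        if vals:
            for n, v in vals.items():
                getattr(net, attr)[net.index(n)] = v
    return net


@pytest.fixture(scope="session")
def topology():
    return lake_topology_fixture()


@pytest.fixture(scope="session")
def scenario():
    return generate_seasonal_scenario(ScenarioConfig(seed=1))


@pytest.fixture()
def chain_net():
    """A -> B -> C with unit internal flows, balanced by import/respiration."""
    return make_net(
        ("A", "B", "C"),
        {("A", "B"): 1.0, ("B", "C"): 1.0},
        imports={"A": 1.0},
        respiration={"C": 1.0},
    )


@pytest.fixture()
def fan_net():
    """A splits evenly to B and C."""
    return make_net(
        ("A", "B", "C"),
        {("A", "B"): 0.5, ("A", "C"): 0.5},
        imports={"A": 1.0},
        exports={"B": 0.5, "C": 0.5},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20140227)
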