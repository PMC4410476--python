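"""Shared fixtures: planted-truth datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from regnet import synthetic
from regnet.containers import Edge, Interactome


def truth_interactome(network: synthetic.PlantedNetwork) -> Interactome:
    """The planted network as an interactome with unit MI weights."""
    return Interactome(
        {
            reg: [Edge(t, 1.0) for t in targets]
            for reg, targets in network.regulon_map.items()
        }
    )


@pytest.fixture(scope="session")
def desk_data():
    """Desk preset: 10x30 planted regulons, one +2-shifted regulator, 48 samples."""
    net = synthetic.desk_network(seed=0)
    design = synthetic.desk_design()
    expr, truth = synthetic.simulate_expression(net, design, seed=0)
    return net, design, expr, truth


@pytest.fixture(scope="session")
def small_net():
    """4 regulators x 30 targets + 100 background genes."""
    return synthetic.generate_network(4, 30, 0.0, 100, 0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
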