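"""Shared fixtures: small seeded synthetic circuits and hand-built skeletons."""

import numpy as np
import pytest

from hvc_census.skeleton import Skeleton
from hvc_census.synthetic_data import CircuitConfig, generate_circuit


def make_path_skeleton(points, compartment="dendrite", soma_first=True):
    """A simple path skeleton through the given points."""
    skel = Skeleton()
    for i, p in enumerate(points):
        comp = "soma" if (soma_first and i == 0) else compartment
        skel.add_node(i, p, compartment=comp)
        if i:
            skel.add_edge(i - 1, i)
    if soma_first:
        skel.soma_position = np.asarray(points[0], float)
    return skel


@pytest.fixture(scope="session")
def small_circuit():
    """A compact circuit reused by read-only tests (seeded, deterministic)."""
    cfg = CircuitConfig(
        volume_um=(300.0, 300.0, 300.0),
        n_ra=6,
        n_int=2,
        n_x=2,
        axon_path_um=4000.0,
        dendrite_path_um=1000.0,
        seed=42,
    )
    return generate_circuit(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
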