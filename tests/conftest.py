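"""Shared fixtures: tiny hand-built networks and random generator configs."""

from __future__ import annotations

import numpy as np
import pytest

from stpnet.network import AnnotatedNetwork, Interaction, ProteinNode
from stpnet.synthetic import SynthNetConfig, curated_like, generate_network


def make_network(edges, hubs=(), tfs=(), name="toy") -> AnnotatedNetwork:
    """Build a network from (a, b) pairs plus hub/TF id lists."""
    net = AnnotatedNetwork(name=name)
    for a, b in edges:
        net.add_edge(Interaction(a, b))
    for h in hubs:
        net.add_node(ProteinNode(id=h, is_hub=True))
    for t in tfs:
        net.add_node(ProteinNode(id=t, is_tf=True))
    return net


@pytest.fixture
def path3() -> AnnotatedNetwork:
    """A - B - C."""
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def path4() -> AnnotatedNetwork:
    """A - B - C - D."""
    return make_network([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def triangle() -> AnnotatedNetwork:
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def curated_net() -> AnnotatedNetwork:
    """The deterministic preset mirroring the curated-network geometry."""
    return generate_network(curated_like(seed=0))


def random_synth_config(rng: np.random.Generator) -> SynthNetConfig:
    """A random feasible four-hub generator configuration."""
    hubs = ("SNF1", "TOR1", "PKA1", "HOG1")
    degrees = tuple(int(d) for d in rng.integers(6, 20, size=4))
    pairs = [frozenset(p) for p in
             [(hubs[i], hubs[j]) for i in range(4) for j in range(i + 1, 4)]]
    pairwise = {p: int(rng.integers(0, 3)) for p in pairs}
    higher = {}
    if rng.random() < 0.5:
        trip = frozenset(rng.choice(hubs, size=3, replace=False))
        higher[trip] = 1
        for p in pairs:  # keep pairwise totals >= covering higher regions
            if p <= trip:
                pairwise[p] = max(pairwise[p], 1)
    return SynthNetConfig(
        hub_names=hubs,
        hub_degrees=degrees,
        pairwise_overlap=pairwise,
        higher_overlap=higher,
        n_extra_partner_edges=int(rng.integers(0, 8)),
        n_second_shell=int(rng.integers(0, 25)),
        tf_fraction=0.15,
        seed=int(rng.integers(2**31)),
    )


def random_gnp(rng: np.random.Generator, n: int, p: float) -> AnnotatedNetwork:
    """Erdos-Renyi G(n, p) as an AnnotatedNetwork with ids N00..N<n-1>."""
    net = AnnotatedNetwork(name=f"gnp{n}")
    ids = [f"N{i:02d}" for i in range(n)]
    for nid in ids:
        net.add_node(nid)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(Interaction(ids[i], ids[j]))
    return net
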