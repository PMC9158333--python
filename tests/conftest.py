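from __future__ import annotations

import numpy as np
import pytest

from causalmet import (CausalEdge, CausalNetwork, Entity, EntityClass,
                       mini_study)


def make_network(edges, entity_classes=None):
    """Build a CausalNetwork from (source, target, sign, score) tuples."""
    entity_classes = entity_classes or {}
    net = CausalNetwork()
    for u, v, *_ in edges:
        for node in (u, v):
            if node not in net:
                net.add_entity(Entity(
                    node, node,
                    entity_classes.get(node, EntityClass.PROTEIN)))
    for u, v, sign, score in edges:
        net.add_edge(CausalEdge(u, v, sign, score))
    return net


def random_edge_list(rng, n_nodes, n_edges, p_inhibiting=0.3):
    """Random distinct signed scored ordered pairs over ``n_nodes`` nodes."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = set()
    while len(pairs) < n_edges:
        a, b = rng.integers(0, n_nodes, size=2)
        if a != b:
            pairs.add((int(a), int(b)))
    return [
        (nodes[a], nodes[b],
         -1 if rng.random() < p_inhibiting else 1,
         round(float(rng.uniform(0.1, 1.0)), 3))
        for a, b in sorted(pairs)
    ]


@pytest.fixture(scope="session")
def mini():
    """The 60-node mini-interactome study with planted ground truth."""
    return mini_study(seed=42)


@pytest.fixture(scope="session")
def mini_scoring(mini):
    from causalmet import score_network
    return score_network(mini.network, mini.pathway_defs)
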