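"""Synthetic networks with planted hierarchical community structure.

The generator emulates the topological signature the detector relies
on: assortative, hierarchically nested blocks.  Nodes are grouped into a
balanced tree of blocks and each node pair is connected independently
with a probability determined by the depth of the pair's lowest common
ancestor block — highest inside a leaf block, strictly decreasing
toward the root.  Edge weights are drawn independently of the block
structure (community signal is carried by topology), uniform on (0, 1]
by default.

Everything is driven by a single integer seed and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .hierarchy import CommunityTree
from .network import ProteinNetwork

__all__ = [
    "HierarchicalPlantedSpec",
    "generate_hierarchical_planted_graph",
    "generate_random_weighted_graph",
]


def _uniform_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    # uniform on (0, 1]: flip the half-open [0, 1) interval
    return 1.0 - rng.random(size)


@dataclass
class HierarchicalPlantedSpec:
    """Parameters of the hierarchical planted-partition generator.

    ``branching[l]`` is the number of child blocks per block at depth l;
    leaves sit at depth ``levels`` and hold ``leaf_size`` nodes each.
    ``p_within_leaf`` is the connection probability for pairs sharing a
    leaf; ``p_ancestor[l]`` applies to pairs whose lowest common
    ancestor block is at depth l (l = 0 is the root), and must increase
    with l and stay below ``p_within_leaf``.
    """

    levels: int = 2
    branching: Sequence[int] = (2, 2)
    leaf_size: int = 30
    p_within_leaf: float = 0.5
    p_ancestor: Sequence[float] = (0.005, 0.05)
    weight_dist: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=_uniform_weights
    )
    seed: int = 0

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.branching) != self.levels:
            raise ValueError("branching must list one factor per level")
        if len(self.p_ancestor) != self.levels:
            raise ValueError("p_ancestor must list one probability per level")
        if any(b < 1 for b in self.branching) or self.leaf_size < 1:
            raise ValueError("branching factors and leaf_size must be positive")
        probs = [*self.p_ancestor, self.p_within_leaf]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(a >= b for a, b in zip(probs, probs[1:])):
            raise ValueError(
                "connection probabilities must strictly increase with tree depth"
            )


def _block_paths(spec: HierarchicalPlantedSpec) -> list[tuple[int, ...]]:
    return list(product(*(range(b) for b in spec.branching)))


def generate_hierarchical_planted_graph(
    spec: HierarchicalPlantedSpec,
) -> tuple[ProteinNetwork, CommunityTree]:
    """Sample a network plus its planted ground-truth community tree.

    Node ids are ``n<k>`` (zero-padded); the ground-truth tree mirrors
    the block tree with ids ``B`` (root), ``B0``, ``B0.1`` ... encoding
    the block path.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    paths = _block_paths(spec)
    n_total = len(paths) * spec.leaf_size
    width = len(str(n_total - 1))
    names = [f"n{str(i).zfill(width)}" for i in range(n_total)]
    block_nodes = {
        path: names[i * spec.leaf_size : (i + 1) * spec.leaf_size]
        for i, path in enumerate(paths)
    }

    def lca_depth(a: tuple[int, ...], b: tuple[int, ...]) -> int:
        d = 0
        for x, y in zip(a, b):
            if x != y:
                break
            d += 1
        return d

    net = ProteinNetwork(nodes=names)
    for i, pa in enumerate(paths):
        for pb in paths[i:]:
            if pa == pb:
                p = spec.p_within_leaf
                nodes = block_nodes[pa]
                k = len(nodes)
                mask = rng.random((k, k)) < p
                ww = spec.weight_dist(rng, k * k).reshape(k, k)
                for r in range(k):
                    for s in range(r + 1, k):
                        if mask[r, s]:
                            net.add_edge(nodes[r], nodes[s], float(ww[r, s]))
            else:
                p = spec.p_ancestor[lca_depth(pa, pb)]
                na, nb = block_nodes[pa], block_nodes[pb]
                mask = rng.random((len(na), len(nb))) < p
                ww = spec.weight_dist(rng, len(na) * len(nb)).reshape(len(na), len(nb))
                for r in range(len(na)):
                    for s in range(len(nb)):
                        if mask[r, s]:
                            net.add_edge(na[r], nb[s], float(ww[r, s]))

    def nested(prefix: tuple[int, ...], depth: int) -> dict:
        cid = "B" if not prefix else "B" + ".".join(map(str, prefix))
        if depth == spec.levels:
            return {"id": cid, "members": list(block_nodes[prefix])}
        return {
            "id": cid,
            "children": [
                nested(prefix + (b,), depth + 1) for b in range(spec.branching[depth])
            ],
        }

    truth = CommunityTree.from_nested(nested((), 0))
    if net.number_of_edges() == 0:
        raise ValueError("generated graph is edgeless; raise the probabilities")
    return net, truth


def generate_random_weighted_graph(
    n: int, p: float, seed: int = 0
) -> ProteinNetwork:
    """Erdős–Rényi G(n, p) with uniform (0, 1] weights, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    rng = np.random.default_rng(seed + 1)
    width = len(str(max(n - 1, 0)))
    names = {i: f"n{str(i).zfill(width)}" for i in range(n)}
    net = ProteinNetwork(nodes=names.values())
    edges = sorted(g.edges())
    ww = _uniform_weights(rng, len(edges))
    for (u, v), w in zip(edges, ww):
        net.add_edge(names[u], names[v], float(w))
    return net
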