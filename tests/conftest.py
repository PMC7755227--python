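from __future__ import annotations

import itertools

import pytest

from commnav.hierarchy import CommunityTree
from commnav.network import ProteinNetwork


@pytest.fixture
def two_triangles() -> ProteinNetwork:
    """Two disconnected unit-weight triangles: the classic Q = 0.5 case."""
    edges = [
        ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
        ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
    ]
    return ProteinNetwork(edges)


@pytest.fixture
def two_cliques() -> ProteinNetwork:
    """Two disconnected 4-cliques."""
    edges = []
    for grp in ("abcd", "wxyz"):
        edges += [(u, v, 1.0) for u, v in itertools.combinations(grp, 2)]
    return ProteinNetwork(edges)


@pytest.fixture
def navigation_example() -> tuple[ProteinNetwork, CommunityTree]:
    """Small hand-built hierarchy for navigation tests.

    Two level-1 communities: C1 (a leaf) and C4 (split into leaves C5,
    C6, C7).  Cross edges are laid out so that C5 and C7 each relate to
    C1, C6 relates only to C5, and C7's proteins include DET1 and SOC1.
    """
    tree = CommunityTree.from_nested(
        {
            "id": "root",
            "children": [
                {"id": "C1", "members": ["a1", "a2"]},
                {
                    "id": "C4",
                    "children": [
                        {"id": "C5", "members": ["b1", "b2"]},
                        {"id": "C6", "members": ["c1", "c2"]},
                        {"id": "C7", "members": ["DET1", "SOC1", "d3"]},
                    ],
                },
            ],
        }
    )
    net = ProteinNetwork(
        [
            # intra-leaf
            ("a1", "a2", 0.9),
            ("b1", "b2", 0.8),
            ("c1", "c2", 0.7),
            ("DET1", "SOC1", 0.6),
            ("SOC1", "d3", 0.5),
            # cross-leaf
            ("b1", "a1", 0.4),   # C5 - C1
            ("DET1", "a2", 0.3), # C7 - C1
            ("b2", "c1", 0.2),   # C5 - C6
        ]
    )
    return net, tree
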