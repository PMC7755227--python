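"""Interval labels and the community-relation index.

Every community carries a (pre, post, level) triple from a depth-first
traversal of the community tree; every network node carries the (pre,
post) pair of its leaf community.  Ancestry, disjointness and membership
then reduce to constant-time interval comparisons:

    c1 in desc(c2)  <=>  pre(c2) <= pre(c1) and post(c1) <= post(c2)

``desc`` is reflexive here (a community is its own descendant): the
relation-index construction must let a leaf witness itself when pairing
a leaf with a disjoint internal community.

The relation index IC records which disjoint community pairs are joined
by at least one underlying network edge.  It is built in two phases:
phase 1 scans each edge once and collects the connected leaf pairs;
phase 2 derives connected upper pairs (not both leaves) from those leaf
pairs without touching the edge set again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .hierarchy import CommunityTree
from .network import ProteinNetwork

__all__ = [
    "TreeIndex",
    "CommunityRelationIndex",
    "assign_tree_indexes",
    "is_descendant",
    "parent_of",
    "class_of",
    "are_disjoint",
    "member_of",
    "build_relation_index",
]


@dataclass
class TreeIndex:
    """(pre, post, level) labels per community plus per-node leaf labels."""

    pre: dict[str, int]
    post: dict[str, int]
    level: dict[str, int]
    node_label: dict[str, tuple[int, int]]
    leaf_of: dict[str, str]

    def node_pre(self, v: str) -> int:
        """Pre-order label of the leaf community containing node v."""
        return self.node_label[v][0]

    def to_json(self) -> str:
        payload = {
            cid: {"pre": self.pre[cid], "post": self.post[cid], "level": self.level[cid]}
            for cid in sorted(self.pre)
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"


def assign_tree_indexes(tree: CommunityTree) -> TreeIndex:
    """Label communities by a depth-first traversal in stored child order.

    ``pre`` is numbered on entry and ``post`` on exit, each by its own
    counter starting at 1; both are bijections onto 1..|V_C|.
    """
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    level: dict[str, int] = {}
    pre_counter = post_counter = 0
    # iterative DFS with explicit enter/exit events
    stack: list[tuple[str, bool]] = [(tree.root, False)]
    while stack:
        cid, done = stack.pop()
        if done:
            post_counter += 1
            post[cid] = post_counter
            continue
        pre_counter += 1
        pre[cid] = pre_counter
        level[cid] = tree[cid].level
        stack.append((cid, True))
        for child in reversed(tree.children(cid)):
            stack.append((child, False))

    node_label: dict[str, tuple[int, int]] = {}
    leaf_of: dict[str, str] = {}
    for cid in tree.leaves():
        lab = (pre[cid], post[cid])
        for v in tree[cid].members:
            node_label[v] = lab
            leaf_of[v] = cid
    return TreeIndex(pre, post, level, node_label, leaf_of)


# -- constant-time predicates -------------------------------------------


def is_descendant(c1: str, c2: str, idx: TreeIndex) -> bool:
    """c1 in desc(c2), reflexively: the interval of c1 lies inside c2's."""
    try:
        return idx.pre[c2] <= idx.pre[c1] and idx.post[c1] <= idx.post[c2]
    except KeyError as exc:
        raise KeyError(f"community {exc.args[0]!r} is not indexed") from exc


def parent_of(c: str, tree: CommunityTree) -> str | None:
    """Parent community id; None for the root."""
    return tree.parent(c)


def class_of(v: str, idx: TreeIndex) -> str:
    """The leaf community containing protein v."""
    try:
        return idx.leaf_of[v]
    except KeyError as exc:
        raise KeyError(f"node {v!r} is not assigned to any leaf community") from exc


def are_disjoint(c1: str, c2: str, idx: TreeIndex) -> bool:
    """Neither community contains the other (c1 ~/~ c2)."""
    return not is_descendant(c1, c2, idx) and not is_descendant(c2, c1, idx)


def member_of(v: str, c: str, idx: TreeIndex) -> bool:
    """Does protein v belong to community c (at any depth below it)?"""
    return is_descendant(class_of(v, idx), c, idx)


# -- community-relation index -------------------------------------------


@dataclass
class CommunityRelationIndex:
    """Between-community adjacency induced by the network's edges.

    ``leaf_edges`` joins pairs of distinct leaves; ``upper_edges`` joins
    disjoint pairs that are not both leaves.  Pairs are stored once,
    ordered by pre-order label.  The counters record the work done during
    construction (phase 1 touches each network edge exactly once; phase 2
    inspects community pairs only).
    """

    leaf_edges: set[tuple[str, str]] = field(default_factory=set)
    upper_edges: set[tuple[str, str]] = field(default_factory=set)
    edge_inspections: int = 0
    pair_inspections: int = 0

    def edges(self) -> set[tuple[str, str]]:
        return self.leaf_edges | self.upper_edges

    def connected(self, c1: str, c2: str, idx: TreeIndex) -> bool:
        """Is there at least one network edge between these two communities?"""
        pair = _ordered_pair(c1, c2, idx)
        return pair in self.leaf_edges or pair in self.upper_edges

    def to_json(self) -> str:
        payload = {
            "leaf_edges": sorted(self.leaf_edges),
            "upper_edges": sorted(self.upper_edges),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"


def _ordered_pair(c1: str, c2: str, idx: TreeIndex) -> tuple[str, str]:
    return (c1, c2) if idx.pre[c1] < idx.pre[c2] else (c2, c1)


def build_relation_index(
    tree: CommunityTree, idx: TreeIndex, net: ProteinNetwork
) -> CommunityRelationIndex:
    """Build IC: the disjoint community pairs connected by some edge.

    Phase 1 scans each edge of the network once and records the pairs of
    distinct leaf communities it connects.  Phase 2 enumerates the
    disjoint community pairs that are not both leaves (ordered by
    pre-order label) and keeps those above some connected leaf pair,
    ``desc`` taken reflexively so a leaf can pair with a disjoint
    internal community.
    """
    ic = CommunityRelationIndex()

    # phase 1: leaf-leaf adjacency from the edge set
    for u, v in net.edges:
        ic.edge_inspections += 1
        lu, lv = class_of(u, idx), class_of(v, idx)
        if lu != lv:
            ic.leaf_edges.add(_ordered_pair(lu, lv, idx))

    # ancestors (self included) per leaf, for the upward propagation
    def ancestors_self(cid: str) -> list[str]:
        out = [cid]
        p = tree.parent(cid)
        while p is not None:
            out.append(p)
            p = tree.parent(p)
        return out

    anc: dict[str, list[str]] = {
        leaf: ancestors_self(leaf) for leaf in tree.leaves()
    }

    # connected pairs at every level, derived from the leaf pairs alone
    connected: set[tuple[str, str]] = set(ic.leaf_edges)
    for l1, l2 in ic.leaf_edges:
        for a1 in anc[l1]:
            for a2 in anc[l2]:
                if are_disjoint(a1, a2, idx):
                    connected.add(_ordered_pair(a1, a2, idx))

    # phase 2: disjoint pairs, not both leaves, ordered by pre
    leaf_set = set(tree.leaves())
    by_pre = sorted(tree.communities, key=lambda c: idx.pre[c])
    for i, c1 in enumerate(by_pre):
        for c2 in by_pre[i + 1 :]:
            ic.pair_inspections += 1
            if not are_disjoint(c1, c2, idx):
                continue
            if c1 in leaf_set and c2 in leaf_set:
                continue
            if (c1, c2) in connected:
                ic.upper_edges.add((c1, c2))
    return ic
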