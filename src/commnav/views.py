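"""Multi-resolution views of a network and the zoom algebra.

A view is a graph whose vertices are a mix of meta-nodes (communities of
the hierarchy, pairwise disjoint) and atomic nodes (individual
proteins), such that the meta-nodes' member sets together with the
atomic nodes partition the protein set — the *frontier*.  Three edge
families connect them:

* protein–protein: an underlying network edge between two atomic nodes;
* community–community: at least one underlying edge between the two
  communities' members;
* protein–community: at least one underlying edge between the protein
  and a member of the community.

``zoom_in`` replaces a meta-node by its children (or, for a leaf, by its
member proteins); ``zoom_out`` collapses every view vertex lying inside
the enclosing community back into a single meta-node.  Views are
immutable values; both operations return a new view, and a zoom_out
applied right after a zoom_in restores the previous view exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .hierarchy import CommunityTree
from .indexes import (
    CommunityRelationIndex,
    TreeIndex,
    class_of,
    is_descendant,
    member_of,
)
from .network import ProteinNetwork

__all__ = [
    "PROTEIN_PROTEIN",
    "COMMUNITY_COMMUNITY",
    "PROTEIN_COMMUNITY",
    "ViewEdge",
    "ViewGraph",
    "MetaEdgeStats",
    "EdgeInspectionCounter",
    "initial_view",
    "level1_view",
    "zoom_in",
    "zoom_out",
    "path_to_node",
    "meta_edge_stats",
    "view_to_json",
]

PROTEIN_PROTEIN = "protein-protein"
COMMUNITY_COMMUNITY = "community-community"
PROTEIN_COMMUNITY = "protein-community"


class ViewEdge(NamedTuple):
    """Typed unordered view edge.

    For symmetric families the endpoints are stored sorted; for
    protein–community edges ``u`` is the protein and ``v`` the community.
    """

    u: str
    v: str
    family: str


def _pp(a: str, b: str) -> ViewEdge:
    return ViewEdge(*sorted((a, b)), PROTEIN_PROTEIN)


def _cc(a: str, b: str) -> ViewEdge:
    return ViewEdge(*sorted((a, b)), COMMUNITY_COMMUNITY)


def _pc(protein: str, community: str) -> ViewEdge:
    return ViewEdge(protein, community, PROTEIN_COMMUNITY)


class EdgeInspectionCounter:
    """Counts underlying network-edge inspections (complexity guard)."""

    def __init__(self) -> None:
        self.edges = 0


@dataclass(frozen=True)
class ViewGraph:
    """Immutable resolution-level graph G_L = (V_L, E_L)."""

    meta_nodes: frozenset[str]
    atomic_nodes: frozenset[str]
    edges: frozenset[ViewEdge]

    def __contains__(self, x: str) -> bool:
        return x in self.meta_nodes or x in self.atomic_nodes

    def edges_incident(self, x: str) -> list[ViewEdge]:
        return [e for e in self.edges if x in (e.u, e.v)]

    def frontier_partition_ok(self, tree: CommunityTree) -> bool:
        """Do meta-node member sets plus atomic nodes partition V exactly?"""
        total = 0
        union: set[str] = set()
        for c in self.meta_nodes:
            m = tree[c].members
            total += len(m)
            union |= m
        total += len(self.atomic_nodes)
        union |= self.atomic_nodes
        return total == len(union) and union == set(tree.node_set)


def initial_view(tree: CommunityTree) -> ViewGraph:
    """The starting representation: the root meta-node alone, no edges."""
    return ViewGraph(frozenset({tree.root}), frozenset(), frozenset())


def level1_view(
    tree: CommunityTree,
    idx: TreeIndex,
    ic: CommunityRelationIndex,
    net: ProteinNetwork,
) -> ViewGraph:
    """Convenience: the view after one zoom_in on the root.

    Shows the level-1 communities with their between-community edges —
    the first screen a navigation front-end would present.
    """
    return zoom_in(initial_view(tree), tree.root, tree, idx, ic, net)


def _frontier_container(
    u: str, view: ViewGraph, tree: CommunityTree, idx: TreeIndex
) -> str | None:
    """The view vertex whose members include protein u (or u itself)."""
    if u in view.atomic_nodes:
        return u
    c: str | None = class_of(u, idx)
    while c is not None and c not in view.meta_nodes:
        c = tree.parent(c)
    return c


def _child_containing(
    u: str, parent: str, tree: CommunityTree, idx: TreeIndex
) -> str | None:
    """The child of ``parent`` whose members include protein u, if any."""
    c: str | None = class_of(u, idx)
    while c is not None and tree.parent(c) != parent:
        c = tree.parent(c)
    return c


def zoom_in(
    view: ViewGraph,
    c: str,
    tree: CommunityTree,
    idx: TreeIndex,
    ic: CommunityRelationIndex,
    net: ProteinNetwork,
    counter: EdgeInspectionCounter | None = None,
) -> ViewGraph:
    """Expand meta-node ``c`` into its children or member proteins.

    A leaf community is replaced by its member proteins together with
    their internal edges; cross edges to the surviving atomic nodes and
    meta-nodes previously adjacent to ``c`` are re-derived from the
    network.  An internal community is replaced by its children, with
    child–child and child–meta edges taken from the relation index and
    child–protein edges re-derived from the network.  Every edge
    formerly incident to ``c`` is removed.  Each underlying network edge
    is inspected at most once (tracked by ``counter`` when given).
    """
    if c not in view.meta_nodes:
        raise ValueError(f"{c!r} is not a meta-node of the current view")
    if counter is None:
        counter = EdgeInspectionCounter()

    # nodes of the current view adjacent to c
    adj_atomic: set[str] = set()
    adj_meta: set[str] = set()
    for e in view.edges:
        if e.family == PROTEIN_COMMUNITY and e.v == c:
            adj_atomic.add(e.u)
        elif e.family == COMMUNITY_COMMUNITY and c in (e.u, e.v):
            adj_meta.add(e.u if e.v == c else e.v)

    new_edges: set[ViewEdge] = set()
    comm = tree[c]
    if comm.is_leaf:
        members = comm.members
        new_atomic = members
        new_meta: Iterable[str] = ()
        for v1 in sorted(members):
            for u, _w in net.adjacency(v1).items():
                if u in members:
                    if v1 < u:  # count each internal edge once
                        counter.edges += 1
                        new_edges.add(_pp(v1, u))
                    continue
                counter.edges += 1
                if u in adj_atomic:
                    new_edges.add(_pp(v1, u))
                else:
                    m = _frontier_container(u, view, tree, idx)
                    if m is not None and m in adj_meta:
                        new_edges.add(_pc(v1, m))
    else:
        children = tree.children(c)
        new_meta = children
        new_atomic = frozenset()
        child_set = set(children)
        # child-child edges from the relation index
        for i, c1 in enumerate(children):
            for c2 in children[i + 1 :]:
                if ic.connected(c1, c2, idx):
                    new_edges.add(_cc(c1, c2))
        # child-meta edges from the relation index
        for c1 in children:
            for m in adj_meta:
                if ic.connected(c1, m, idx):
                    new_edges.add(_cc(c1, m))
        # child-protein edges from the network
        for v2 in sorted(adj_atomic):
            for u, _w in net.adjacency(v2).items():
                if u in adj_atomic and u < v2:
                    continue  # peer atomic edge, not ours to create
                counter.edges += 1
                child = _child_containing(u, c, tree, idx)
                if child is not None and child in child_set:
                    new_edges.add(_pc(v2, child))

    kept_edges = {e for e in view.edges if c not in (e.u, e.v)}
    return ViewGraph(
        meta_nodes=(view.meta_nodes - {c}) | frozenset(new_meta),
        atomic_nodes=view.atomic_nodes | frozenset(new_atomic),
        edges=frozenset(kept_edges | new_edges),
    )


def zoom_out(
    view: ViewGraph, x: str, tree: CommunityTree, idx: TreeIndex
) -> ViewGraph:
    """Collapse the community enclosing ``x`` back into one meta-node.

    For an atomic node the enclosing community is its leaf (all atomic
    nodes of that leaf collapse together); for a meta-node it is the
    parent community.  Every view vertex lying inside the enclosing
    community — sibling meta-nodes, deeper-expanded descendants, atomic
    members — is absorbed, and each edge from an absorbed vertex to a
    survivor is replaced by an edge to the new meta-node.
    """
    if x not in view:
        raise ValueError(f"{x!r} is not present in the current view")
    if x in view.meta_nodes:
        cp = tree.parent(x)
        if cp is None:
            raise ValueError("cannot zoom out on the root community")
    else:
        cp = class_of(x, idx)

    group_meta = {m for m in view.meta_nodes if is_descendant(m, cp, idx)}
    group_atomic = {v for v in view.atomic_nodes if member_of(v, cp, idx)}
    group = group_meta | group_atomic

    new_edges: set[ViewEdge] = set()
    for e in view.edges:
        u_in, v_in = e.u in group, e.v in group
        if u_in and v_in:
            continue
        if not u_in and not v_in:
            new_edges.add(e)
            continue
        other = e.v if u_in else e.u
        if other in view.meta_nodes:
            new_edges.add(_cc(other, cp))
        else:
            new_edges.add(_pc(other, cp))

    return ViewGraph(
        meta_nodes=(view.meta_nodes - group_meta) | {cp},
        atomic_nodes=view.atomic_nodes - group_atomic,
        edges=frozenset(new_edges),
    )


def path_to_node(v: str, tree: CommunityTree, idx: TreeIndex) -> list[str]:
    """Root-to-leaf community path containing protein ``v`` (root first)."""
    path = [class_of(v, idx)]
    while True:
        p = tree.parent(path[-1])
        if p is None:
            break
        path.append(p)
    return path[::-1]


class MetaEdgeStats(NamedTuple):
    """Summary of the underlying edges witnessing one view edge."""

    count: int
    min_w: float
    max_w: float
    mean_w: float


def meta_edge_stats(
    edge: ViewEdge,
    view: ViewGraph,
    tree: CommunityTree,
    idx: TreeIndex,
    net: ProteinNetwork,
) -> MetaEdgeStats:
    """Count/min/max/mean weight of the network edges behind a view edge."""
    if edge not in view.edges:
        raise ValueError(f"edge {edge} is absent from the view")
    weights: list[float] = []
    if edge.family == PROTEIN_PROTEIN:
        weights.append(net.weight(edge.u, edge.v))
    elif edge.family == PROTEIN_COMMUNITY:
        for u, w in net.adjacency(edge.u).items():
            if member_of(u, edge.v, idx):
                weights.append(w)
    else:
        m1, m2 = tree[edge.u].members, tree[edge.v].members
        small, other = (m1, edge.v) if len(m1) <= len(m2) else (m2, edge.u)
        for v1 in small:
            for u, w in net.adjacency(v1).items():
                if member_of(u, other, idx):
                    weights.append(w)
    if not weights:  # pragma: no cover - impossible on edge-correct views
        raise ValueError(f"view edge {edge} has no underlying network edge")
    return MetaEdgeStats(
        count=len(weights),
        min_w=min(weights),
        max_w=max(weights),
        mean_w=sum(weights) / len(weights),
    )


def view_to_json(
    view: ViewGraph,
    tree: CommunityTree,
    idx: TreeIndex,
    net: ProteinNetwork | None = None,
    with_stats: bool = False,
    scores: dict[str, float] | None = None,
) -> str:
    """Deterministic JSON serialization of a view.

    With ``with_stats`` (requires ``net``) every edge carries its
    underlying count/min/max/mean weight summary; ``scores`` attaches an
    optional per-protein score to atomic nodes.
    """
    meta = [
        {"id": c, "size": tree[c].size, "level": tree[c].level}
        for c in sorted(view.meta_nodes)
    ]
    atomic = []
    for v in sorted(view.atomic_nodes):
        rec: dict = {"id": v, "leaf": class_of(v, idx)}
        if scores is not None and v in scores:
            rec["score"] = scores[v]
        atomic.append(rec)
    edges = []
    for e in sorted(view.edges):
        rec = {"u": e.u, "v": e.v, "family": e.family}
        if with_stats:
            if net is None:
                raise ValueError("with_stats requires the underlying network")
            s = meta_edge_stats(e, view, tree, idx, net)
            rec["stats"] = {
                "count": s.count,
                "min_w": s.min_w,
                "max_w": s.max_w,
                "mean_w": s.mean_w,
            }
        edges.append(rec)
    payload = {
        "schema_version": 1,
        "meta_nodes": meta,
        "atomic_nodes": atomic,
        "edges": edges,
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"
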