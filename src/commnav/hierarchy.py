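"""Divisive hierarchical community detection.

The hierarchy is built top-down: the Louvain method partitions the whole
network into level-1 communities (only the final, highest-modularity
partition of a Louvain run is kept — never the intermediate dendrogram);
each community large enough (>= ``minsplit`` members) whose own Louvain
partition is non-trivial and has positive modularity on the induced
subgraph is split again, recursively, until no community qualifies.  The
result is a rooted tree whose leaves partition the node set.

``minsplit`` controls leaf granularity: it is the minimum community size
at which a further split is attempted.  The default of 50 suits networks
of a few hundred to a few thousand nodes; larger networks (tens of
thousands of nodes) warrant several hundred.

Randomness is confined to the Louvain node-visit order, driven by a
single integer seed; identical (network, minsplit, seed) yield an
identical tree.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .network import ProteinNetwork

__all__ = [
    "Community",
    "CommunityTree",
    "modularity",
    "louvain_top_partition",
    "gain_modularity_check",
    "build_hierarchy",
]

ROOT_ID = "C0"


@dataclass
class Community:
    """A node of the community tree: a set of proteins at a given depth."""

    id: str
    members: frozenset[str]
    level: int
    parent: str | None = None
    children: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def display_label(self) -> str:
        """Label in the "C4-L1" style (community id plus level suffix)."""
        return f"{self.id}-L{self.level}"


class CommunityTree:
    """Rooted tree of nested communities; leaves partition the node set."""

    def __init__(
        self,
        communities: Mapping[str, Community],
        root: str = ROOT_ID,
        minsplit: int | None = None,
        seed: int | None = None,
    ) -> None:
        self.communities = dict(communities)
        self.root = root
        self.minsplit = minsplit
        self.seed = seed

    # -- construction ----------------------------------------------------

    @classmethod
    def from_nested(cls, nested: dict, minsplit: int | None = None,
                    seed: int | None = None) -> "CommunityTree":
        """Build a tree from nested dicts ``{"id", "members"?, "children"?}``.

        Internal nodes may omit ``members``; they are inferred as the
        union of their children's members.  Useful for hand-written and
        planted ground-truth trees.
        """
        comms: dict[str, Community] = {}

        def walk(spec: dict, level: int, parent: str | None) -> frozenset[str]:
            cid = spec["id"]
            if cid in comms:
                raise ValueError(f"duplicate community id {cid!r}")
            kids = spec.get("children", [])
            if kids:
                members: frozenset[str] = frozenset()
                child_ids = []
                comms[cid] = Community(cid, frozenset(), level, parent, [])
                for k in kids:
                    members |= walk(k, level + 1, cid)
                    child_ids.append(k["id"])
                comms[cid].members = frozenset(spec.get("members", members))
                comms[cid].children = child_ids
                return comms[cid].members
            members = frozenset(spec["members"])
            comms[cid] = Community(cid, members, level, parent, [])
            return members

        walk(nested, 0, None)
        tree = cls(comms, root=nested["id"], minsplit=minsplit, seed=seed)
        tree.validate()
        return tree

    # -- queries ---------------------------------------------------------

    def __getitem__(self, cid: str) -> Community:
        return self.communities[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.communities

    def parent(self, cid: str) -> str | None:
        return self.communities[cid].parent

    def children(self, cid: str) -> list[str]:
        return self.communities[cid].children

    def leaves(self) -> list[str]:
        return [c.id for c in self.communities.values() if c.is_leaf]

    def depth(self) -> int:
        return max(c.level for c in self.communities.values())

    @property
    def node_set(self) -> frozenset[str]:
        return self.communities[self.root].members

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        root = self.communities[self.root]
        if root.level != 0 or root.parent is not None:
            raise ValueError("root must have level 0 and no parent")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            cid = stack.pop()
            if cid in seen:
                raise ValueError(f"community {cid!r} reached twice (cycle?)")
            seen.add(cid)
            c = self.communities[cid]
            if c.children:
                union: set[str] = set()
                total = 0
                for k in c.children:
                    child = self.communities[k]
                    if child.parent != cid:
                        raise ValueError(f"{k!r} has wrong parent pointer")
                    if child.level != c.level + 1:
                        raise ValueError(f"{k!r} has wrong level")
                    union |= child.members
                    total += len(child.members)
                if union != set(c.members) or total != len(c.members):
                    raise ValueError(
                        f"children of {cid!r} do not partition its member set"
                    )
                stack.extend(c.children)
        if seen != set(self.communities):
            raise ValueError("tree contains communities unreachable from the root")
        # leaves partition V (follows from the per-node checks plus root cover)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        """Deterministic JSON serialization of the whole tree."""
        payload = {
            "schema_version": 1,
            "root": self.root,
            "minsplit": self.minsplit,
            "seed": self.seed,
            "communities": {
                cid: {
                    "members": sorted(c.members),
                    "level": c.level,
                    "parent": c.parent,
                    "children": list(c.children),
                }
                for cid, c in sorted(self.communities.items())
            },
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "CommunityTree":
        payload = json.loads(text)
        comms = {
            cid: Community(
                cid,
                frozenset(rec["members"]),
                rec["level"],
                rec["parent"],
                list(rec["children"]),
            )
            for cid, rec in payload["communities"].items()
        }
        tree = cls(
            comms,
            root=payload["root"],
            minsplit=payload.get("minsplit"),
            seed=payload.get("seed"),
        )
        tree.validate()
        return tree


# -- modularity and Louvain ---------------------------------------------


def modularity(net: ProteinNetwork, partition: Mapping[str, object]) -> float:
    """Newman–Girvan weighted modularity of a partition.

    Q = (1/2m) * sum_ij [W_ij - k_i k_j / 2m] * delta(c_i, c_j), with m the
    total edge weight and k_i the weighted degree.  The trivial
    single-community partition scores exactly 0.
    """
    missing = net.nodes - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = net.total_weight()
    if m <= 0:
        raise ValueError("modularity is undefined on a zero-total-weight network")
    intra: dict[object, float] = {}
    degree: dict[object, float] = {}
    for (u, v), w in net.edges.items():
        cu, cv = partition[u], partition[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    for v in net.nodes:
        c = partition[v]
        degree[c] = degree.get(c, 0.0) + net.weighted_degree(v)
    q = 0.0
    for c in degree:
        q += intra.get(c, 0.0) / m - (degree[c] / (2.0 * m)) ** 2
    return q


def louvain_top_partition(net: ProteinNetwork, seed: int) -> dict[str, int]:
    """Final (highest-modularity) Louvain partition of the network.

    Only the last aggregation level of the Louvain run is kept.  Labels
    are consecutive integers assigned by each community's smallest member
    id, so the output is independent of backend set ordering.
    """
    if net.number_of_edges() == 0:
        raise ValueError("Louvain requires a network with at least one edge")
    g = net.to_networkx()
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    comms = sorted((frozenset(c) for c in comms), key=lambda c: min(c))
    labels: dict[str, int] = {}
    for k, c in enumerate(comms):
        for v in c:
            labels[v] = k
    return labels


def gain_modularity_check(
    subnet: ProteinNetwork, proposed: Mapping[str, object]
) -> bool:
    """Is the proposed split worth applying?

    True iff the proposal has at least two communities and its modularity
    on the subnetwork is strictly positive, i.e. it beats the trivial
    single-community partition (whose Q is identically 0).  Edgeless
    subnetworks are never split.
    """
    if subnet.number_of_edges() == 0:
        return False
    if len(set(proposed.values())) < 2:
        return False
    return modularity(subnet, proposed) > 0.0


def _child_seed(seed: int, invocation: int) -> int:
    # one deterministic sub-seed per Louvain invocation, in discovery order
    return (seed * 2654435761 + invocation) % (2**31)


def build_hierarchy(
    net: ProteinNetwork, minsplit: int = 50, seed: int = 0
) -> CommunityTree:
    """Build the divisive community hierarchy of a network.

    Level 1 is the Louvain partition of the whole network.  A community
    with at least ``minsplit`` members is split into the Louvain partition
    of its induced subgraph (internal edges only) whenever that partition
    is non-trivial with positive modularity; newly created communities
    are enqueued and the loop ends when no community can be split.
    Community ids are assigned in breadth-first discovery order.

    Isolated nodes become their own level-1 singleton communities.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot build a hierarchy of an empty network")
    if net.number_of_edges() == 0:
        raise ValueError("cannot build a hierarchy of an edgeless network")
    if minsplit < 2:
        raise ValueError("minsplit must be at least 2")

    comms: dict[str, Community] = {
        ROOT_ID: Community(ROOT_ID, frozenset(net.nodes), 0, None, [])
    }
    counter = 0  # community id counter (root is C0)
    invocation = 0  # Louvain invocation counter, for sub-seeds

    def partition_to_children(
        parent: Community, labels: Mapping[str, int]
    ) -> list[Community]:
        nonlocal counter
        groups: dict[int, set[str]] = {}
        for v, lab in labels.items():
            groups.setdefault(lab, set()).add(v)
        out = []
        for members in sorted(groups.values(), key=min):
            counter += 1
            cid = f"C{counter}"
            out.append(
                Community(cid, frozenset(members), parent.level + 1, parent.id, [])
            )
        return out

    top = louvain_top_partition(net, _child_seed(seed, invocation))
    invocation += 1
    level1 = partition_to_children(comms[ROOT_ID], top)
    for c in level1:
        comms[c.id] = c
    comms[ROOT_ID].children = [c.id for c in level1]

    queue = deque(level1)
    while queue:
        c = queue.popleft()
        if c.size < minsplit:
            continue
        subnet = net.induced_subgraph(c.members)
        if subnet.number_of_edges() == 0:
            continue
        labels = louvain_top_partition(subnet, _child_seed(seed, invocation))
        invocation += 1
        if not gain_modularity_check(subnet, labels):
            continue
        kids = partition_to_children(c, labels)
        for k in kids:
            comms[k.id] = k
        c.children = [k.id for k in kids]
        queue.extend(kids)

    tree = CommunityTree(comms, root=ROOT_ID, minsplit=minsplit, seed=seed)
    tree.validate()
    return tree
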