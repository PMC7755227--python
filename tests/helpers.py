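"""Shared test helpers: brute-force oracles and random instance builders.

The oracles deliberately avoid the package's index/view code paths: they
recompute everything from member sets and the raw edge list, so index
and view implementations are checked against an independent route.
"""

from __future__ import annotations

import random
from itertools import combinations

from commnav.hierarchy import Community, CommunityTree
from commnav.network import ProteinNetwork
from commnav.views import (
    COMMUNITY_COMMUNITY,
    PROTEIN_COMMUNITY,
    PROTEIN_PROTEIN,
    ViewEdge,
    ViewGraph,
)

# -- brute-force relation index -----------------------------------------


def brute_force_relation_index(
    tree: CommunityTree, net: ProteinNetwork
) -> tuple[set[frozenset], set[frozenset]]:
    """All disjoint community pairs joined by some edge, by member sets.

    Returns (leaf_pairs, upper_pairs) as sets of frozen 2-sets.
    """
    leaves = set(tree.leaves())
    leaf_pairs: set[frozenset] = set()
    upper_pairs: set[frozenset] = set()
    comms = list(tree.communities)
    edges = list(net.edges)
    for c1, c2 in combinations(comms, 2):
        m1, m2 = tree[c1].members, tree[c2].members
        if m1 & m2:
            continue  # not disjoint (one contains the other, or shared nodes)
        if any((u in m1 and v in m2) or (u in m2 and v in m1) for u, v in edges):
            pair = frozenset((c1, c2))
            if c1 in leaves and c2 in leaves:
                leaf_pairs.add(pair)
            else:
                upper_pairs.add(pair)
    return leaf_pairs, upper_pairs


def as_pair_sets(ic) -> tuple[set[frozenset], set[frozenset]]:
    return (
        {frozenset(p) for p in ic.leaf_edges},
        {frozenset(p) for p in ic.upper_edges},
    )


# -- brute-force view reconstruction ------------------------------------


def brute_force_view_edges(
    view: ViewGraph, tree: CommunityTree, net: ProteinNetwork
) -> frozenset[ViewEdge]:
    """Recompute all three edge families from the frontier and E alone."""
    container: dict[str, str] = {v: v for v in view.atomic_nodes}
    for c in view.meta_nodes:
        for v in tree[c].members:
            container[v] = c
    out: set[ViewEdge] = set()
    for u, v in net.edges:
        cu, cv = container[u], container[v]
        if cu == cv:
            continue
        u_atomic = cu == u and u in view.atomic_nodes
        v_atomic = cv == v and v in view.atomic_nodes
        if u_atomic and v_atomic:
            out.add(ViewEdge(*sorted((u, v)), PROTEIN_PROTEIN))
        elif u_atomic:
            out.add(ViewEdge(u, cv, PROTEIN_COMMUNITY))
        elif v_atomic:
            out.add(ViewEdge(v, cu, PROTEIN_COMMUNITY))
        else:
            out.add(ViewEdge(*sorted((cu, cv)), COMMUNITY_COMMUNITY))
    return frozenset(out)


# -- random instances ----------------------------------------------------


def random_tree_instance(
    rng: random.Random,
    n_nodes: int | None = None,
    max_levels: int = 4,
    edge_p: float = 0.25,
) -> tuple[ProteinNetwork, CommunityTree]:
    """A random weighted graph plus a random nested-partition tree.

    The tree is built by recursively splitting shuffled member lists,
    independent of graph structure — suitable as an arbitrary valid
    hierarchy for index and view oracles.
    """
    n = n_nodes if n_nodes is not None else rng.randint(8, 30)
    names = [f"v{i:03d}" for i in range(n)]
    counter = [0]

    def nested(members: list[str], depth: int) -> dict:
        cid = f"T{counter[0]}"
        counter[0] += 1
        if depth >= max_levels - 1 or len(members) < 4 or rng.random() < 0.25:
            return {"id": cid, "members": members}
        k = rng.randint(2, min(4, len(members) // 2))
        shuffled = members[:]
        rng.shuffle(shuffled)
        cuts = sorted(rng.sample(range(1, len(members)), k - 1))
        parts = [
            shuffled[a:b] for a, b in zip([0, *cuts], [*cuts, len(members)])
        ]
        return {"id": cid, "children": [nested(p, depth + 1) for p in parts]}

    tree = CommunityTree.from_nested(nested(names, 0))
    net = ProteinNetwork(nodes=names)
    for u, v in combinations(names, 2):
        if rng.random() < edge_p:
            net.add_edge(u, v, 1.0 - rng.random())
    return net, tree


def random_plain_tree(rng: random.Random, n_communities: int) -> CommunityTree:
    """A random tree with roughly ``n_communities`` communities.

    Grown by attaching children to random internal nodes; members are
    assigned one synthetic protein per leaf.
    """
    comms = {"T0": Community("T0", frozenset(), 0, None, [])}
    k = 1
    while len(comms) < n_communities:
        parent = rng.choice(list(comms))
        # give a childless node at least two children at once (keeps the
        # "internal => >= 2 children" shape of real hierarchies)
        n_new = 2 if not comms[parent].children else 1
        for _ in range(n_new):
            cid = f"T{k}"
            k += 1
            comms[cid] = Community(
                cid, frozenset(), comms[parent].level + 1, parent, []
            )
            comms[parent].children.append(cid)
    for cid, c in comms.items():
        if not c.children:
            c.members = frozenset({f"p_{cid}"})

    def fill(cid: str) -> frozenset[str]:
        c = comms[cid]
        if c.children:
            m: frozenset[str] = frozenset()
            for ch in c.children:
                m |= fill(ch)
            c.members = m
        return c.members

    fill("T0")
    tree = CommunityTree(comms, root="T0")
    tree.validate()
    return tree


def walk_is_descendant(tree: CommunityTree, c1: str, c2: str) -> bool:
    """Reflexive ancestry by explicit parent-pointer walking."""
    cur: str | None = c1
    while cur is not None:
        if cur == c2:
            return True
        cur = tree.parent(cur)
    return False
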