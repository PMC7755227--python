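import json
import random

import pytest
from helpers import brute_force_view_edges, random_tree_instance

from commnav.indexes import assign_tree_indexes, build_relation_index
from commnav.views import (
    COMMUNITY_COMMUNITY,
    PROTEIN_COMMUNITY,
    PROTEIN_PROTEIN,
    EdgeInspectionCounter,
    ViewEdge,
    initial_view,
    level1_view,
    meta_edge_stats,
    path_to_node,
    view_to_json,
    zoom_in,
    zoom_out,
)


@pytest.fixture
def nav(navigation_example):
    net, tree = navigation_example
    idx = assign_tree_indexes(tree)
    ic = build_relation_index(tree, idx, net)
    return net, tree, idx, ic


class TestInitialView:
    def test_root_alone_no_edges(self, nav):
        net, tree, idx, ic = nav
        v = initial_view(tree)
        assert v.meta_nodes == {tree.root}
        assert v.atomic_nodes == frozenset()
        assert v.edges == frozenset()
        assert v.frontier_partition_ok(tree)

    def test_level1_view_shows_first_level_communities(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        assert v.meta_nodes == {"C1", "C4"}
        assert v.edges == {ViewEdge("C1", "C4", COMMUNITY_COMMUNITY)}


class TestZoomIn:
    def test_expanding_internal_community_uses_relation_index(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v2 = zoom_in(v, "C4", tree, idx, ic, net)
        assert v2.meta_nodes == {"C1", "C5", "C6", "C7"}
        assert v2.edges == {
            ViewEdge("C1", "C5", COMMUNITY_COMMUNITY),
            ViewEdge("C1", "C7", COMMUNITY_COMMUNITY),
            ViewEdge("C5", "C6", COMMUNITY_COMMUNITY),
        }
        assert v2.frontier_partition_ok(tree)

    def test_expanding_leaf_shows_proteins_with_all_three_families(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        v = zoom_in(v, "C7", tree, idx, ic, net)
        assert v.atomic_nodes == {"DET1", "SOC1", "d3"}
        assert v.meta_nodes == {"C1", "C5", "C6"}
        assert ViewEdge("DET1", "SOC1", PROTEIN_PROTEIN) in v.edges
        assert ViewEdge("DET1", "C1", PROTEIN_COMMUNITY) in v.edges
        # C7's former community edge to C1 is gone
        assert ViewEdge("C1", "C7", COMMUNITY_COMMUNITY) not in v.edges
        assert v.edges == brute_force_view_edges(v, tree, net)

    def test_zoom_on_non_meta_node_rejected(self, nav):
        net, tree, idx, ic = nav
        with pytest.raises(ValueError, match="not a meta-node"):
            zoom_in(initial_view(tree), "C5", tree, idx, ic, net)

    def test_each_network_edge_inspected_at_most_once(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        for target in ["C4", "C7", "C5", "C1", "C6"]:
            counter = EdgeInspectionCounter()
            v = zoom_in(v, target, tree, idx, ic, net, counter=counter)
            assert counter.edges <= net.number_of_edges()


class TestZoomOut:
    def test_collapsing_protein_restores_leaf_meta_node(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        expanded = zoom_in(v, "C7", tree, idx, ic, net)
        assert zoom_out(expanded, "SOC1", tree, idx) == v

    def test_collapsing_any_sibling_restores_parent_view(self, nav):
        net, tree, idx, ic = nav
        v1 = level1_view(tree, idx, ic, net)
        v2 = zoom_in(v1, "C4", tree, idx, ic, net)
        for sib in ("C5", "C6", "C7"):
            assert zoom_out(v2, sib, tree, idx) == v1

    def test_root_collapse_rejected(self, nav):
        net, tree, idx, ic = nav
        with pytest.raises(ValueError, match="root"):
            zoom_out(initial_view(tree), "root", tree, idx)

    def test_collapsing_level1_community_restores_initial_view(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        assert zoom_out(v, "C1", tree, idx) == initial_view(tree)

    def test_absent_node_rejected(self, nav):
        net, tree, idx, ic = nav
        with pytest.raises(ValueError, match="not present"):
            zoom_out(initial_view(tree), "C5", tree, idx)

    def test_collapse_absorbs_deeper_expanded_siblings(self, nav):
        """Collapsing into a community absorbs every view vertex inside it,
        even those exposed by deeper zooms, keeping the frontier a partition."""
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        v = zoom_in(v, "C7", tree, idx, ic, net)  # C7's proteins now visible
        collapsed = zoom_out(v, "C5", tree, idx)  # collapse into C4
        assert collapsed.meta_nodes == {"C1", "C4"}
        assert collapsed.atomic_nodes == frozenset()
        assert collapsed.frontier_partition_ok(tree)


class TestRandomizedOracles:
    def run_sequence(self, rng, steps=6):
        net, tree = random_tree_instance(rng)
        idx = assign_tree_indexes(tree)
        ic = build_relation_index(tree, idx, net)
        view = initial_view(tree)
        views = [view]
        for _ in range(steps):
            expandable = sorted(view.meta_nodes)
            if not expandable:
                break
            target = rng.choice(expandable)
            view = zoom_in(view, target, tree, idx, ic, net)
            views.append(view)
        return net, tree, idx, ic, views

    def test_edge_families_match_brute_force_along_sequences(self):
        rng = random.Random(10)
        for _ in range(30):
            net, tree, idx, ic, views = self.run_sequence(rng)
            for v in views:
                assert v.edges == brute_force_view_edges(v, tree, net)
                assert v.frontier_partition_ok(tree)

    def test_zoom_out_inverts_zoom_in(self):
        rng = random.Random(11)
        for _ in range(30):
            net, tree = random_tree_instance(rng)
            idx = assign_tree_indexes(tree)
            ic = build_relation_index(tree, idx, net)
            view = initial_view(tree)
            for _ in range(5):
                expandable = sorted(view.meta_nodes)
                if not expandable:
                    break
                target = rng.choice(expandable)
                new = zoom_in(view, target, tree, idx, ic, net)
                comm = tree[target]
                child = (
                    rng.choice(sorted(comm.members))
                    if comm.is_leaf
                    else rng.choice(comm.children)
                )
                assert zoom_out(new, child, tree, idx) == view
                view = new

    def test_repeated_zoom_out_reaches_initial_view(self):
        rng = random.Random(12)
        net, tree, idx, ic, views = self.run_sequence(rng, steps=8)
        view = views[-1]
        guard = 0
        while view.meta_nodes != {tree.root}:
            target = next(
                iter(sorted(view.atomic_nodes) + sorted(view.meta_nodes - {tree.root}))
            )
            view = zoom_out(view, target, tree, idx)
            guard += 1
            assert guard <= len(tree.communities) + len(tree.node_set)
        assert view == initial_view(tree)

    def test_edge_count_conservation(self):
        """Underlying-edge counts across view edges plus edges hidden inside
        frontier containers add up to |E|."""
        rng = random.Random(13)
        for _ in range(10):
            net, tree, idx, ic, views = self.run_sequence(rng)
            for view in views:
                total = 0
                for e in view.edges:
                    if e.family == PROTEIN_PROTEIN:
                        total += 1
                    else:
                        total += meta_edge_stats(e, view, tree, idx, net).count
                for c in view.meta_nodes:
                    total += net.induced_subgraph(tree[c].members).number_of_edges()
                assert total == net.number_of_edges()


class TestPathToNode:
    def test_navigation_example_path(self, nav):
        net, tree, idx, ic = nav
        assert path_to_node("DET1", tree, idx) == ["root", "C4", "C7"]

    def test_path_endpoints_and_parent_links(self, nav):
        net, tree, idx, ic = nav
        for v in sorted(tree.node_set):
            path = path_to_node(v, tree, idx)
            assert path[0] == tree.root
            assert v in tree[path[-1]].members
            assert tree[path[-1]].is_leaf
            for a, b in zip(path, path[1:]):
                assert tree.parent(b) == a

    def test_unknown_node_rejected(self, nav):
        net, tree, idx, ic = nav
        with pytest.raises(KeyError):
            path_to_node("ghost", tree, idx)


class TestMetaEdgeStats:
    def test_protein_protein_edge_is_singleton(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        v = zoom_in(v, "C7", tree, idx, ic, net)
        e = ViewEdge("DET1", "SOC1", PROTEIN_PROTEIN)
        s = meta_edge_stats(e, v, tree, idx, net)
        assert s == (1, 0.6, 0.6, 0.6)

    def test_community_pair_stats_enumerate_underlying_weights(self):
        from commnav.hierarchy import CommunityTree
        from commnav.network import ProteinNetwork

        tree = CommunityTree.from_nested(
            {
                "id": "root",
                "children": [
                    {"id": "L", "members": ["a", "b"]},
                    {"id": "R", "members": ["x", "y"]},
                ],
            }
        )
        net = ProteinNetwork(
            [("a", "x", 0.2), ("a", "y", 0.4), ("b", "x", 0.6), ("a", "b", 1.0)]
        )
        idx = assign_tree_indexes(tree)
        ic = build_relation_index(tree, idx, net)
        v = level1_view(tree, idx, ic, net)
        s = meta_edge_stats(ViewEdge("L", "R", COMMUNITY_COMMUNITY), v, tree, idx, net)
        assert s.count == 3
        assert s.min_w == pytest.approx(0.2)
        assert s.max_w == pytest.approx(0.6)
        assert s.mean_w == pytest.approx(0.4)

    def test_stats_count_conserved_across_zoom_in(self, nav):
        net, tree, idx, ic = nav
        v1 = level1_view(tree, idx, ic, net)
        before = meta_edge_stats(
            ViewEdge("C1", "C4", COMMUNITY_COMMUNITY), v1, tree, idx, net
        )
        v2 = zoom_in(v1, "C4", tree, idx, ic, net)
        after = sum(
            meta_edge_stats(e, v2, tree, idx, net).count
            for e in v2.edges
            if "C1" in (e.u, e.v)
        )
        assert after == before.count

    def test_absent_edge_rejected(self, nav):
        net, tree, idx, ic = nav
        v = initial_view(tree)
        with pytest.raises(ValueError, match="absent"):
            meta_edge_stats(ViewEdge("C1", "C4", COMMUNITY_COMMUNITY), v, tree, idx, net)


class TestViewSerialization:
    def test_schema_and_determinism(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        v = zoom_in(v, "C7", tree, idx, ic, net)
        doc = json.loads(view_to_json(v, tree, idx, net, with_stats=True))
        assert {m["id"] for m in doc["meta_nodes"]} == {"C1", "C5", "C6"}
        assert {a["id"] for a in doc["atomic_nodes"]} == {"DET1", "SOC1", "d3"}
        for e in doc["edges"]:
            assert e["family"] in (
                PROTEIN_PROTEIN,
                COMMUNITY_COMMUNITY,
                PROTEIN_COMMUNITY,
            )
            assert e["stats"]["count"] >= 1
        assert view_to_json(v, tree, idx, net) == view_to_json(v, tree, idx, net)

    def test_scores_carried_through(self, nav):
        net, tree, idx, ic = nav
        v = level1_view(tree, idx, ic, net)
        v = zoom_in(v, "C4", tree, idx, ic, net)
        v = zoom_in(v, "C7", tree, idx, ic, net)
        doc = json.loads(view_to_json(v, tree, idx, scores={"DET1": 0.97}))
        rec = next(a for a in doc["atomic_nodes"] if a["id"] == "DET1")
        assert rec["score"] == 0.97
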