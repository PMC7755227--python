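# commnav

Multi-resolution community detection and navigation for weighted
biomolecular networks.

Protein–protein interaction and functional-association networks are too
large to inspect flat.  `commnav` organizes such a network into a
hierarchy of nested communities and lets you navigate it the way a map
viewer navigates geography: start from a single meta-node covering the
whole network, zoom into a community to reveal its sub-communities (or,
at the bottom, its proteins), and zoom back out — while the tool keeps
every intermediate view consistent with the underlying interactions.

It is intended for computational biologists and tool builders who need
the community engine behind an interactive network browser: detection,
indexing, view transformation, and export, all headless, deterministic
and scriptable.

## What it computes

* **Divisive hierarchical Louvain.**  The Louvain method partitions the
  network G = (V, E) into level-1 communities (only the final,
  highest-modularity partition of each run is kept).  Every community
  with at least `minsplit` members whose induced subgraph G_c admits a
  non-trivial Louvain partition with modularity

      Q = (1/2m) Σ_ij [ W_ij − k_i k_j / 2m ] δ(c_i, c_j)  >  0

  is split again, recursively.  The leaves of the resulting community
  tree partition V.

* **Interval indexes.**  Each community gets (pre, post, level) labels
  from one depth-first traversal, making ancestry, disjointness and
  membership queries constant-time: c1 ∈ desc(c2) ⇔ pre(c2) ≤ pre(c1)
  and post(c1) ≤ post(c2).

* **Community-relation index.**  A two-phase O(|E| + |V_C|²) pass
  records every pair of disjoint communities joined by at least one
  network edge — the data structure that makes zooming fast.

* **Zoom algebra.**  `zoom_in` replaces a meta-node by its children or
  member proteins; `zoom_out` collapses everything inside the enclosing
  community back into one meta-node.  Every view keeps three edge
  families (protein–protein, protein–community, community–community)
  exactly consistent with E, and `zoom_out` undoes `zoom_in`.

* **Exports.**  Community sub-networks (TSV or JSON, with optional
  prediction scores and translation among seven protein identifier
  schemes) and the "maptree" hierarchy overview (JSON or Newick).

* **Synthetic benchmarks.**  A hierarchical planted-partition generator
  with known ground truth, used to validate recovery end to end.

## Worked example

Generate a 120-protein benchmark with 2 × 2 planted blocks of 30, build
its hierarchy, and replay a navigation session:

```
$ commnav simulate --kind planted --seed 7 --out sim
wrote 120 nodes / 967 edges to sim

$ commnav detect --network sim/network.tsv --nodes sim/nodes.txt \
      --minsplit 50 --seed 11 --out run
levels: 1
communities: 4
leaves: 4
leaf sizes: min 30 / mean 30.0 / max 30
```

The detector recovered the four planted sub-blocks exactly: four leaf
communities of 30 proteins each (at this strong separation Louvain
finds them in one level; `minsplit` 50 then stops further splitting,
since no leaf has 50 members).  Now navigate: expand the root, expand
the first community, and ask for the path to protein `n000`:

```
$ printf 'expand C0\nexpand C1\npath n000\n' > session.txt
$ commnav view --hierarchy run/hierarchy.json --network sim/network.tsv \
      --nodes sim/nodes.txt --script session.txt --out view.json --stats
final view: 3 meta-nodes, 30 proteins, 254 edges
```

`view.json` now holds the mixed-resolution view: meta-nodes C2, C3, C4
(the three unexpanded communities), the 30 proteins of C1 as atomic
nodes, and 254 edges across the three families.  Each community-level
edge carries the count and min/mean/max weight of the interactions
behind it, e.g. the C2–C3 edge summarizes its single underlying
interaction of weight 0.205.  The recorded path for `n000` is
`["C0", "C1"]` — root, then its leaf community.

Export that community (with identifier translation if a mapping table
is available):

```
$ commnav export --hierarchy run/hierarchy.json --network sim/network.tsv \
      --nodes sim/nodes.txt --community C1 --format tsv --out C1/
```

The same operations are available as a library:

```python
from commnav import (build_hierarchy, assign_tree_indexes,
                     build_relation_index, initial_view, zoom_in)

tree = build_hierarchy(net, minsplit=50, seed=11)
idx = assign_tree_indexes(tree)
ic = build_relation_index(tree, idx, net)
view = zoom_in(initial_view(tree), tree.root, tree, idx, ic, net)
```

See `docs/methods.md` for the model, its assumptions and parameter
guidance.

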