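# Methods

## Problem setting

Protein–protein interaction and functional-association networks with
thousands of nodes cannot be inspected flat: any single rendering either
hides structure (too coarse) or drowns it (too fine).  `commnav`
implements the computational core of multi-resolution network
navigation: a divisive hierarchy of non-overlapping communities, index
structures that make ancestry queries on that hierarchy constant-time,
a precomputed community-relation index, and a zoom algebra that turns
the hierarchy into navigable mixed-resolution views.

The input is a weighted undirected graph G = (V, E) with a symmetric
weight matrix W, W_ij ∈ (0, 1], W_ij = 0 meaning "no edge".  Node
identifiers are opaque case-sensitive strings; no identifier-scheme
inference is attempted.

## Divisive hierarchical community detection

Communities are detected with a top-down extension of the Louvain
modularity heuristic.  One Louvain invocation on G yields the level-1
partition; only the final (highest-modularity) partition of the run is
kept, never the intermediate vertex-moving dendrogram, because the
intermediate levels are dominated by singletons at the bottom and by
oversized aggregates at the top.  Each community c is then considered
for a further split:

* it must have at least `minsplit` members, and
* the Louvain partition of the induced subgraph G_c (internal edges
  only) must be non-trivial (≥ 2 parts) with strictly positive
  modularity on G_c.

The second condition is the *gain* test: the trivial single-community
partition scores exactly Q = 0, so Q > 0 means the split strictly
improves local modularity.  Qualifying communities are replaced by
their sub-partition and the loop continues on a FIFO worklist until no
community qualifies.  The result is a rooted tree whose leaves
partition V; internal non-root communities always have ≥ minsplit
members, ≥ 2 children and positive children-partition modularity —
these are enforced invariants, not tendencies.

Weighted modularity is the Newman–Girvan quality

    Q = (1/2m) Σ_ij [ W_ij − k_i k_j / 2m ] δ(c_i, c_j)

with m the total edge weight and k_i the weighted degree.  Edge
weights always participate: W is central to the data model, so the
unweighted special case is just W_ij = 1.

**Parameters.** `minsplit` (default 50, dimensionless node count) is
the only structural knob.  50 suits networks of a few hundred to a few
thousand nodes; for networks beyond ~15k nodes several hundred is more
appropriate, since leaf communities are meant to be small enough to
display but large enough to be meaningful.  `seed` drives the Louvain
node-visit order; identical (network, minsplit, seed) produce a
byte-identical hierarchy.  Sub-seeds for recursive Louvain invocations
are derived from the master seed by a Knuth-style multiplicative hash
of the invocation counter in breadth-first discovery order.

**Backend.** The Louvain optimiser is
`networkx.community.louvain_communities`, which accepts a seed and is
deterministic given one.  The package's own modularity implementation
(needed by the gain test) is cross-checked against
`networkx.community.modularity` in the test suite, and Louvain outputs
are cross-checked against exhaustive set-partition enumeration on small
graphs.

**Degenerate inputs.** Empty and edgeless networks are rejected
(modularity is undefined at m = 0).  Isolated nodes inside an otherwise
connected network survive as their own level-1 singleton communities,
preserving the partition invariant.  A disconnected induced subgraph is
split normally if its Louvain partition passes the gain test.

**Depth.** The recursion shrinks communities geometrically, so the tree
depth stays small in practice (single digits on every fixture in the
suite; an Erdős–Rényi graph with 10⁴ nodes and 10⁵ edges yields depth
≈ 3 at minsplit 50).

## Interval labels and constant-time predicates

Each community receives a (pre, post, level) triple from one
depth-first traversal in stored child order; `pre` is numbered on
entry, `post` on exit, each by its own counter starting at 1 (any
consistent convention satisfies the interval property; separate
counters read most simply).  Each protein carries the (pre, post) pair
of its leaf community.  Then

    c1 ∈ desc(c2)  ⇔  pre(c2) ≤ pre(c1) ∧ post(c1) ≤ post(c2)

and disjointness (`neither contains the other`), leaf lookup
(`class(v)`), and membership (`v ∈ c ⇔ class(v) ∈ desc(c)`) are all
O(1) dictionary-and-compare operations.

`desc` is deliberately **reflexive**.  The relation-index construction
pairs a leaf with a disjoint internal community by requiring a
connected leaf pair below both sides; the leaf side can only be
witnessed by itself, which strict descent would forbid.

Edges are canonically oriented so the endpoint whose leaf community has
the smaller pre-order label comes first; ties (both endpoints in the
same leaf) break lexicographically by node id.

## Community-relation index (IC)

IC records every disjoint community pair joined by at least one network
edge.  Construction is two-phase:

1. scan each edge once; when its endpoints' leaf communities differ,
   record that leaf pair (set Ē_I);
2. derive the upper pairs (disjoint, not both leaves, ordered by
   pre-label) as exactly those with some connected leaf pair below both
   sides (set E_I).

Phase 2 never touches the edge set: connectivity is propagated from the
leaf pairs up the (short) ancestor chains and then read off while
enumerating community pairs, keeping the work at O(|E| + |V_C|²).  Both
counts are recorded on the returned index and asserted in tests
(`edge_inspections == |E|`, `pair_inspections ≤ |V_C|²`).  The
symmetric relation is stored once per pair with the lower-pre
representative first.  A brute-force oracle (every community pair ×
every edge, by raw member sets) confirms exact equality on randomized
instances.

## Views and the zoom algebra

A view G_L mixes meta-nodes (pairwise disjoint communities) and atomic
nodes (proteins not inside any displayed meta-node); its frontier —
meta-node member sets plus atomic nodes — partitions V after every
reachable operation, and its three edge families (protein–protein,
protein–community, community–community) are exactly those induced by E
on the frontier.  Views are immutable values; zoom operations return
new views, which makes inversion testable and undo trivial.

The initial view is the root meta-node alone with no edges; a
convenience (`level1_view`) applies one zoom on the root to produce the
level-1 screen a front-end would show first.  Both entry points are
exposed rather than blessing either as canonical.

**zoom_in(c)** replaces meta-node c by its children (internal c) or its
member proteins (leaf c).  Child–child and child–meta edges come from
the relation index, which is authoritative for community pairs;
protein-level edges are re-derived from E, restricted to view vertices
previously adjacent to c (correct because edge-correct views already
connect c to every vertex with an underlying link into it).  The
implementation touches each network edge at most once per call — the
complexity guard counter in the test suite asserts this.  Locating the
frontier vertex containing an arbitrary neighbour walks leaf-to-root
parent pointers, bounded by the (small) tree depth.

**zoom_out(x)** collapses the community c_p enclosing x: the leaf
class(x) when x is a protein, parent(x) when x is a meta-node.  The
collapse group is *every* view vertex whose members lie inside c_p —
sibling meta-nodes, atomic members, and also vertices exposed by deeper
zooms below a sibling.  Collapsing only the immediate siblings would
strand those deeper vertices inside the new meta-node and break the
frontier partition; absorbing the whole subtree is the unique
generalization that preserves it, and it coincides with sibling-only
collapse whenever no deeper expansion exists (in particular,
zoom_out ∘ zoom_in = identity, property-tested).  Leaves are atomic
units: a leaf's proteins expand and collapse together, so a partially
expanded leaf cannot arise.

**Edge statistics.** Every community-level view edge summarizes the
multiset of underlying edge weights: count, min, max, mean.  Counts are
conserved under zoom (the count behind (c, c̄) equals the summed counts
of the child-level edges replacing it), asserted as a property test.

**path_to_node(v)** returns the unique root → class(v) community chain,
supporting search-and-drill navigation.

## Exporters

Community export produces the induced sub-network of a community as
JSON (versioned schema) or as a two-file TSV layout (`edges.tsv` +
`nodes.tsv`); the two-file form preserves isolated members and carries
optional per-protein prediction scores.  Identifier translation into
any of seven schemes (gene name, Ensembl gene/protein, Entrez, RefSeq
protein/mRNA, UniProt) is order-preserving with pass-through for
unmapped ids.  The maptree export serializes the hierarchy as nested
JSON or Newick (labels sanitized; `[size=N]` comments opt-in).

## Synthetic benchmarks

The planted generator emulates what the detector exploits in real
interactomes — assortative, hierarchically nested modules — and nothing
else: node pairs connect independently with a probability set by the
depth of their lowest common ancestor block (deeper ⇒ denser), and
weights are drawn independently of block structure, uniform on (0, 1].
It does not reproduce heavy-tailed degree distributions, hubs,
overlapping modules, or weight–topology correlation, so recovery
results certify the pipeline's correctness on its own model class, not
performance on real interactomes.

Default study conditions: 2 super-blocks × 2 sub-blocks of 30 nodes
(120 nodes), p = 0.5 within a leaf block, 0.05 within a super-block,
0.005 across super-blocks — a strongly separated regime where the leaf
blocks are unambiguous.  Under these conditions the detector's leaves
match the planted sub-blocks with adjusted Rand index ≥ 0.9 in at
least 8 of 10 seeds (observed: 10 of 10, mean ARI ≈ 1.0).  A
near-flat-probability control shows ARI ≈ 0, confirming the benchmark
is not trivially passable.

An Erdős–Rényi generator (`fast_gnp` sampling plus uniform weights)
provides structure-free graphs for determinism, scale and counter
tests.  The scale check in the test suite runs detection plus full
index construction on a 10⁴-node, ~10⁵-edge random graph (observed
well under a minute on one CPU; asserted under five).

## Numerical and design notes

* Weights are written with `repr` (shortest round-trip form), so
  read(write(net)) == net exactly, including float edge cases.
* Louvain community label assignment, child ordering (by smallest
  member id) and JSON serialization (sorted keys, fixed separators) are
  all deterministic, giving byte-identical artifacts across reruns.
* Explicit zero-weight edges are rejected rather than dropped: an
  explicit 0 contradicts "absent ⇔ 0" and most likely flags an upstream
  error.
* Duplicate edge records are rejected even when consistent, so a file
  containing both (a, b) and (b, a) fails loudly.
* The modularity "gain" test compares against Q = 0 with a strict
  inequality; a split that merely ties the trivial partition is not
  applied.

## Known limitations

* Louvain is a heuristic: the hierarchy is a local optimum and can
  differ across seeds on weakly modular graphs; only determinism at
  fixed seed is guaranteed.
* The relation index is rebuilt, not incrementally updated; edits to
  the network require a full re-index (cheap at the intended scales).
* Balanced planted trees only; no degree-corrected or overlapping-block
  benchmark generators.
* No rendering, layout or interactive front-end: the session-script
  replay in the CLI is the navigation surface.
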