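"""Weighted undirected protein-network model and tuple-format I/O.

A network is a set of proteins (opaque string identifiers) plus a set of
weighted undirected edges with weights in (0, 1].  The on-disk "network
tuple format" is a headerless TSV of ``node1 <tab> node2 [<tab> weight]``
rows; a missing weight column means a unitary edge (weight 1.0).  Isolated
proteins cannot be expressed in the tuple format, so an optional node-list
file (one identifier per line) may accompany it.

ID translation between identification schemes (gene name, Ensembl,
Entrez, RefSeq, UniProt) is handled by :class:`IDMappingTable`; an
identifier with no correspondence in the requested scheme passes through
unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NetworkFormatError",
    "ProteinNetwork",
    "IDMappingTable",
    "ID_SCHEMES",
    "read_network_tsv",
    "write_network_tsv",
    "read_mapping_tsv",
    "translate_ids",
]


class NetworkFormatError(ValueError):
    """Raised for malformed tuple-format input or invariant violations."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    """Unordered pair as a lexicographically ordered tuple."""
    return (u, v) if u <= v else (v, u)


class ProteinNetwork:
    """Undirected weighted graph G = (V, E) with weights W in (0, 1].

    Edges are stored once per unordered pair; an absent pair is weight 0.
    Self-loops are rejected, as are weights outside (0, 1] (an explicit
    zero weight contradicts "absent pair <=> weight 0").
    """

    def __init__(
        self,
        edges: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self._edges: dict[tuple[str, str], float] = {}
        for n in nodes:
            self._adj.setdefault(str(n), {})
        items = edges.items() if isinstance(edges, Mapping) else ()
        triples = (
            ((u, v, w) for (u, v), w in items)
            if isinstance(edges, Mapping)
            else iter(edges)
        )
        for u, v, w in triples:
            self.add_edge(str(u), str(v), float(w))

    def add_edge(self, u: str, v: str, w: float = 1.0) -> None:
        if u == v:
            raise NetworkFormatError(f"self-loop on node {u!r}")
        if not (0.0 < w <= 1.0):
            raise NetworkFormatError(
                f"edge ({u!r}, {v!r}) has weight {w}; weights must lie in (0, 1]"
            )
        key = _canonical(u, v)
        if key in self._edges and self._edges[key] != w:
            raise NetworkFormatError(
                f"duplicate edge record for pair ({u!r}, {v!r}) with conflicting weights"
            )
        if key in self._edges:
            raise NetworkFormatError(f"duplicate edge record for pair ({u!r}, {v!r})")
        self._edges[key] = w
        self._adj.setdefault(u, {})[v] = w
        self._adj.setdefault(v, {})[u] = w

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Canonical unordered pair -> weight (a copy)."""
        return dict(self._edges)

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return len(self._edges)

    def has_node(self, v: str) -> bool:
        return v in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical(u, v) in self._edges

    def weight(self, u: str, v: str) -> float:
        """W_uv; 0.0 when the pair is absent."""
        return self._edges.get(_canonical(u, v), 0.0)

    def adjacency(self, v: str) -> dict[str, float]:
        return self._adj[v]

    def neighbors(self, v: str) -> Iterable[str]:
        return self._adj[v].keys()

    def weighted_degree(self, v: str) -> float:
        return sum(self._adj[v].values())

    def total_weight(self) -> float:
        """m = sum of all edge weights (each unordered edge once)."""
        return sum(self._edges.values())

    def induced_subgraph(self, members: Iterable[str]) -> "ProteinNetwork":
        """Subgraph on ``members`` keeping internal edges only."""
        keep = set(members)
        sub = ProteinNetwork(nodes=keep)
        for (u, v), w in self._edges.items():
            if u in keep and v in keep:
                sub.add_edge(u, v, w)
        return sub

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self._adj))
        for (u, v), w in sorted(self._edges.items()):
            g.add_edge(u, v, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ProteinNetwork(|V|={self.number_of_nodes()}, "
            f"|E|={self.number_of_edges()})"
        )


# -- ID mapping ----------------------------------------------------------

ID_SCHEMES = (
    "gene_name",
    "ensembl_gene",
    "ensembl_protein",
    "entrez",
    "refseq_protein",
    "refseq_mrna",
    "uniprot",
)

_MAPPING_COLUMNS = ("primary_id", *ID_SCHEMES, "aliases")


@dataclass
class IDMappingTable:
    """Primary identifier -> alternative identifiers in seven schemes.

    Missing alternatives are stored as ``None``; aliases are free-form
    synonyms not tied to any scheme.
    """

    rows: dict[str, dict[str, str | None]] = field(default_factory=dict)
    aliases: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def lookup(self, primary: str, scheme: str) -> str | None:
        rec = self.rows.get(primary)
        return rec.get(scheme) if rec else None


def translate_ids(
    ids: Sequence[str], mapping: IDMappingTable, scheme: str
) -> list[str]:
    """Translate identifiers into ``scheme``, order-preserving.

    Identifiers with no correspondence in the requested scheme are kept
    as-is (the primary identifier is used when no mapping exists).
    """
    if scheme not in ID_SCHEMES:
        raise ValueError(
            f"unknown id scheme {scheme!r}; valid schemes: {', '.join(ID_SCHEMES)}"
        )
    out = []
    for i in ids:
        alt = mapping.lookup(i, scheme)
        out.append(alt if alt else i)
    return out


def read_mapping_tsv(path: str | Path) -> IDMappingTable:
    """Read an ID-mapping table (TSV with header; empty cell = missing)."""
    table = IDMappingTable()
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "primary_id":
            raise NetworkFormatError(
                "mapping file must start with a header whose first column is primary_id"
            )
        col_of = {name: k for k, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            primary = cells[col_of["primary_id"]]
            if primary in table.rows:
                raise NetworkFormatError(
                    f"line {lineno}: duplicate primary id {primary!r}"
                )
            rec: dict[str, str | None] = {}
            for scheme in ID_SCHEMES:
                k = col_of.get(scheme)
                val = cells[k] if k is not None and k < len(cells) else ""
                rec[scheme] = val or None
            table.rows[primary] = rec
            ka = col_of.get("aliases")
            raw = cells[ka] if ka is not None and ka < len(cells) else ""
            table.aliases[primary] = tuple(a for a in raw.split("|") if a)
    return table


# -- tuple-format I/O ----------------------------------------------------


def read_network_tsv(
    path: str | Path,
    node_file: str | Path | None = None,
    header: bool = False,
) -> ProteinNetwork:
    """Parse a network tuple-format TSV into a :class:`ProteinNetwork`.

    Each line is ``node1 <tab> node2 [<tab> weight]``; the weight defaults
    to 1.0.  ``(a, b)`` and ``(b, a)`` denote the same edge and duplicate
    records are rejected.  ``node_file`` optionally declares extra
    (possibly isolated) nodes, one identifier per line.
    """
    net = ProteinNetwork()
    with open(path, "rt", encoding="utf-8") as fh:
        lines = iter(enumerate(fh, start=1))
        if header:
            next(lines, None)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise NetworkFormatError(
                    f"line {lineno}: expected 2 or 3 tab-separated columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise NetworkFormatError(f"line {lineno}: empty node identifier")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"line {lineno}: weight {parts[2]!r} is not a number"
                    ) from exc
            else:
                w = 1.0
            try:
                net.add_edge(u, v, w)
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"line {lineno}: {exc}") from exc
    if node_file is not None:
        with open(node_file, "rt", encoding="utf-8") as fh:
            extra = [ln.strip() for ln in fh if ln.strip()]
        return ProteinNetwork(net.edges, nodes=net.nodes | set(extra))
    return net


def canonical_edge_order(
    net: ProteinNetwork, idx=None
) -> list[tuple[str, str, float]]:
    """Edges as (first, second, weight) in canonical order.

    With a tree index, endpoints are oriented so the pre-order label of
    the first endpoint's leaf community is the lower one (ties within a
    leaf broken lexicographically by node id) and edges sorted by those
    labels; without an index the order is lexicographic.
    """
    rows = []
    for (u, v), w in net.edges.items():
        if idx is not None:
            pu, pv = idx.node_pre(u), idx.node_pre(v)
            if (pu, u) > (pv, v):
                u, v = v, u
            rows.append(((idx.node_pre(u), u, idx.node_pre(v), v), (u, v, w)))
        else:
            rows.append(((u, v), (u, v, w)))
    rows.sort(key=lambda r: r[0])
    return [r[1] for r in rows]


def write_network_tsv(
    net: ProteinNetwork,
    path: str | Path,
    mapping: IDMappingTable | None = None,
    scheme: str | None = None,
    idx=None,
) -> None:
    """Write a network in tuple format, optionally translating ids.

    When ``scheme`` is given a ``mapping`` is required; identifiers
    lacking a correspondence keep their primary id.
    """
    if scheme is not None and mapping is None:
        raise ValueError("an id mapping table is required when a scheme is requested")

    def tr(i: str) -> str:
        if scheme is None:
            return i
        return translate_ids([i], mapping, scheme)[0]

    buf = io.StringIO()
    for u, v, w in canonical_edge_order(net, idx):
        buf.write(f"{tr(u)}\t{tr(v)}\t{w!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_node_list(net: ProteinNetwork, path: str | Path) -> None:
    """Write the node set, one id per line (preserves isolated nodes)."""
    Path(path).write_text(
        "".join(f"{n}\n" for n in sorted(net.nodes)), encoding="utf-8"
    )
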