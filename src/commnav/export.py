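"""Exporters: community sub-networks and the maptree hierarchy overview.

A community export is the induced sub-network on the community's member
set, as either JSON (one self-describing document) or TSV (an
``edges.tsv`` plus a ``nodes.tsv``, the two-file layout preserving
isolated members and optional per-node prediction scores).  The maptree
export serializes the whole hierarchy as nested JSON or as a Newick
string.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .hierarchy import CommunityTree
from .network import IDMappingTable, ProteinNetwork, translate_ids

__all__ = [
    "export_community",
    "write_community_export",
    "export_maptree",
]


def export_community(
    c: str,
    tree: CommunityTree,
    net: ProteinNetwork,
    format: str = "json",
    scores: dict[str, float] | None = None,
    mapping: IDMappingTable | None = None,
    scheme: str | None = None,
) -> dict[str, str] | str:
    """Induced sub-network of community ``c`` as file content.

    Returns the JSON document as a string for ``format="json"``, or a
    dict ``{"edges.tsv": ..., "nodes.tsv": ...}`` for ``format="tsv"``.
    Node ids are translated into ``scheme`` when a mapping is supplied;
    ids with no correspondence keep their primary form.
    """
    if c not in tree:
        raise KeyError(f"unknown community {c!r}")
    if format not in ("json", "tsv"):
        raise ValueError(f"unknown export format {format!r} (use json or tsv)")

    members = sorted(tree[c].members)

    def tr(i: str) -> str:
        if scheme is None:
            return i
        if mapping is None:
            raise ValueError("id translation requires a mapping table")
        return translate_ids([i], mapping, scheme)[0]

    sub = net.induced_subgraph(members)
    edge_rows = [(tr(u), tr(v), w) for (u, v), w in sorted(sub.edges.items())]
    node_rows = []
    for v in members:
        rec: dict = {"id": tr(v)}
        if scores is not None and v in scores:
            rec["score"] = scores[v]
        node_rows.append(rec)

    if format == "json":
        payload = {
            "schema_version": 1,
            "community": c,
            "level": tree[c].level,
            "nodes": node_rows,
            "edges": [{"u": u, "v": v, "weight": w} for u, v, w in edge_rows],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"

    edges_tsv = "".join(f"{u}\t{v}\t{w!r}\n" for u, v, w in edge_rows)
    has_scores = scores is not None
    lines = ["id\tscore\n" if has_scores else "id\n"]
    for rec in node_rows:
        if has_scores:
            lines.append(f"{rec['id']}\t{rec.get('score', '')}\n")
        else:
            lines.append(f"{rec['id']}\n")
    return {"edges.tsv": edges_tsv, "nodes.tsv": "".join(lines)}


def write_community_export(content: dict[str, str] | str, out: str | Path) -> None:
    """Write an export to disk: a file for JSON, a directory for TSV."""
    out = Path(out)
    if isinstance(content, str):
        out.write_text(content, encoding="utf-8")
    else:
        out.mkdir(parents=True, exist_ok=True)
        for name, text in content.items():
            (out / name).write_text(text, encoding="utf-8")


_NEWICK_UNSAFE = re.compile(r"[\s()\[\],:;']")


def _sanitize(label: str) -> str:
    return _NEWICK_UNSAFE.sub("_", label)


def export_maptree(
    tree: CommunityTree, format: str = "json", include_sizes: bool = False
) -> str:
    """Whole-hierarchy overview as nested JSON or a Newick string.

    JSON nodes carry ``{id, level, size, children}``.  Newick labels are
    the community ids (sanitized); with ``include_sizes`` each label is
    followed by a ``[size=N]`` comment.
    """
    if format == "json":

        def node(cid: str) -> dict:
            c = tree[cid]
            return {
                "id": cid,
                "level": c.level,
                "size": c.size,
                "children": [node(k) for k in c.children],
            }

        return (
            json.dumps(
                {"schema_version": 1, "maptree": node(tree.root)},
                sort_keys=True,
                separators=(",", ":"),
            )
            + "\n"
        )
    if format == "newick":

        def nwk(cid: str) -> str:
            c = tree[cid]
            label = _sanitize(cid)
            if include_sizes:
                label += f"[size={c.size}]"
            if c.is_leaf:
                return label
            return "(" + ",".join(nwk(k) for k in c.children) + ")" + label

        return nwk(tree.root) + ";"
    raise ValueError(f"unknown maptree format {format!r} (use json or newick)")


def maptree_from_json(text: str) -> CommunityTree:
    """Rebuild a (member-less) topology check tree from a maptree JSON.

    Only topology, ids and levels are recoverable; member sets are not
    part of the maptree schema, so leaves get synthetic placeholder
    members sized to match.  Intended for round-trip/topology tests.
    """
    payload = json.loads(text)["maptree"]

    def to_nested(node: dict) -> dict:
        if node["children"]:
            return {
                "id": node["id"],
                "children": [to_nested(k) for k in node["children"]],
            }
        return {
            "id": node["id"],
            "members": [f"{node['id']}#{i}" for i in range(node["size"])],
        }

    return CommunityTree.from_nested(to_nested(payload))
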