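"""Reading and writing causal graphs and tabular pipeline artifacts.

Canonical interchange is a plain edge-list TSV whose header comments also
carry the node list and tier tags (so isolated nodes and the
instrument/trait distinction round-trip). GraphML (via networkx) round-trips
too; DOT is a write-only export for rendering.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .graph import TRAIT, CausalGraph


class GraphParseError(ValueError):
    """Malformed graph file; message carries the line number."""


def write_graph(graph: CausalGraph, path: str | Path, fmt: str | None = None) -> None:
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(graph, path)
    elif fmt == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    elif fmt == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unrecognized graph format {fmt!r}")


def read_graph(path: str | Path, fmt: str | None = None) -> CausalGraph:
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        tiers = {n: d.get("tier", TRAIT) for n, d in g.nodes(data=True)}
        return CausalGraph(nodes=tiers, edges=list(g.edges()))
    if fmt == "dot":
        raise ValueError("DOT is a write-only export format; use TSV or GraphML")
    raise ValueError(f"unrecognized graph format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"tsv": "tsv", "txt": "tsv", "graphml": "graphml", "dot": "dot", "gv": "dot"}.get(
        suffix, "tsv"
    )


def _write_tsv(graph: CausalGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in graph.nodes():
            fh.write(f"#node\t{node}\t{graph.tier(node)}\n")
        fh.write("source\ttarget\n")
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


def _read_tsv(path: str | Path) -> CausalGraph:
    nodes: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#node\t"):
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphParseError(f"{path}:{lineno}: bad node line {line!r}")
            nodes[parts[1]] = parts[2]
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[:2] == ["source", "target"]:
            header_seen = True
            continue
        if len(parts) < 2:
            raise GraphParseError(
                f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
            )
        edges.append((parts[0], parts[1]))
    if not header_seen and not nodes and not edges:
        raise GraphParseError(f"{path}:1: empty or unrecognized edge-list file")
    for u, v in edges:
        nodes.setdefault(u, TRAIT)
        nodes.setdefault(v, TRAIT)
    return CausalGraph(nodes=nodes, edges=edges)


def _write_dot(graph: CausalGraph, path: str | Path) -> None:
    lines = ["digraph causal_network {"]
    for node in graph.nodes():
        shape = "box" if graph.tier(node) == "instrument" else "ellipse"
        lines.append(f'  "{node}" [shape={shape}, tier="{graph.tier(node)}"];')
    for u, v in graph.edges():
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
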