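"""Topology metrics for the learned metabolite network.

Four per-node parameters summarise a node's role:

* ``out_degree`` — number of arrows leaving the node (how many metabolites it
  influences directly);
* ``in_degree`` — number of arrows entering it;
* ``connectivity`` — ``out_degree + in_degree``;
* ``max_effect_blocking_steps`` — the length (edge count) of the longest
  directed path starting at the node, i.e. how far an intervention on the node
  can propagate before every route is blocked at a node with no outgoing
  edges. A sink has 0 steps by definition.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .graph import CausalGraph

METRIC_COLUMNS = [
    "out_degree",
    "in_degree",
    "connectivity",
    "max_effect_blocking_steps",
]


def _as_digraph(graph: CausalGraph | nx.DiGraph) -> nx.DiGraph:
    return graph.to_networkx() if isinstance(graph, CausalGraph) else graph


def max_effect_blocking_steps(graph: CausalGraph | nx.DiGraph, node: str) -> int:
    """Longest directed path length (in edges) starting at ``node``.

    Computed by the Bellman recursion ``steps(v) = 1 + max(steps(c))`` over
    children ``c`` (0 for a sink), evaluated in reverse topological order.
    Raises on cyclic input, where the quantity is undefined.
    """
    return all_effect_blocking_steps(graph)[node]


def all_effect_blocking_steps(graph: CausalGraph | nx.DiGraph) -> dict[str, int]:
    """Longest outgoing path length for every node, in one topological sweep."""
    g = _as_digraph(graph)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("effect blocking steps require an acyclic graph") from exc
    steps: dict[str, int] = {}
    for v in reversed(order):
        succ = list(g.successors(v))
        steps[v] = 1 + max(steps[c] for c in succ) if succ else 0
    return steps


def influence_set(graph: CausalGraph | nx.DiGraph, nodes: Iterable[str]) -> set[str]:
    """Union of strict descendants of the query nodes (everything they reach)."""
    g = _as_digraph(graph)
    query = list(nodes)
    for n in query:
        if n not in g:
            raise KeyError(f"unknown node {n!r}")
    out: set[str] = set()
    for n in query:
        out |= nx.descendants(g, n)
    return out


def metrics_table(graph: CausalGraph | nx.DiGraph) -> pd.DataFrame:
    """Per-node network parameters as a table (index = node name).

    Columns: out_degree, in_degree, connectivity, max_effect_blocking_steps.
    Row order follows node insertion order so a fixture graph built in table
    order prints in table order.
    """
    g = _as_digraph(graph)
    steps = all_effect_blocking_steps(g)
    rows = {
        n: (
            g.out_degree(n),
            g.in_degree(n),
            g.out_degree(n) + g.in_degree(n),
            steps[n],
        )
        for n in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)
    df.index.name = "metabolite"
    return df


def write_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="metabolite")
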