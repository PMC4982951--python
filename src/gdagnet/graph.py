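"""Directed causal graphs over named nodes with a two-tier structure.

The central object of the pipeline is a directed acyclic graph whose nodes
are tagged as either ``instrument`` (genome-wide principal components, which
are exogenous by construction: inherited genotype variation can influence a
phenotype but not vice versa) or ``trait`` (the measured metabolites).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

INSTRUMENT = "instrument"
TRAIT = "trait"
_TIERS = (INSTRUMENT, TRAIT)


class GraphInvariantError(ValueError):
    """Raised when a graph violates the two-tier acyclicity contract."""


class CausalGraph:
    """A directed acyclic graph with an ``instrument``/``trait`` tier per node.

    Invariants enforced by :meth:`validate` (called on construction):

    * no directed cycles;
    * no edge points into an instrument node (instruments are exogenous);
    * no edge joins two instrument nodes.

    A list of residual *undirected* edges may be carried during structure
    learning; it is empty in any final output.

    Parameters
    ----------
    nodes
        Mapping from node name to tier, or an iterable of names (all traits).
    edges
        Iterable of ``(source, target)`` pairs. Nodes referenced only in
        ``edges`` are added as traits.
    undirected
        Residual undirected edges as ``(u, v)`` pairs (order irrelevant).
    """

    def __init__(
        self,
        nodes: Mapping[str, str] | Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
        validate: bool = True,
    ) -> None:
        g = nx.DiGraph()
        if isinstance(nodes, Mapping):
            for name, tier in nodes.items():
                if tier not in _TIERS:
                    raise GraphInvariantError(
                        f"unknown tier {tier!r} for node {name!r}; "
                        f"expected one of {_TIERS}"
                    )
                g.add_node(str(name), tier=tier)
        else:
            for name in nodes:
                g.add_node(str(name), tier=TRAIT)
        for u, v in edges:
            for end in (u, v):
                if end not in g:
                    g.add_node(str(end), tier=TRAIT)
            g.add_edge(str(u), str(v))
        self._g = g
        self.undirected: list[frozenset[str]] = [
            frozenset((str(u), str(v))) for u, v in undirected
        ]
        if validate:
            self.validate()

    # -- container protocol -------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (
            set(self.nodes()) == set(other.nodes())
            and self.tiers() == other.tiers()
            and set(self.edges()) == set(other.edges())
            and set(self.undirected) == set(other.undirected)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CausalGraph({self._g.number_of_nodes()} nodes, "
            f"{self._g.number_of_edges()} edges, "
            f"{len(self.undirected)} undirected)"
        )

    # -- accessors ----------------------------------------------------------

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges)

    def tier(self, node: str) -> str:
        return self._g.nodes[node]["tier"]

    def tiers(self) -> dict[str, str]:
        return {n: d["tier"] for n, d in self._g.nodes(data=True)}

    def trait_nodes(self) -> list[str]:
        return [n for n in self._g.nodes if self.tier(n) == TRAIT]

    def instrument_nodes(self) -> list[str]:
        return [n for n in self._g.nodes if self.tier(n) == INSTRUMENT]

    def parents(self, node: str) -> set[str]:
        return set(self._g.predecessors(node))

    def children(self, node: str) -> set[str]:
        return set(self._g.successors(node))

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the underlying :class:`networkx.DiGraph` (tier node attr)."""
        return self._g.copy()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> "CausalGraph":
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise GraphInvariantError(f"graph contains a directed cycle: {cycle}")
        for u, v in self._g.edges:
            if self.tier(v) == INSTRUMENT:
                raise GraphInvariantError(
                    f"edge {u}->{v} points into instrument node {v!r}"
                )
            if self.tier(u) == INSTRUMENT and self.tier(v) == INSTRUMENT:
                raise GraphInvariantError(
                    f"edge {u}->{v} joins two instrument nodes"
                )
        return self

    # -- derived graphs -----------------------------------------------------

    def trait_subgraph(self) -> "CausalGraph":
        """Induced subgraph on trait nodes (instrument nodes deleted).

        Edges among traits are unchanged; this is the step that turns the
        two-tier genome+metabolite network into the metabolite-only network.
        """
        traits = self.trait_nodes()
        keep = set(traits)
        return CausalGraph(
            nodes={t: TRAIT for t in traits},
            edges=[(u, v) for u, v in self.edges() if u in keep and v in keep],
            undirected=[
                tuple(sorted(e)) for e in self.undirected if e <= keep
            ],
        )

    def copy(self) -> "CausalGraph":
        return CausalGraph(
            nodes=self.tiers(),
            edges=self.edges(),
            undirected=[tuple(sorted(e)) for e in self.undirected],
            validate=False,
        )
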