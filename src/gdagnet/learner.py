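"""Two-tier constraint-based causal structure learning.

The learner recovers a directed network over {selected genome-wide PC
instruments} ∪ {metabolite traits} from conditional-independence tests,
with the genome tier constrained to be exogenous: an edge touching an
instrument can only point away from it, because inherited genotype variation
influences phenotypes and not the other way around. This hard background
knowledge is what turns an otherwise only partially identifiable Markov
equivalence class into a (nearly) fully directed graph — the instrumental
variable / Mendelian-randomization anchor.

The procedure is the stable variant of the PC algorithm with tiered
background knowledge:

1. **Skeleton.** Starting from the complete graph minus instrument–instrument
   pairs, remove an edge as soon as some conditioning set drawn from the
   current neighbourhoods (sizes 0..max_cond) renders the pair independent
   under the Fisher-z partial-correlation test. Separation sets are recorded.
2. **Orientation.** Instrument–trait edges are directed out of the
   instrument; v-structures are oriented from the separation sets; Meek's
   closure rules propagate orientations without creating cycles or new
   v-structures; any still-undirected trait–trait edge is resolved by a
   deterministic, logged fallback so the final output is a DAG.

An *oracle mode* accepts an exact population covariance matrix instead of
data and declares a pair independent when the partial correlation vanishes —
used to separate algorithmic behaviour from sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import INSTRUMENT, TRAIT, CausalGraph

log = logging.getLogger(__name__)

Pair = frozenset


@dataclass
class SeparationSets:
    """Conditioning sets that separated node pairs removed from the skeleton."""

    sets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def record(self, x: str, y: str, cond: Iterable[str]) -> None:
        self.sets[frozenset((x, y))] = tuple(sorted(cond))

    def get(self, x: str, y: str) -> tuple[str, ...] | None:
        return self.sets.get(frozenset((x, y)))

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.sets


# ---------------------------------------------------------------------------
# conditional-independence tests


def _partial_corr(corr: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0:
        return 0.0
    r = -prec[0, 1] / denom
    return float(np.clip(r, -1.0, 1.0))


class FisherZTest:
    """Gaussian CI test: Fisher z-transform of the partial correlation."""

    def __init__(self, data: pd.DataFrame, alpha: float = 0.001) -> None:
        if data.isna().any().any():
            raise ValueError("CI testing requires complete-case data")
        self.alpha = float(alpha)
        self.names = list(data.columns)
        self._idx = {n: i for i, n in enumerate(self.names)}
        self.n = len(data)
        self.corr = np.corrcoef(data.to_numpy(), rowvar=False)

    def independent(self, x: str, y: str, cond: tuple[str, ...]) -> bool:
        df = self.n - len(cond) - 3
        if df < 0:
            log.warning(
                "skipping CI test %s _||_ %s | %s: n=%d too small", x, y, cond, self.n
            )
            return False  # cannot justify removing the edge
        r = _partial_corr(
            self.corr, self._idx[x], self._idx[y], tuple(self._idx[c] for c in cond)
        )
        if abs(r) >= 1.0:
            return False
        z = np.arctanh(r)
        p = 2.0 * stats.norm.sf(np.sqrt(df) * abs(z))
        return p > self.alpha


class OracleCovarianceTest:
    """Exact CI test from a population covariance: zero partial correlation."""

    def __init__(self, cov: pd.DataFrame, tol: float = 1e-8) -> None:
        self.tol = float(tol)
        self.names = list(cov.columns)
        self._idx = {n: i for i, n in enumerate(self.names)}
        d = np.sqrt(np.diag(cov.to_numpy()))
        self.corr = cov.to_numpy() / np.outer(d, d)

    def independent(self, x: str, y: str, cond: tuple[str, ...]) -> bool:
        r = _partial_corr(
            self.corr, self._idx[x], self._idx[y], tuple(self._idx[c] for c in cond)
        )
        return abs(r) < self.tol


# ---------------------------------------------------------------------------
# skeleton


def estimate_skeleton(
    data: pd.DataFrame | None = None,
    tiers: Mapping[str, str] | None = None,
    alpha: float = 0.001,
    max_cond: int | None = 3,
    cov: pd.DataFrame | None = None,
    oracle_tol: float = 1e-8,
) -> tuple[nx.Graph, SeparationSets]:
    """PC-stable skeleton over instruments and traits.

    Instrument–instrument pairs are excluded a priori (never tested, never
    adjacent). Pass ``cov`` instead of ``data`` for oracle mode, where
    ``max_cond=None`` (unbounded) is the natural choice.
    """
    if (data is None) == (cov is None):
        raise ValueError("provide exactly one of data= or cov=")
    test = FisherZTest(data, alpha) if data is not None else OracleCovarianceTest(cov, oracle_tol)
    names = test.names
    tiers = dict(tiers) if tiers else {n: TRAIT for n in names}
    for n in names:
        tiers.setdefault(n, TRAIT)

    g = nx.Graph()
    g.add_nodes_from(names)
    for x, y in combinations(sorted(names), 2):
        if tiers[x] == INSTRUMENT and tiers[y] == INSTRUMENT:
            continue
        g.add_edge(x, y)
    seps = SeparationSets()

    level = 0
    while True:
        if max_cond is not None and level > max_cond:
            break
        # stable variant: neighbourhoods frozen for the whole level
        adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
        if all(len(adj[v]) - 1 < level for v in g.nodes):
            break
        for x, y in sorted(map(tuple, map(sorted, g.edges()))):
            if not g.has_edge(x, y):
                continue
            removed = False
            for base, other in ((x, y), (y, x)):
                candidates = [v for v in adj[base] if v != other]
                if len(candidates) < level:
                    continue
                for cond in combinations(candidates, level):
                    if test.independent(x, y, cond):
                        g.remove_edge(x, y)
                        seps.record(x, y, cond)
                        log.debug("removed %s - %s | %s", x, y, cond)
                        removed = True
                        break
                if removed:
                    break
        level += 1
    return g, seps


# ---------------------------------------------------------------------------
# orientation


@dataclass
class OrientationResult:
    """A fully directed graph plus how each edge direction was decided."""

    graph: CausalGraph
    provenance: dict[tuple[str, str], str]  # edge -> constraint/v-structure/meek/fallback
    dropped: list[tuple[str, str, str]]  # (u, v, reason) for conflict-dropped edges

    def provenance_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rule": rule}
            for (u, v), rule in sorted(self.provenance.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rule"])


class _PDAG:
    """Mutable partially directed graph used during orientation."""

    def __init__(self, skeleton: nx.Graph) -> None:
        self.undirected: set[frozenset] = {frozenset(e) for e in skeleton.edges()}
        self.directed: set[tuple[str, str]] = set()
        self.nodes = sorted(skeleton.nodes)
        self._adj = {v: set(skeleton.neighbors(v)) for v in skeleton.nodes}

    def adjacent(self, x: str, y: str) -> bool:
        return y in self._adj[x]

    def has_undirected(self, x: str, y: str) -> bool:
        return frozenset((x, y)) in self.undirected

    def has_directed_path(self, x: str, y: str) -> bool:
        dg = nx.DiGraph(list(self.directed))
        return x in dg and y in dg and nx.has_path(dg, x, y)

    def orient(self, x: str, y: str) -> bool:
        """Direct x->y; returns False if that edge is already fixed y->x."""
        if (y, x) in self.directed:
            return False
        self.undirected.discard(frozenset((x, y)))
        self.directed.add((x, y))
        return True

    def drop(self, x: str, y: str) -> None:
        self.undirected.discard(frozenset((x, y)))
        self.directed.discard((x, y))
        self.directed.discard((y, x))
        self._adj[x].discard(y)
        self._adj[y].discard(x)


def _apply_meek(pdag: _PDAG, provenance: dict, rule_name: str = "meek") -> None:
    """Meek closure rules 1-4, iterated to a fixpoint.

    Each rule is sound for DAGs consistent with the current orientations and
    background knowledge: it only directs an edge whose opposite direction
    would force a cycle or a new v-structure.
    """
    changed = True
    while changed:
        changed = False
        for e in sorted(map(tuple, map(sorted, pdag.undirected))):
            a, b = e
            for x, y in ((a, b), (b, a)):
                if not pdag.has_undirected(x, y):
                    continue
                if _meek_forces(pdag, x, y):
                    if pdag.orient(x, y):
                        provenance[(x, y)] = rule_name
                        changed = True
                    break
    return


def _meek_forces(pdag: _PDAG, x: str, y: str) -> bool:
    """Does some Meek rule force the undirected edge x-y into x->y?"""
    directed = pdag.directed
    # R1: w -> x, x - y, w and y nonadjacent  =>  x -> y
    for (w, v) in directed:
        if v == x and w != y and not pdag.adjacent(w, y):
            return True
    # R2 generalised to acyclicity: a directed path x ~> y forbids y -> x;
    # here we orient x -> y when x ~> y already holds through directed edges.
    if pdag.has_directed_path(x, y):
        return True
    # R3: x - c, x - d, c -> y, d -> y, c and d nonadjacent  =>  x -> y
    into_y = [w for (w, v) in directed if v == y]
    for c, d in combinations(sorted(into_y), 2):
        if (
            pdag.has_undirected(x, c)
            and pdag.has_undirected(x, d)
            and not pdag.adjacent(c, d)
        ):
            return True
    # R4: x adjacent to b, chain b -> c -> y, b and y nonadjacent  =>  x -> y
    # (y -> x would force b -> x by acyclicity/R2, creating the new
    # v-structure b -> x <- y; both escapes are forbidden.)
    for (c, v) in directed:
        if v != y:
            continue
        for (b, w) in directed:
            if w != c or b == y or b == x:
                continue
            if pdag.adjacent(x, b) and not pdag.adjacent(b, y):
                return True
    return False


def orient_edges(
    skeleton: nx.Graph,
    sepsets: SeparationSets,
    tiers: Mapping[str, str],
    instrument_counts: Mapping[str, int] | None = None,
) -> OrientationResult:
    """Orient a skeleton into a DAG using tiers, v-structures, Meek, fallback.

    ``instrument_counts`` (trait -> number of attached instruments) feeds the
    deterministic fallback for edges left undirected by the sound rules: the
    endpoint with more instruments points at the other, ties broken by node
    name. Every fallback (and every conflict-dropped edge) is logged.
    """
    tiers = dict(tiers)
    for v in skeleton.nodes:
        tiers.setdefault(v, TRAIT)
    pdag = _PDAG(skeleton)
    provenance: dict[tuple[str, str], str] = {}
    dropped: list[tuple[str, str, str]] = []

    # (1) background knowledge: instrument edges point at the trait
    for e in sorted(map(tuple, map(sorted, set(pdag.undirected)))):
        u, v = e
        if tiers[u] == INSTRUMENT and tiers[v] == TRAIT:
            pdag.orient(u, v)
            provenance[(u, v)] = "constraint"
        elif tiers[v] == INSTRUMENT and tiers[u] == TRAIT:
            pdag.orient(v, u)
            provenance[(v, u)] = "constraint"

    # (2) v-structures from separation sets
    for x, y in combinations(sorted(skeleton.nodes), 2):
        if pdag.adjacent(x, y):
            continue
        sep = sepsets.get(x, y)
        if sep is None:
            continue
        for z in sorted(set(skeleton.neighbors(x)) & set(skeleton.neighbors(y))):
            if z in sep:
                continue
            if tiers[z] == INSTRUMENT:
                log.warning(
                    "v-structure %s -> %s <- %s ignored: collider is an instrument",
                    x, z, y,
                )
                continue
            ok_x = pdag.orient(x, z) if pdag.adjacent(x, z) else True
            ok_y = pdag.orient(y, z) if pdag.adjacent(y, z) else True
            for ok, tail in ((ok_x, x), (ok_y, y)):
                if ok and pdag.adjacent(tail, z) and (tail, z) in pdag.directed:
                    provenance.setdefault((tail, z), "v-structure")
                if not ok:
                    log.warning(
                        "orientation conflict at collider %s -> %s <- %s: "
                        "dropping edge %s - %s", x, z, y, tail, z,
                    )
                    pdag.drop(tail, z)
                    provenance.pop((z, tail), None)
                    provenance.pop((tail, z), None)
                    dropped.append((tail, z, "v-structure conflict"))

    # (3) Meek closure
    _apply_meek(pdag, provenance)

    # (4) deterministic fallback for residual undirected trait-trait edges
    counts = dict(instrument_counts or {})
    for v in skeleton.nodes:
        counts.setdefault(
            v,
            sum(
                1
                for (w, t) in pdag.directed
                if t == v and tiers.get(w) == INSTRUMENT
            ),
        )
    while pdag.undirected:
        e = min(map(tuple, map(sorted, pdag.undirected)))
        a, b = e
        if counts.get(a, 0) > counts.get(b, 0):
            src, dst = a, b
        elif counts.get(b, 0) > counts.get(a, 0):
            src, dst = b, a
        else:
            src, dst = (a, b) if a < b else (b, a)
        if pdag.has_directed_path(dst, src):
            src, dst = dst, src  # the preferred direction would close a cycle
        log.info("fallback orientation %s -> %s (no rule determined it)", src, dst)
        pdag.orient(src, dst)
        provenance[(src, dst)] = "fallback"
        _apply_meek(pdag, provenance)

    graph = CausalGraph(nodes=tiers, edges=sorted(pdag.directed))
    return OrientationResult(graph=graph, provenance=provenance, dropped=dropped)


def trait_subgraph(graph: CausalGraph) -> CausalGraph:
    """Delete the instrument (genome PC) nodes, keeping trait edges intact."""
    return graph.trait_subgraph()


def learn_structure(
    data: pd.DataFrame | None = None,
    tiers: Mapping[str, str] | None = None,
    alpha: float = 0.001,
    max_cond: int | None = 3,
    cov: pd.DataFrame | None = None,
    instrument_counts: Mapping[str, int] | None = None,
) -> OrientationResult:
    """Skeleton + orientation in one call; returns the two-tier DAG."""
    skel, seps = estimate_skeleton(
        data=data, tiers=tiers, alpha=alpha, max_cond=max_cond, cov=cov
    )
    return orient_edges(skel, seps, tiers or {}, instrument_counts=instrument_counts)
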