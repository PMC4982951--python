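"""Causal effect sizes by back-door adjustment on the learned network.

Once the trait network is directed, the causal effect of one metabolite on
another can be estimated from observational data by ordinary least squares:
regress the outcome on the exposure together with the exposure's parents.
Under the graph, the parents of the exposure close every back-door
(confounding) path, so the exposure coefficient identifies the *total*
causal effect — the sum over all directed paths of products of edge weights
in a linear system. When the only directed path is the edge itself, this
coincides with the direct edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graph import CausalGraph


class CollinearityError(ValueError):
    """Adjustment covariates are linearly dependent; names the offending pair."""


@dataclass(frozen=True)
class EffectEstimate:
    """A single exposure -> outcome effect with its adjustment context."""

    exposure: str
    outcome: str
    adjustment: tuple[str, ...]
    estimate: float
    standard_error: float
    n_used: int
    structurally_zero: bool = False  # outcome not a descendant of exposure

    def __post_init__(self) -> None:
        overlap = {self.exposure, self.outcome} & set(self.adjustment)
        if overlap:
            raise ValueError(f"adjustment set contains {sorted(overlap)}")


def adjustment_set(graph: CausalGraph, exposure: str, outcome: str) -> set[str]:
    """Back-door adjustment set: the parents of the exposure.

    Conditioning on the exposure's parents blocks every path into the
    exposure, hence every back-door path to any outcome, so this set is valid
    for all exposure/outcome pairs under the graph.
    """
    for name in (exposure, outcome):
        if name not in graph:
            raise KeyError(f"unknown node {name!r}")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    return graph.parents(exposure) - {outcome}


def is_structurally_zero(graph: CausalGraph, exposure: str, outcome: str) -> bool:
    """True when the graph admits no directed path exposure ~> outcome."""
    return outcome not in nx.descendants(graph.to_networkx(), exposure)


def _check_collinearity(x: pd.DataFrame) -> None:
    if x.shape[1] < 2:
        return
    corr = np.corrcoef(x.to_numpy(), rowvar=False)
    cols = list(x.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise CollinearityError(
                    f"covariates {cols[i]!r} and {cols[j]!r} are collinear "
                    f"(|r| = {abs(corr[i, j]):.6f})"
                )
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise CollinearityError(f"covariate matrix {cols} is rank deficient")


def estimate_effect(
    data: pd.DataFrame,
    graph: CausalGraph,
    exposure: str,
    outcome: str,
) -> EffectEstimate:
    """OLS effect of ``exposure`` on ``outcome`` adjusting for its parents.

    Complete-case rows only. When the graph admits no directed path from
    exposure to outcome the causal effect is structurally zero and the
    estimate is flagged accordingly (the regression is still reported, as a
    diagnostic of residual association).
    """
    adj = sorted(adjustment_set(graph, exposure, outcome))
    cols = [exposure, *adj]
    sub = data[[outcome, *cols]].dropna()
    x = sub[cols]
    _check_collinearity(x)
    fit = sm.OLS(sub[outcome].to_numpy(), sm.add_constant(x.to_numpy())).fit()
    return EffectEstimate(
        exposure=exposure,
        outcome=outcome,
        adjustment=tuple(adj),
        estimate=float(fit.params[1]),
        standard_error=float(fit.bse[1]),
        n_used=int(len(sub)),
        structurally_zero=is_structurally_zero(graph, exposure, outcome),
    )


def estimate_child_effects(
    data: pd.DataFrame, graph: CausalGraph, exposure: str
) -> list[EffectEstimate]:
    """Effects of an exposure on each of its local (child) metabolites."""
    return [
        estimate_effect(data, graph, exposure, child)
        for child in sorted(graph.children(exposure))
    ]


def effects_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    rows = [
        {
            "exposure": e.exposure,
            "outcome": e.outcome,
            "adjustment_set": ";".join(e.adjustment),
            "estimate": e.estimate,
            "se": e.standard_error,
            "n": e.n_used,
            "structurally_zero": e.structurally_zero,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["exposure", "outcome", "adjustment_set", "estimate", "se", "n", "structurally_zero"],
    )


def implied_total_effects(
    weights, trait_names: list[str]
) -> pd.DataFrame:
    """Total effects implied by SEM weights: entry (i, j) = sum over directed
    paths i ~> j of the product of edge weights, i.e. ``(I - W)^{-1} - I``."""
    idx = {n: i for i, n in enumerate(trait_names)}
    p = len(trait_names)
    w = np.zeros((p, p))
    for (u, v), wt in dict(weights).items():
        w[idx[u], idx[v]] = wt
    total = np.linalg.inv(np.eye(p) - w) - np.eye(p)
    return pd.DataFrame(total, index=trait_names, columns=trait_names)
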