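"""Synthetic genotype and metabolite data with known causal ground truth.

The real study population (a cohort of 2479 individuals with array genotypes
and serum fatty-acid metabolomics) is not publicly deposited, so this module
generates data with the same statistical structure the analysis assumes:

* genotypes in linkage-disequilibrium blocks — dosages in {0, 1, 2} obtained
  by thresholding correlated Gaussian latent variables (two independent
  "haplotype" draws per person) at minor-allele-frequency quantiles;
* fifteen metabolite traits generated from a sparse acyclic linear-Gaussian
  structural equation model, with direct genetic effects (standardized
  dosages) entering the source traits so that genome-derived instruments can
  anchor edge directions downstream.

Two reference networks over the fifteen fatty-acid names are provided.
``reported_degree_graph`` reproduces the published per-node out-/in-degree
profile exactly (29 edges). ``default_trait_graph`` is the default simulation
network: it reroutes a single edge (margarate -> oleate instead of
margarate -> eicosenoate) so that the two dietary source metabolites,
palmitoleate and margarate, jointly influence all thirteen other traits —
the qualitative property the analysis is designed to detect. The published
degree table and that joint-influence property cannot both hold in one DAG
(oleate is listed with in-degree zero), hence the two variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import TRAIT, CausalGraph


class ConfigurationError(ValueError):
    """Invalid simulation configuration (cyclic edges, bad dimensions, ...)."""


#: The fifteen fatty-acid metabolites, in published table order.
FATTY_ACIDS = [
    "Myristate",
    "Myristoleate",
    "Palmitate",
    "Palmitoleate",
    "Margarate",
    "Heptadecanoate",
    "Stearate",
    "Oleate",
    "Nonadecanoate",
    "Eicosenoate",
    "Linoleate",
    "Linolenate",
    "Dihomo-linoleate",
    "Decanoylcarnitine",
    "Laurylcarnitine",
]

#: 29 directed edges whose per-node out/in degrees match the published
#: network-parameter table row for row (e.g. dihomo-linoleate 0 out / 6 in,
#: margarate 5 out / 0 in). Margarate's longest outgoing path is
#: margarate -> heptadecanoate -> nonadecanoate -> stearate ->
#: decanoylcarnitine -> laurylcarnitine: five steps, blocked at the
#: carnitine sink, and margarate does not reach myristate.
REPORTED_DEGREE_EDGES: list[tuple[str, str]] = [
    ("Palmitoleate", "Myristate"),
    ("Palmitoleate", "Palmitate"),
    ("Palmitoleate", "Linolenate"),
    ("Palmitoleate", "Heptadecanoate"),
    ("Palmitoleate", "Stearate"),
    ("Margarate", "Heptadecanoate"),
    ("Margarate", "Linolenate"),
    ("Margarate", "Eicosenoate"),
    ("Margarate", "Laurylcarnitine"),
    ("Margarate", "Palmitate"),
    ("Oleate", "Myristoleate"),
    ("Oleate", "Eicosenoate"),
    ("Oleate", "Dihomo-linoleate"),
    ("Myristate", "Myristoleate"),
    ("Myristate", "Linolenate"),
    ("Myristate", "Dihomo-linoleate"),
    ("Palmitate", "Eicosenoate"),
    ("Palmitate", "Dihomo-linoleate"),
    ("Palmitate", "Linoleate"),
    ("Heptadecanoate", "Nonadecanoate"),
    ("Myristoleate", "Dihomo-linoleate"),
    ("Linolenate", "Eicosenoate"),
    ("Eicosenoate", "Dihomo-linoleate"),
    ("Eicosenoate", "Linoleate"),
    ("Nonadecanoate", "Stearate"),
    ("Nonadecanoate", "Dihomo-linoleate"),
    ("Stearate", "Decanoylcarnitine"),
    ("Stearate", "Laurylcarnitine"),
    ("Decanoylcarnitine", "Laurylcarnitine"),
]

#: Default simulation network: one edge rerouted so palmitoleate + margarate
#: jointly reach every other node (margarate -> oleate replaces
#: margarate -> eicosenoate). Still 15 nodes / 29 edges.
DEFAULT_TRAIT_EDGES: list[tuple[str, str]] = [
    ("Margarate", "Oleate") if e == ("Margarate", "Eicosenoate") else e
    for e in REPORTED_DEGREE_EDGES
]

# Fixed, all-positive weights keep every directed path reinforcing (no exact
# path cancellations, so the generating model stays faithful to its graph).
_WEIGHT_CYCLE = [0.7, 0.45, 0.55, 0.8, 0.35, 0.6, 0.5, 0.65, 0.4]

#: Default edge weights of the simulated structural equation model.
DEFAULT_EDGE_WEIGHTS: dict[tuple[str, str], float] = {
    e: _WEIGHT_CYCLE[i % len(_WEIGHT_CYCLE)]
    for i, e in enumerate(DEFAULT_TRAIT_EDGES)
}


def reported_degree_graph() -> CausalGraph:
    """The 29-edge network matching the published degree profile exactly."""
    return CausalGraph(nodes=FATTY_ACIDS, edges=REPORTED_DEGREE_EDGES)


def default_trait_graph() -> CausalGraph:
    """The default simulation DAG (joint-influence variant, 29 edges)."""
    return CausalGraph(nodes=FATTY_ACIDS, edges=DEFAULT_TRAIT_EDGES)


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``edge_weights`` define the trait-level structural equation model and must
    induce a DAG. ``genetic_effects`` attach standardized SNP dosages to
    traits (keyed by ``(snp_index, trait_name)``); by default they target the
    source traits, mirroring the premise that genome variation is causally
    upstream of the metabolome.
    """

    n_samples: int = 2479
    n_snps: int = 300
    block_size: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_r: float = 0.9
    trait_names: tuple[str, ...] = tuple(FATTY_ACIDS)
    edge_weights: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS)
    )
    genetic_effects: Mapping[tuple[int, str], float] = field(
        default_factory=lambda: {
            (0, "Palmitoleate"): 0.6,
            (20, "Palmitoleate"): 0.45,
            (40, "Margarate"): 0.6,
            (60, "Margarate"): 0.45,
        }
    )
    noise_sd: float | Mapping[str, float] = 1.0
    seed: int = 20160801

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0 or self.block_size <= 0:
            raise ConfigurationError("n_samples, n_snps, block_size must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.within_block_r <= 1.0:
            raise ConfigurationError("within_block_r must be in [0, 1]")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ConfigurationError("trait_names must be distinct")
        names = set(self.trait_names)
        for (u, v) in self.edge_weights:
            if u not in names or v not in names:
                raise ConfigurationError(f"edge ({u!r}, {v!r}) references unknown trait")
        # acyclicity check: CausalGraph raises GraphInvariantError on a cycle
        try:
            CausalGraph(nodes=list(self.trait_names), edges=list(self.edge_weights))
        except ValueError as exc:
            raise ConfigurationError(f"edge_weights must form a DAG: {exc}") from exc
        for (snp, trait) in self.genetic_effects:
            if not 0 <= snp < self.n_snps:
                raise ConfigurationError(f"genetic effect on SNP {snp} out of range")
            if trait not in names:
                raise ConfigurationError(f"genetic effect on unknown trait {trait!r}")
        for name in self.trait_names:
            if self.noise_sd_for(name) <= 0:
                raise ConfigurationError(f"noise_sd for {name!r} must be positive")

    def noise_sd_for(self, trait: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[trait])
        return float(self.noise_sd)

    def trait_graph(self) -> CausalGraph:
        return CausalGraph(nodes=list(self.trait_names), edges=list(self.edge_weights))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "n_snps": self.n_snps,
            "block_size": self.block_size,
            "maf_range": list(self.maf_range),
            "within_block_r": self.within_block_r,
            "trait_names": list(self.trait_names),
            "edge_weights": [[u, v, w] for (u, v), w in self.edge_weights.items()],
            "genetic_effects": [[s, t, w] for (s, t), w in self.genetic_effects.items()],
            "noise_sd": (
                dict(self.noise_sd) if isinstance(self.noise_sd, Mapping) else self.noise_sd
            ),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_samples=payload["n_samples"],
            n_snps=payload["n_snps"],
            block_size=payload["block_size"],
            maf_range=tuple(payload["maf_range"]),
            within_block_r=payload["within_block_r"],
            trait_names=tuple(payload["trait_names"]),
            edge_weights={(u, v): w for u, v, w in payload["edge_weights"]},
            genetic_effects={(s, t): w for s, t, w in payload["genetic_effects"]},
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class GroundTruth:
    """The generating trait DAG, its weights, and which traits carry instruments."""

    dag: CausalGraph
    weights: Mapping[tuple[str, str], float]
    instrument_targets: frozenset[str]

    def __post_init__(self) -> None:
        self.dag.validate()
        if set(self.weights) != set(self.dag.edges()):
            raise ConfigurationError("weights must be nonzero exactly on DAG edges")

    def write_edges(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for (u, v), w in sorted(self.weights.items()):
                fh.write(f"{u}\t{v}\t{w}\n")


# ---------------------------------------------------------------------------
# genotype simulation


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    g_seed, t_seed = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(g_seed), np.random.default_rng(t_seed)


def simulate_genotypes(config: SimulationConfig):
    """Dosage matrix (samples x SNPs, values in {0,1,2}) in LD blocks.

    Each block is generated from two haplotype draws of an equicorrelated
    Gaussian latent vector (pairwise latent correlation ``within_block_r``);
    an allele is the minor one when its latent falls below the MAF quantile.
    Blocks are mutually independent. With ``within_block_r = 1`` and a
    degenerate MAF range, all SNPs in a block are identical columns.
    """
    from .instruments import GenotypeMatrix  # local import to avoid a cycle

    rng, _ = _rng_streams(config.seed)
    n, m, bs = config.n_samples, config.n_snps, config.block_size
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    r = config.within_block_r
    dosages = np.empty((n, m), dtype=np.int8)
    for start in range(0, m, bs):
        width = min(bs, m - start)
        block_dos = np.zeros((n, width), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, width))
            latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
            thresh = stats.norm.ppf(mafs[start : start + width])
            block_dos += (latent < thresh).astype(np.int8)
        dosages[:, start : start + width] = block_dos
    sample_ids = [f"S{i:05d}" for i in range(n)]
    snp_ids = [f"snp{j:05d}" for j in range(m)]
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, dosages=dosages.astype(float))


# ---------------------------------------------------------------------------
# trait simulation


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x, dtype=float)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def simulate_traits(genotypes, config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Traits from the linear-Gaussian SEM, plus the generating ground truth.

    Each trait is the weighted sum of its parent traits, plus standardized
    dosages of its causal SNPs, plus independent Gaussian noise, evaluated in
    topological order of the trait DAG.
    """
    _, rng = _rng_streams(config.seed)
    dag = config.trait_graph()
    import networkx as nx

    order = list(nx.topological_sort(dag.to_networkx()))
    n = genotypes.dosages.shape[0]
    if n != config.n_samples:
        raise ConfigurationError(
            f"genotypes have {n} samples but config expects {config.n_samples}"
        )
    z = _standardize_columns(np.asarray(genotypes.dosages, dtype=float))
    values: dict[str, np.ndarray] = {}
    for trait in order:
        x = rng.normal(0.0, config.noise_sd_for(trait), size=n)
        for parent in dag.parents(trait):
            x = x + config.edge_weights[(parent, trait)] * values[parent]
        for (snp, target), w in config.genetic_effects.items():
            if target == trait:
                x = x + w * z[:, snp]
        values[trait] = x
    traits = pd.DataFrame(
        {name: values[name] for name in config.trait_names},
        index=genotypes.sample_ids,
    )
    traits.index.name = "sample"
    truth = GroundTruth(
        dag=dag,
        weights=dict(config.edge_weights),
        instrument_targets=frozenset(t for (_s, t) in config.genetic_effects),
    )
    return traits, truth


def simulate_cohort(config: SimulationConfig):
    """Convenience: genotypes, traits and ground truth in one call."""
    genotypes = simulate_genotypes(config)
    traits, truth = simulate_traits(genotypes, config)
    return genotypes, traits, truth


# ---------------------------------------------------------------------------
# analytic second moments


def sem_covariance(
    names: Sequence[str],
    weights: Mapping[tuple[str, str], float],
    noise_var: Mapping[str, float],
) -> pd.DataFrame:
    """Exact covariance implied by a linear-Gaussian SEM.

    With weight matrix ``W`` (``W[i, j]`` = coefficient of ``names[i]`` in the
    equation of ``names[j]``) and exogenous noise variances ``D``, the model
    ``x = W'x + e`` implies ``Cov(x) = (I - W')^{-1} D (I - W')^{-T}``.
    """
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    w = np.zeros((p, p))
    for (u, v), wt in weights.items():
        w[idx[u], idx[v]] = wt
    a = np.linalg.inv(np.eye(p) - w.T)
    d = np.diag([float(noise_var[n]) for n in names])
    cov = a @ d @ a.T
    return pd.DataFrame(cov, index=list(names), columns=list(names))


def trait_covariance(config: SimulationConfig) -> pd.DataFrame:
    """Analytic covariance of the traits, marginalising genetic effects.

    Standardized dosages have unit variance; multiple causal SNPs of one
    trait are treated as independent (they live in different LD blocks in the
    default configuration), so they fold into the trait's exogenous variance.
    """
    noise_var = {t: config.noise_sd_for(t) ** 2 for t in config.trait_names}
    for (_snp, trait), w in config.genetic_effects.items():
        noise_var[trait] += w**2
    return sem_covariance(list(config.trait_names), dict(config.edge_weights), noise_var)


def joint_covariance(
    trait_names: Sequence[str],
    edge_weights: Mapping[tuple[str, str], float],
    instrument_effects: Mapping[str, Mapping[str, float]],
    noise_sd: float | Mapping[str, float] = 1.0,
) -> pd.DataFrame:
    """Analytic covariance over instruments and traits jointly.

    Instruments are exogenous unit-variance variables with direct effects on
    their target traits. This is the input for oracle-mode structure
    learning, where the learner sees exact population moments instead of a
    finite sample.
    """
    names = list(instrument_effects) + list(trait_names)
    weights: dict[tuple[str, str], float] = dict(edge_weights)
    for inst, targets in instrument_effects.items():
        for trait, w in targets.items():
            weights[(inst, trait)] = w
    noise_var: dict[str, float] = {i: 1.0 for i in instrument_effects}
    for t in trait_names:
        sd = noise_sd[t] if isinstance(noise_sd, Mapping) else noise_sd
        noise_var[t] = float(sd) ** 2
    return sem_covariance(names, weights, noise_var)


# ---------------------------------------------------------------------------
# serialization


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def rank_inverse_normal(traits: pd.DataFrame, offset: float = 3.0 / 8.0) -> pd.DataFrame:
    """Rank-based inverse-normal transform (Blom offset), applied per column.

    The measured metabolites were normalized before analysis; the simulator
    already emits Gaussian traits, so this transform is an optional
    pre-processing step for externally supplied trait tables.
    """
    n = len(traits)
    ranks = traits.rank(method="average")
    return pd.DataFrame(
        stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1)),
        index=traits.index,
        columns=traits.columns,
    )
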