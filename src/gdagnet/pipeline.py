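"""End-to-end pipeline: simulate/load -> prune -> instruments -> learn ->
metrics -> effects, with a JSON run manifest.

Every stage writes its artifact under the configured output directory, so a
run is fully reproducible from the manifest (package version, seed, config
hash) and inspectable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .effects import effects_frame, estimate_child_effects
from .graph import INSTRUMENT, TRAIT
from .graphio import write_graph
from .instruments import GenotypeMatrix, compute_pcs, ld_prune, select_instruments
from .learner import learn_structure, trait_subgraph
from .metrics import metrics_table, write_metrics
from .synth import (
    SimulationConfig,
    joint_covariance,
    read_traits,
    simulate_genotypes,
    simulate_traits,
    write_traits,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Either ``genotype_path``+``trait_path`` point at existing TSV inputs, or
    ``simulation`` describes a synthetic cohort to generate first. In
    ``oracle`` mode the structure learner is fed the exact covariance implied
    by the simulation config (one unit-variance instrument per trait that
    carries genetic effects) instead of finite-sample estimates.
    """

    out_dir: str = "gdag_run"
    genotype_path: str | None = None
    trait_path: str | None = None
    simulation: SimulationConfig | None = None
    alpha: float = 0.001
    r2_threshold: float = 0.80
    prune_window: int = 100
    k_pcs: int = 50
    max_cond: int | None = 3
    oracle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if self.k_pcs < 1:
            raise ValueError("k_pcs must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        if self.simulation is not None:
            payload["simulation"] = json.loads(_sim_json(self.simulation))
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        sim = payload.pop("simulation", None)
        cfg = cls(**payload)
        if sim is not None:
            cfg.simulation = _sim_from_payload(sim)
        return cfg

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where outputs land is not analysis content
        if self.simulation is not None:
            payload["simulation"] = json.loads(_sim_json(self.simulation))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sim_json(sim: SimulationConfig) -> str:
    return json.dumps(
        {
            "n_samples": sim.n_samples,
            "n_snps": sim.n_snps,
            "block_size": sim.block_size,
            "maf_range": list(sim.maf_range),
            "within_block_r": sim.within_block_r,
            "trait_names": list(sim.trait_names),
            "edge_weights": [[u, v, w] for (u, v), w in sim.edge_weights.items()],
            "genetic_effects": [[s, t, w] for (s, t), w in sim.genetic_effects.items()],
            "noise_sd": dict(sim.noise_sd) if isinstance(sim.noise_sd, dict) else sim.noise_sd,
            "seed": sim.seed,
        },
        sort_keys=True,
    )


def _sim_from_payload(payload: dict) -> SimulationConfig:
    return SimulationConfig(
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


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    genotypes, traits, truth = _load_inputs(config, out, artifacts)

    if config.oracle:
        if config.simulation is None:
            raise PipelineError("stage 'learn' failed: oracle mode needs a simulation config")
        sim = config.simulation
        targets = sorted({t for (_s, t) in sim.genetic_effects})
        inst_effects = {f"IV_{t}": {t: 0.6} for t in targets}
        cov = joint_covariance(
            list(sim.trait_names), dict(sim.edge_weights), inst_effects, sim.noise_sd
        )
        tiers = {i: INSTRUMENT for i in inst_effects} | {t: TRAIT for t in sim.trait_names}
        result = _learn(config, cov=cov, tiers=tiers)
    else:
        pruned = _prune(genotypes, config, out, artifacts)
        pcs, report = _instruments(pruned, traits, config, out, artifacts)
        kept = pcs.selected_scores()
        joined = pd.concat([kept, traits], axis=1)
        tiers = {pc: INSTRUMENT for pc in kept.columns} | {t: TRAIT for t in traits.columns}
        counts = {t: 0 for t in traits.columns}
        for pc, assoc in pcs.selected.items():
            for t in assoc:
                counts[t] += 1
        result = _learn(config, data=joined, tiers=tiers, instrument_counts=counts)

    write_graph(result.graph, out / "network_two_tier.tsv")
    write_graph(result.graph, out / "network_two_tier.graphml")
    write_graph(result.graph, out / "network_two_tier.dot")
    result.provenance_frame().to_csv(out / "orientation_provenance.tsv", sep="\t", index=False)
    artifacts["two_tier_graph"] = "network_two_tier.tsv"

    trait_net = trait_subgraph(result.graph)
    write_graph(trait_net, out / "network_traits.tsv")
    write_graph(trait_net, out / "network_traits.graphml")
    write_graph(trait_net, out / "network_traits.dot")
    artifacts["trait_graph"] = "network_traits.tsv"

    metrics = _metrics(trait_net, out, artifacts)

    if traits is not None:
        _effects(traits, trait_net, out, artifacts)

    manifest = {
        "package": "gdagnet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "alpha": config.alpha,
        "n_trait_nodes": len(trait_net.nodes()),
        "n_trait_edges": len(trait_net.edges()),
        "dropped_edges": result.dropped,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_json(out / "config.json")
    # acyclicity asserted on every run output
    trait_net.validate()
    assert metrics["out_degree"].sum() == metrics["in_degree"].sum()
    return manifest


@_stage("inputs")
def _load_inputs(config: PipelineConfig, out: Path, artifacts: dict):
    truth = None
    if config.simulation is not None:
        genotypes = simulate_genotypes(config.simulation)
        traits, truth = simulate_traits(genotypes, config.simulation)
        genotypes.to_tsv(out / "genotypes.tsv")
        write_traits(traits, out / "traits.tsv")
        truth.write_edges(out / "ground_truth_edges.tsv")
        artifacts["genotypes"] = "genotypes.tsv"
        artifacts["traits"] = "traits.tsv"
        artifacts["ground_truth"] = "ground_truth_edges.tsv"
    elif config.genotype_path and config.trait_path:
        genotypes = GenotypeMatrix.from_tsv(config.genotype_path)
        traits = read_traits(config.trait_path)
        if list(traits.index.astype(str)) != [str(s) for s in genotypes.sample_ids]:
            raise ValueError("genotype and trait tables disagree on samples")
    else:
        raise ValueError("need either simulation config or genotype+trait paths")
    return genotypes, traits, truth


@_stage("prune")
def _prune(genotypes, config, out: Path, artifacts: dict):
    pruned = ld_prune(genotypes, config.r2_threshold, window=config.prune_window)
    (out / "pruned_snps.txt").write_text("\n".join(pruned.snp_ids) + "\n")
    artifacts["pruned_snps"] = "pruned_snps.txt"
    log.info("LD pruning kept %d of %d SNPs", pruned.n_snps, genotypes.n_snps)
    return pruned


@_stage("instruments")
def _instruments(pruned, traits, config, out: Path, artifacts: dict):
    k = min(config.k_pcs, pruned.n_snps, pruned.n_samples)
    if k < config.k_pcs:
        log.info("k_pcs clamped to %d (matrix bound)", k)
    pcs = compute_pcs(pruned, k)
    pcs.scores.to_csv(out / "pc_scores.tsv", sep="\t")
    selected, report = select_instruments(pcs, traits, alpha=config.alpha)
    report.to_csv(out / "instrument_report.tsv", sep="\t", index=False)
    artifacts["pc_scores"] = "pc_scores.tsv"
    artifacts["instrument_report"] = "instrument_report.tsv"
    log.info("%d of %d PCs selected as instruments", len(selected.selected), k)
    return selected, report


@_stage("learn")
def _learn(config: PipelineConfig, **kwargs):
    return learn_structure(alpha=config.alpha, max_cond=config.max_cond, **kwargs)


@_stage("metrics")
def _metrics(trait_net, out: Path, artifacts: dict):
    metrics = metrics_table(trait_net)
    write_metrics(metrics, out / "metrics.tsv")
    artifacts["metrics"] = "metrics.tsv"
    return metrics


@_stage("effects")
def _effects(traits, trait_net, out: Path, artifacts: dict):
    estimates = []
    for exposure in trait_net.nodes():
        estimates.extend(estimate_child_effects(traits, trait_net, exposure))
    effects_frame(estimates).to_csv(out / "effects.tsv", sep="\t", index=False)
    artifacts["effects"] = "effects.tsv"
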