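"""LD pruning and genome-wide principal-component instruments.

The first two stages of the pipeline reduce a genome-wide dosage matrix to a
small set of strong, mutually orthogonal instrumental variables:

1. linkage-disequilibrium pruning drops SNPs that are nearly perfectly
   correlated (r^2 above a threshold, default 0.80) with a nearby retained
   SNP, which then serves as their proxy;
2. principal components of the standardized pruned dosages summarise
   variation across the genome — these PCs, not individual SNPs, are the
   candidate instruments;
3. per-trait multiple regression with backward elimination keeps the PCs
   that remain significant (default alpha = 0.001) for at least one trait.

This genome-wide PCA extracts variation *across SNPs* to build instruments;
it is not the sample-structure PCA used for population-stratification
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

_VALID_DOSAGES = (0.0, 1.0, 2.0)


class AlignmentError(ValueError):
    """Sample IDs/ordering disagree between two inputs that must be joined."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix (alt-allele counts 0/1/2, NaN = missing)."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, _VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, _VALID_DOSAGES)][0]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)
        df.index.name = "sample"
        return df

    def to_tsv(self, path: str | Path) -> None:
        # integers where observed, blank cells for missing calls
        self.to_frame().astype("Int64").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            sample_ids=[str(s) for s in df.index],
            snp_ids=[str(c) for c in df.columns],
            dosages=df.to_numpy(dtype=float),
        )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read GT fields of a VCF as alt-allele dosages (missing -> NaN)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_ids: list[str] = []
        columns: list[np.ndarray] = []
        for var in vcf:
            name = var.ID or f"{var.CHROM}:{var.POS}"
            snp_ids.append(str(name))
            # gt_types: 0=hom-ref 1=het 2=hom-alt 3=unknown
            gt = np.asarray(var.gt_types, dtype=float)
            dos = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
            columns.append(dos)
        return cls(
            sample_ids=samples,
            snp_ids=snp_ids,
            dosages=np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        )


@dataclass
class InstrumentSet:
    """Principal-component instruments: scores, loadings share, selection."""

    pc_ids: list[str]
    scores: pd.DataFrame  # samples x PCs
    explained_variance: np.ndarray  # fraction of total variance, non-increasing
    selected: dict[str, list[str]] = field(default_factory=dict)  # pc -> traits

    def selected_scores(self) -> pd.DataFrame:
        return self.scores[[pc for pc in self.pc_ids if pc in self.selected]]

    def restrict(self, pc_ids: Sequence[str]) -> "InstrumentSet":
        keep = [pc for pc in self.pc_ids if pc in set(pc_ids)]
        idx = [self.pc_ids.index(pc) for pc in keep]
        return InstrumentSet(
            pc_ids=keep,
            scores=self.scores[keep],
            explained_variance=self.explained_variance[idx],
            selected={pc: v for pc, v in self.selected.items() if pc in set(keep)},
        )


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.80,
    window: int = 100,
    min_call_rate: float = 0.95,
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning of a dosage matrix.

    Scanning SNPs in their genomic order, a SNP is dropped when its squared
    Pearson correlation (pairwise-complete, dosage scale) with an
    already-retained SNP at most ``window`` positions upstream exceeds
    ``r2_threshold`` — the retained SNP is its proxy. Monomorphic SNPs and
    SNPs with call rate below ``min_call_rate`` are dropped up front (logged,
    so no correlation is ever computed against a zero-variance column).
    Pruning preserves the original SNP order and is idempotent.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if genotypes.n_snps < 2:
        raise ValueError("ld_prune requires at least 2 SNPs")
    d = genotypes.dosages
    call_rate = np.isfinite(d).mean(axis=0)
    candidates: list[int] = []
    for j in range(genotypes.n_snps):
        if call_rate[j] < min_call_rate:
            log.warning(
                "dropping %s: call rate %.3f < %.2f",
                genotypes.snp_ids[j], call_rate[j], min_call_rate,
            )
            continue
        col = d[:, j]
        if np.nanstd(col) == 0:
            log.warning("dropping monomorphic SNP %s", genotypes.snp_ids[j])
            continue
        candidates.append(j)
    kept: list[int] = []
    for j in candidates:
        proxy = None
        for i in reversed(kept):
            if j - i > window:
                break
            if _pairwise_complete_r2(d[:, i], d[:, j]) > r2_threshold:
                proxy = i
                break
        if proxy is None:
            kept.append(j)
        else:
            log.debug(
                "pruned %s (r2 proxy %s)", genotypes.snp_ids[j], genotypes.snp_ids[proxy]
            )
    return genotypes.subset(kept)


# ---------------------------------------------------------------------------
# principal-component instruments


def _standardize_impute(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, then scale each SNP to mean 0 / sd 1."""
    x = d.copy()
    mu = np.nanmean(x, axis=0)
    ind = np.where(~np.isfinite(x))
    x[ind] = np.take(mu, ind[1])
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def compute_pcs(genotypes: GenotypeMatrix, k: int = 50) -> InstrumentSet:
    """Top-``k`` principal components of the standardized dosage matrix.

    Scores are the sample projections (mutually orthogonal columns); the
    explained-variance fractions are non-increasing. The sign of each
    component is fixed so that its largest-magnitude SNP loading is positive,
    making runs comparable across machines and column orders.
    """
    bound = min(genotypes.n_samples, genotypes.n_snps)
    if not 1 <= k <= bound:
        raise ValueError(
            f"k={k} out of range: must be between 1 and min(n_samples, n_snps)={bound}"
        )
    z = _standardize_impute(genotypes.dosages)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each right vector positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    explained = (s**2 / np.sum(s**2))[:k]
    pc_ids = [f"PC{i + 1}" for i in range(k)]
    return InstrumentSet(
        pc_ids=pc_ids,
        scores=pd.DataFrame(scores, index=genotypes.sample_ids, columns=pc_ids),
        explained_variance=explained,
    )


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    pcs: InstrumentSet,
    traits: pd.DataFrame,
    alpha: float = 0.001,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Keep PCs that survive backward elimination against at least one trait.

    Each trait is regressed on all candidate PCs; the least significant PC is
    removed until every remaining PC has p < ``alpha``. A PC is selected when
    it survives for at least one trait; the per-PC lists of associated traits
    are recorded, and the full report (pc, trait, beta, p at the surviving
    step) is returned alongside.
    """
    if list(pcs.scores.index) != list(traits.index):
        raise AlignmentError(
            "instrument scores and trait table must share the same samples "
            f"in the same order ({len(pcs.scores)} vs {len(traits)} rows)"
        )
    selected: dict[str, list[str]] = {}
    rows: list[dict] = []
    x_full = pcs.scores
    for trait in traits.columns:
        y = traits[trait].to_numpy()
        current = list(pcs.pc_ids)
        while current:
            x = sm.add_constant(x_full[current].to_numpy())
            fit = sm.OLS(y, x).fit()
            pvals = fit.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if pvals[worst] < alpha:
                for pc, beta, p in zip(current, fit.params[1:], pvals):
                    rows.append({"pc": pc, "trait": trait, "beta": beta, "p": p})
                    selected.setdefault(pc, []).append(trait)
                break
            current.pop(worst)
    report = pd.DataFrame(rows, columns=["pc", "trait", "beta", "p"])
    out = InstrumentSet(
        pc_ids=list(pcs.pc_ids),
        scores=pcs.scores,
        explained_variance=pcs.explained_variance,
        selected={pc: sorted(traits_) for pc, traits_ in selected.items()},
    )
    return out, report
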