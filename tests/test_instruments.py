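"""LD pruning, PC instrument construction, and significance-based selection."""

import numpy as np
import pandas as pd
import pytest

from gdagnet import (
    AlignmentError,
    GenotypeMatrix,
    SimulationConfig,
    compute_pcs,
    ld_prune,
    select_instruments,
    simulate_genotypes,
)


def _matrix(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=ids or [f"snp{j}" for j in range(m)],
        dosages=dosages,
    )


class TestLdPrune:
    def test_duplicate_columns_keep_exactly_one(self, rng):
        col = rng.integers(0, 3, size=50)
        g = _matrix(np.column_stack([col, col]))
        pruned = ld_prune(g, 0.80)
        assert pruned.snp_ids == ["snp0"]

    def test_independent_snps_all_retained(self, rng):
        g = _matrix(rng.integers(0, 3, size=(800, 12)))
        pruned = ld_prune(g, 0.80)
        assert pruned.snp_ids == g.snp_ids

    def test_retained_set_verified_by_exhaustive_pairwise_oracle(self):
        cfg = SimulationConfig(
            n_samples=600, n_snps=50, block_size=50, within_block_r=0.95,
            maf_range=(0.2, 0.4), trait_names=("A",), edge_weights={},
            genetic_effects={}, seed=5,
        )
        g = simulate_genotypes(cfg)
        pruned = ld_prune(g, 0.80)
        kept = [g.snp_ids.index(s) for s in pruned.snp_ids]
        corr = np.corrcoef(g.dosages, rowvar=False)
        # no retained pair above threshold
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                assert corr[kept[a], kept[b]] ** 2 <= 0.80
        # every removed SNP has a retained proxy above threshold
        removed = [j for j in range(g.n_snps) if j not in kept]
        for j in removed:
            assert max(corr[j, k] ** 2 for k in kept) > 0.80

    def test_pruning_is_idempotent(self):
        cfg = SimulationConfig(
            n_samples=400, n_snps=40, block_size=8, within_block_r=0.97,
            trait_names=("A",), edge_weights={}, genetic_effects={}, seed=9,
        )
        pruned = ld_prune(simulate_genotypes(cfg), 0.80)
        again = ld_prune(pruned, 0.80)
        assert again.snp_ids == pruned.snp_ids
        assert (again.dosages == pruned.dosages).all()

    def test_monomorphic_snp_dropped_not_divided_by_zero(self, rng, caplog):
        d = rng.integers(0, 3, size=(100, 3)).astype(float)
        d[:, 1] = 2.0
        with caplog.at_level("WARNING"):
            pruned = ld_prune(_matrix(d), 0.80)
        assert pruned.snp_ids == ["snp0", "snp2"]
        assert "monomorphic" in caplog.text

    def test_order_preserved(self, rng):
        g = _matrix(rng.integers(0, 3, size=(500, 20)))
        pruned = ld_prune(g, 0.99)
        original_pos = [g.snp_ids.index(s) for s in pruned.snp_ids]
        assert original_pos == sorted(original_pos)


class TestComputePcs:
    def test_rank_one_matrix_first_pc_explains_everything(self):
        base = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0]), (4, 1)).T
        pcs = compute_pcs(_matrix(base), k=2)
        assert pcs.explained_variance[0] > 0.999

    def test_scores_match_dense_eigendecomposition_oracle(self, rng):
        d = rng.integers(0, 3, size=(10, 8)).astype(float)
        pcs = compute_pcs(_matrix(d), k=5)
        z = (d - d.mean(0)) / d.std(0)
        evals, evecs = np.linalg.eigh(z.T @ z)
        order = np.argsort(evals)[::-1]
        expected = z @ evecs[:, order[:5]]
        got = pcs.scores.to_numpy()
        for i in range(5):
            # eigenvectors are sign-indeterminate; compare up to sign
            assert np.allclose(np.abs(got[:, i]), np.abs(expected[:, i]), atol=1e-8)

    def test_block_structure_leading_pcs_align_with_block_means(self):
        cfg = SimulationConfig(
            n_samples=2000, n_snps=30, block_size=10, within_block_r=0.95,
            maf_range=(0.3, 0.4), trait_names=("A",), edge_weights={},
            genetic_effects={}, seed=2,
        )
        g = simulate_genotypes(cfg)
        pcs = compute_pcs(g, k=3)
        z = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0)
        block_means = np.column_stack([z[:, i : i + 10].mean(1) for i in (0, 10, 20)])
        # equal blocks give near-degenerate leading eigenvalues, so individual
        # PCs may rotate within the block-mean subspace; the spanned subspace
        # itself is determined: each block mean is reproduced almost exactly
        # by the leading three PCs
        scores = pcs.scores.to_numpy()
        for b in range(3):
            y = block_means[:, b]
            coef, *_ = np.linalg.lstsq(scores, y, rcond=None)
            resid = y - scores @ coef
            r2 = 1 - resid.var() / y.var()
            assert r2 > 0.95

    def test_score_columns_orthogonal_and_variance_nonincreasing(self, rng):
        d = rng.integers(0, 3, size=(200, 20)).astype(float)
        pcs = compute_pcs(_matrix(d), k=6)
        s = pcs.scores.to_numpy()
        gram = s.T @ s
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-6)
        assert (np.diff(pcs.explained_variance) <= 1e-12).all()

    def test_sign_invariance_under_snp_permutation(self, rng):
        d = rng.integers(0, 3, size=(300, 12)).astype(float)
        perm = rng.permutation(12)
        a = compute_pcs(_matrix(d), k=4).scores.to_numpy()
        b = compute_pcs(_matrix(d[:, perm]), k=4).scores.to_numpy()
        for i in range(4):
            assert np.allclose(a[:, i], b[:, i], atol=1e-8) or np.allclose(
                a[:, i], -b[:, i], atol=1e-8
            )

    def test_k_out_of_range_error_names_bound(self, rng):
        g = _matrix(rng.integers(0, 3, size=(10, 4)).astype(float))
        with pytest.raises(ValueError, match="min\\(n_samples, n_snps\\)=4"):
            compute_pcs(g, k=5)


class TestSelectInstruments:
    def _pcs(self, rng, n=600, k=8):
        scores = rng.standard_normal((n, k))
        q, _ = np.linalg.qr(scores)
        ids = [f"PC{i+1}" for i in range(k)]
        from gdagnet import InstrumentSet

        return InstrumentSet(
            pc_ids=ids,
            scores=pd.DataFrame(q, index=[f"s{i}" for i in range(n)], columns=ids),
            explained_variance=np.linspace(0.2, 0.1, k),
        )

    def test_alpha_one_selects_every_pc(self, rng):
        pcs = self._pcs(rng)
        traits = pd.DataFrame(
            rng.standard_normal((600, 3)), index=pcs.scores.index, columns=list("ABC")
        )
        selected, _ = select_instruments(pcs, traits, alpha=0.999999)
        assert set(selected.selected) == set(pcs.pc_ids)

    def test_planted_strong_effect_always_selected(self, rng):
        hits = 0
        for _ in range(20):
            pcs = self._pcs(rng, n=2479)
            y = 0.5 * (pcs.scores["PC3"] / pcs.scores["PC3"].std()) + rng.standard_normal(2479)
            traits = pd.DataFrame({"T": y.to_numpy()}, index=pcs.scores.index)
            selected, report = select_instruments(pcs, traits, alpha=0.001)
            hits += "PC3" in selected.selected
        assert hits == 20

    def test_null_selection_rate_near_alpha(self, rng):
        false_hits, tests = 0, 0
        for _ in range(25):
            pcs = self._pcs(rng, n=500, k=10)
            traits = pd.DataFrame(
                rng.standard_normal((500, 4)),
                index=pcs.scores.index,
                columns=list("ABCD"),
            )
            selected, _ = select_instruments(pcs, traits, alpha=0.001)
            false_hits += sum(len(v) for v in selected.selected.values())
            tests += 10 * 4
        assert false_hits / tests <= 0.005

    def test_sample_mismatch_raises_alignment_error(self, rng):
        pcs = self._pcs(rng, n=50)
        traits = pd.DataFrame(
            rng.standard_normal((49, 2)), index=[f"s{i}" for i in range(49)], columns=list("AB")
        )
        with pytest.raises(AlignmentError):
            select_instruments(pcs, traits)

    def test_report_lists_surviving_pc_trait_pairs(self, rng):
        pcs = self._pcs(rng, n=2000)
        y = 0.6 * (pcs.scores["PC1"] / pcs.scores["PC1"].std()) + rng.standard_normal(2000)
        traits = pd.DataFrame({"T": y.to_numpy()}, index=pcs.scores.index)
        selected, report = select_instruments(pcs, traits, alpha=0.001)
        assert {"pc", "trait", "beta", "p"} <= set(report.columns)
        assert (report["p"] < 0.001).all()
        assert selected.selected.get("PC1") == ["T"]
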