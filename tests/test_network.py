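"""Coexpression stage: soft threshold, TOM, modules, eigengenes, GS/MM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from dormabreak import (
    ExpressionMatrix,
    adjacency,
    detect_modules,
    gene_trait_statistics,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    significant_modules,
    topological_overlap,
)
from dormabreak.errors import ValidationError
from dormabreak.network import WeightedCoexpressionNetwork, correlation_pvalue
from dormabreak.simulate import ExpressionSimConfig, simulate_expression


def _expr_from_log(log_values, trait=None):
    """FPKM matrix whose log1p transform equals `log_values` up to a
    global shift (correlation-preserving), so tests can reason on the
    log scale exactly."""
    log_values = np.asarray(log_values, dtype=float)
    shift = 0.1 - log_values.min()
    n_genes, n_samples = log_values.shape
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=np.expm1(log_values + shift),
        trait=np.arange(n_samples, dtype=float) if trait is None else trait,
    )


class TestSoftThreshold:
    def test_too_few_genes_rejected(self):
        expr = _expr_from_log(np.random.default_rng(0).normal(size=(2, 9)))
        with pytest.raises(ValidationError, match="too few genes"):
            pick_soft_threshold(expr)

    def test_too_few_samples_rejected(self):
        expr = _expr_from_log(np.random.default_rng(0).normal(size=(40, 3)))
        with pytest.raises(ValidationError, match="too few samples"):
            pick_soft_threshold(expr)

    def test_planted_power_law_structure_reaches_scale_free_fit(self):
        """Hub-dominated module-size spectrum: chosen beta fits a power law.

        Module sizes follow a decaying power law, so gene connectivity is
        spread over decades; the chosen power should reach the standard
        scale-free fit criterion (median over seeds, R^2 >= 0.85).
        """
        sizes = tuple(int(round(150 * r**-0.7)) for r in range(1, 50) if 150 * r**-0.7 >= 3)
        trait = tuple(np.linspace(0, 100, 60))
        r2s = []
        for seed in range(5):
            cfg = ExpressionSimConfig(
                seed=seed,
                n_genes=sum(sizes),
                module_sizes=sizes,
                module_r=tuple([0.0] * len(sizes)),
                n_samples=60,
                trait=trait,
                noise_sd=0.5,
            )
            sim = simulate_expression(cfg)
            st = pick_soft_threshold(sim.expr, powers=tuple(range(1, 21)))
            row = st.table[st.table.power == st.beta].iloc[0]
            assert row.slope < 0
            r2s.append(row.scale_free_r2)
        assert np.median(r2s) >= 0.85

    def test_mean_connectivity_decreases_with_power(self):
        sim = simulate_expression(ExpressionSimConfig(seed=0, n_genes=120, module_sizes=(40,), module_r=(0.9,)))
        st = pick_soft_threshold(sim.expr, powers=(1, 4, 8, 16))
        k = st.table.mean_connectivity.to_numpy()
        assert np.all(np.diff(k) < 0)


class TestAdjacencyAndTOM:
    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=9)
        logs = np.vstack([base, 2 * base + 1.0] + [rng.normal(size=9) for _ in range(3)])
        expr = _expr_from_log(logs)
        a = adjacency(expr, beta=26)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 0] == 0.0

    def test_high_power_crushes_weak_correlations(self):
        rng = np.random.default_rng(2)
        expr = _expr_from_log(rng.normal(size=(40, 30)))
        a = adjacency(expr, beta=26)
        off = a.values[np.triu_indices(40, 1)]
        assert off.max() < 1e-3

    def test_tom_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        expr = _expr_from_log(rng.normal(size=(12, 9)))
        a = adjacency(expr, beta=6)
        tom = topological_overlap(a).values
        av = a.values
        k = av.sum(axis=0)
        n = 12
        oracle = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    oracle[i, j] = 1.0
                    continue
                shared = sum(av[i, u] * av[u, j] for u in range(n))
                oracle[i, j] = (shared + av[i, j]) / (min(k[i], k[j]) + 1 - av[i, j])
        np.testing.assert_allclose(tom, oracle, atol=1e-9)

    def test_tom_symmetric_unit_interval(self):
        sim = simulate_expression(ExpressionSimConfig(seed=4, n_genes=80, module_sizes=(30,), module_r=(0.9,)))
        tom = topological_overlap(adjacency(sim.expr, beta=12)).values
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        assert np.allclose(np.diag(tom), 1.0)

    def test_constant_gene_excluded_with_warning(self):
        logs = np.vstack([np.zeros(9), np.random.default_rng(5).normal(size=(39, 9))])
        expr = _expr_from_log(logs)
        with pytest.warns(UserWarning, match="zero-variance"):
            a = adjacency(expr, beta=2)
        assert "g0" not in a.index


class TestDetectModules:
    def _block_expr(self, sizes, n_samples=9, seed=0, cross=0.0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for b, size in enumerate(sizes):
            latent = rng.normal(size=n_samples)
            for _ in range(size):
                rows.append(latent + rng.normal(0, 0.05, n_samples))
                labels.append(b)
        return _expr_from_log(np.asarray(rows)), np.asarray(labels)

    def test_two_planted_blocks_recovered_exactly(self):
        expr, truth = self._block_expr([50, 50])
        tom = topological_overlap(adjacency(expr, beta=6))
        labels = detect_modules(tom, min_module_size=10)
        assert labels.nunique() == 2
        ct = pd.crosstab(labels, pd.Series(truth, index=expr.gene_ids))
        assert (ct.max(axis=1) == ct.sum(axis=1)).all()  # pure clusters

    def test_small_block_left_unassigned(self):
        expr, _ = self._block_expr([50, 10])
        tom = topological_overlap(adjacency(expr, beta=6))
        labels = detect_modules(tom, min_module_size=30)
        assert (labels == "unassigned").sum() == 10
        assert labels.nunique() == 2

    def test_largest_module_gets_first_colour(self):
        expr, truth = self._block_expr([60, 40])
        tom = topological_overlap(adjacency(expr, beta=6))
        labels = detect_modules(tom, min_module_size=10)
        sizes = labels.value_counts()
        assert sizes.index[0] == "turquoise" and sizes.iloc[0] == 60
        assert sizes.index[1] == "blue"

    def test_invariant_to_gene_input_order(self):
        expr, _ = self._block_expr([30, 25], seed=3)
        tom = topological_overlap(adjacency(expr, beta=6))
        shuffled = tom.sample(frac=1.0, axis=0, random_state=0)
        shuffled = shuffled[shuffled.index]
        a = detect_modules(tom, min_module_size=5)
        b = detect_modules(shuffled, min_module_size=5)
        assert a.sort_index().equals(b.sort_index())

    def test_min_module_size_validated(self):
        with pytest.raises(ValidationError):
            detect_modules(pd.DataFrame(np.eye(3)), min_module_size=1)

    def test_planted_six_module_design_ari(self):
        """Study-shaped planted design is recovered with high ARI."""
        aris = []
        for seed in range(3):
            sim = simulate_expression(ExpressionSimConfig(seed=seed))
            res = WeightedCoexpressionNetwork(sim.expr).fit(beta=26)
            labels = res.assignment.labels
            aris.append(adjusted_rand_score(sim.labels.loc[labels.index], labels))
        assert np.mean(aris) >= 0.9


class TestEigengenes:
    def test_rank_one_module_recovers_shared_profile(self):
        rng = np.random.default_rng(6)
        latent = rng.normal(size=9)
        logs = np.vstack([2.0 * latent + b for b in range(5)])
        expr = _expr_from_log(logs)
        labels = pd.Series("m", index=expr.gene_ids)
        me = module_eigengene(expr, labels).loc["m"].to_numpy()
        z = (latent - latent.mean()) / np.linalg.norm(latent - latent.mean())
        assert np.allclose(me, z, atol=1e-9) or np.allclose(me, -z, atol=1e-9)
        assert np.corrcoef(me, latent)[0, 1] > 0  # orientation

    def test_unit_norm_and_rayleigh_optimality(self):
        sim = simulate_expression(ExpressionSimConfig(seed=7, n_genes=40, module_sizes=(30,), module_r=(0.8,)))
        me = module_eigengene(sim.expr, sim.labels).loc["M1"].to_numpy()
        assert np.linalg.norm(me) == pytest.approx(1.0)
        logs = np.log1p(sim.expr.values[:30])
        xs = (logs - logs.mean(axis=1, keepdims=True)) / logs.std(axis=1, keepdims=True)
        var_me = np.sum((xs @ me) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            v = rng.normal(size=me.size)
            v /= np.linalg.norm(v)
            assert np.sum((xs @ v) ** 2) <= var_me + 1e-9

    def test_global_sign_flip_is_absorbed(self):
        rng = np.random.default_rng(8)
        latent = rng.normal(size=9)
        logs = np.vstack([1.5 * latent + rng.normal(0, 0.1, 9) for _ in range(6)])
        labels = pd.Series("m", index=[f"g{i}" for i in range(6)])
        me1 = module_eigengene(_expr_from_log(logs), labels).loc["m"]
        me2 = module_eigengene(_expr_from_log(-logs), labels).loc["m"]
        # orientation makes each eigengene track its members; mirrored
        # members give opposite eigengenes
        assert np.corrcoef(me1, me2)[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_constant_module_rejected(self):
        expr = _expr_from_log(np.zeros((3, 9)))
        labels = pd.Series("m", index=expr.gene_ids)
        with pytest.raises(ValidationError):
            module_eigengene(expr, labels)


class TestTraitStatistics:
    def test_eigengene_equal_to_trait_is_significant(self):
        trait = np.array([0, 10, 20, 40, 50, 60, 80, 90, 100], dtype=float)
        me = pd.DataFrame({"s%d" % j: [v] for j, v in enumerate(trait)}, index=["m"])
        mt = module_trait_correlation(me, trait)
        assert mt.loc["m", "cor"] == pytest.approx(1.0)
        assert significant_modules(mt) == ["m"]

    def test_threshold_one_yields_empty_set(self):
        rng = np.random.default_rng(9)
        me = pd.DataFrame(rng.normal(size=(4, 9)), index=list("abcd"))
        mt = module_trait_correlation(me, rng.normal(size=9))
        assert significant_modules(mt, min_abs_cor=1.0) == []

    def test_constant_trait_rejected(self):
        me = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 9)))
        with pytest.raises(ValidationError, match="constant"):
            module_trait_correlation(me, np.full(9, 5.0))

    def test_planted_trait_modules_pass_at_point_nine(self):
        hits = 0
        for seed in range(10):
            sim = simulate_expression(ExpressionSimConfig(seed=seed))
            me = module_eigengene(sim.expr, sim.labels)  # planted labels
            mt = module_trait_correlation(me, sim.expr.trait)
            sig = significant_modules(mt, min_abs_cor=0.9)
            hits += sig == ["M1", "M2"]
        assert hits >= 9

    def test_gs_mm_match_direct_recomputation(self):
        sim = simulate_expression(
            ExpressionSimConfig(seed=10, n_genes=120, module_sizes=(40, 30), module_r=(0.9, 0.0))
        )
        labels = sim.labels
        me = module_eigengene(sim.expr, labels)
        stats = gene_trait_statistics(sim.expr, sim.expr.trait, labels, me)
        logs = np.log1p(sim.expr.values)
        rng = np.random.default_rng(1)
        for idx in rng.choice(120, size=50, replace=False):
            gene = sim.expr.gene_ids[idx]
            gs_direct, p_direct = sps.pearsonr(logs[idx], sim.expr.trait)
            assert stats.loc[gene, "gs"] == pytest.approx(gs_direct, abs=1e-9)
            assert stats.loc[gene, "p_gs"] == pytest.approx(p_direct, abs=1e-9)
            module = labels[gene]
            if module != "background":
                mm_direct, pm_direct = sps.pearsonr(logs[idx], me.loc[module])
                assert stats.loc[gene, "mm"] == pytest.approx(mm_direct, abs=1e-9)
                assert stats.loc[gene, "p_mm"] == pytest.approx(pm_direct, abs=1e-9)

    def test_gene_identical_to_trait_has_unit_gs(self):
        trait = np.linspace(1, 9, 9)
        logs = np.vstack([trait, np.random.default_rng(2).normal(size=(3, 9))])
        expr = _expr_from_log(logs, trait=trait)
        labels = pd.Series("m", index=expr.gene_ids)
        me = module_eigengene(expr, labels)
        stats = gene_trait_statistics(expr, trait, labels, me)
        assert stats.loc["g0", "abs_gs"] == pytest.approx(1.0)

    def test_pvalue_closed_form_seven_degrees_of_freedom(self):
        # with 9 samples: t = r sqrt(7) / sqrt(1 - r^2)
        for r in (0.1, 0.5, 0.9):
            t = r * np.sqrt(7) / np.sqrt(1 - r**2)
            expected = 2 * sps.t.sf(t, df=7)
            assert correlation_pvalue(r, 9) == pytest.approx(expected, rel=1e-12)
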