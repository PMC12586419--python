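"""Major-gene promotion, fixed+kernel model, marker selection, structure."""

import numpy as np
import pytest

from wheatgs.cv import FeatureSet, make_genotype_folds, run_cv
from wheatgs.fixedfx import (
    FixedKernelRegressor,
    add_structure_covariates,
    evaluate_single_marker_fixed,
    fit_fixed_random,
    promote_markers_to_fixed,
    run_strategy_comparison,
    select_trait_specific_markers,
)
from wheatgs.models import RKHSRegressor
from wheatgs.qc import compute_gaussian_kernel, ordinate_genotypes
from wheatgs.simulate import (
    MajorGeneSpec,
    SimConfig,
    simulate_genotypes,
    simulate_major_genes,
)

MCMC_FAST = dict(n_iter=800, burn_in=250, thin=2)


def _panel_with_genes(n=80, p=150, n_genes=3, seed=0, effect=1.0):
    specs = tuple(
        MajorGeneSpec(f"gene{i}", i + 1, 0.4, effect, ("t",))
        for i in range(n_genes)
    )
    cfg = SimConfig(n_genotypes=n, n_markers=p, n_chromosomes=max(5, n_genes),
                    missing_rate=0.0, major_genes=specs, traits=("t",),
                    seed=seed)
    panel = simulate_genotypes(cfg)
    panel, genes = simulate_major_genes(panel, specs, seed=seed + 1)
    return panel, genes


class TestPromotion:
    def test_zero_promotion_is_identity(self):
        panel, genes = _panel_with_genes()
        promo, reduced = promote_markers_to_fixed(panel, genes, [])
        assert promo.X.shape == (80, 1)
        assert reduced.n_markers == panel.n_markers

    def test_column_bookkeeping_for_full_promotion(self):
        panel, genes = _panel_with_genes(n_genes=3)
        promo, reduced = promote_markers_to_fixed(panel, genes, list(genes.names))
        assert promo.X.shape[1] == 4  # intercept + 3 genes
        assert reduced.n_markers == panel.n_markers - 3
        # conservation: promoted tags + remaining random = original universe
        assert len(promo.removed_random_columns) + reduced.n_markers == panel.n_markers

    def test_perfect_ld_column_dropped_with_log(self):
        panel, genes = _panel_with_genes(n_genes=2)
        genes.calls[:, 1] = genes.calls[:, 0]  # duplicate locus
        promo, _ = promote_markers_to_fixed(panel, genes, list(genes.names))
        assert promo.X.shape[1] == 2
        assert promo.dropped_aliased == ["gene1"]

    def test_double_promotion_and_unknown_marker_rejected(self):
        panel, genes = _panel_with_genes(n_genes=2)
        with pytest.raises(ValueError, match="twice"):
            promote_markers_to_fixed(panel, genes, ["gene0", "gene0"])
        with pytest.raises(ValueError, match="unknown"):
            promote_markers_to_fixed(panel, genes, ["nope"])

    def test_all_missing_calls_rejected(self):
        panel, genes = _panel_with_genes(n_genes=1)
        genes.calls[:, 0] = np.nan
        with pytest.raises(ValueError, match="no genotype calls"):
            promote_markers_to_fixed(panel, genes, ["gene0"])


class TestFixedKernelModel:
    def test_intercept_only_matches_plain_rkhs(self):
        rng = np.random.default_rng(1)
        panel, genes = _panel_with_genes(seed=2)
        K = compute_gaussian_kernel(panel, 0.5).K
        y = rng.normal(0, 1, 80) + K @ rng.normal(0, 1, 80)
        F = np.hstack([np.ones((80, 1)), K])
        fx = FixedKernelRegressor(n_fixed=1, n_iter=12000, burn_in=2000,
                                  random_state=5).fit(F, y)
        rk = RKHSRegressor(n_iter=12000, burn_in=2000, random_state=9).fit(K, y)
        r = np.corrcoef(fx.predict(F), rk.predict(K))[0, 1]
        assert r > 0.999

    def test_recovers_promoted_gene_effect_within_ten_percent(self):
        true_beta = 5.0
        panel, genes = _panel_with_genes(n=300, p=200, n_genes=1, seed=3)
        rng = np.random.default_rng(3)
        y = true_beta * genes.calls[:, 0] + rng.normal(0, 1.0, 300)
        promo, reduced = promote_markers_to_fixed(panel, genes, ["gene0"])
        K = compute_gaussian_kernel(reduced, 0.5).K
        fit = fit_fixed_random(y, promo.X, K, n_iter=2000, burn_in=500,
                               random_state=7)
        assert fit.beta_[1] == pytest.approx(true_beta, rel=0.10)

    def test_promoting_a_large_gene_beats_leaving_it_random(self):
        margins = []
        for seed in range(20):
            panel, genes = _panel_with_genes(n=100, p=120, n_genes=1,
                                             seed=40 + seed, effect=2.5)
            rng = np.random.default_rng(seed)
            cfg = SimConfig(n_genotypes=100, n_markers=120, var_g=1.0,
                            missing_rate=0.0, traits=("t",), seed=40 + seed)
            # polygenic part from the panel + the major gene (>20% of var_g)
            X = panel.dosage - panel.dosage.mean(0)
            g_poly = X @ rng.normal(0, 1, 120)
            g_poly = g_poly / g_poly.std()
            y = g_poly + 2.5 * genes.calls[:, 0] + rng.normal(0, 0.7, 100)
            plan = make_genotype_folds(panel.genotype_ids, 5, 1, seed=seed)
            promo, reduced = promote_markers_to_fixed(panel, genes, ["gene0"])
            K_red = compute_gaussian_kernel(reduced, 0.5).K
            K_full = compute_gaussian_kernel(panel, 0.5).K
            f_fix = FeatureSet(genotype_ids=panel.genotype_ids, K=K_red,
                               X_fixed=promo.X)
            f_rand = FeatureSet(genotype_ids=panel.genotype_ids, K=K_full,
                                X_fixed=np.ones((100, 1)))
            r_fix = run_cv(FixedKernelRegressor(n_fixed=promo.X.shape[1],
                                                **MCMC_FAST),
                           y, f_fix, plan)
            r_rand = run_cv(FixedKernelRegressor(n_fixed=1, **MCMC_FAST),
                            y, f_rand, plan)
            margins.append(np.nanmedian(r_fix.abilities)
                           - np.nanmedian(r_rand.abilities))
        assert np.median(margins) > 0


class TestSelection:
    def test_rule_application(self):
        deltas = {"A": 0.02, "B": -0.01, "C": 0.001}
        assert select_trait_specific_markers(deltas) == ["A", "C"]
        assert select_trait_specific_markers({"A": -0.1, "B": 0.0}) == []

    def test_null_marker_median_delta_near_zero(self):
        meds = []
        for seed in range(6):
            panel, genes = _panel_with_genes(n=80, p=100, n_genes=1,
                                             seed=60 + seed, effect=0.0)
            rng = np.random.default_rng(seed)
            X = panel.dosage - panel.dosage.mean(0)
            g = X @ rng.normal(0, 1, 100)
            y = g / g.std() + rng.normal(0, 1, 80)
            plan = make_genotype_folds(panel.genotype_ids, 5, 2, seed=seed)
            base_feats = FeatureSet(
                genotype_ids=panel.genotype_ids,
                K=compute_gaussian_kernel(panel, 0.5).K,
                X_fixed=np.ones((80, 1)))
            base = run_cv(FixedKernelRegressor(n_fixed=1, **MCMC_FAST),
                          y, base_feats, plan, model_name="90K")
            _, med, _ = evaluate_single_marker_fixed(
                "gene0", panel, genes, y, plan, base, mcmc=MCMC_FAST)
            meds.append(med)
        assert abs(np.median(meds)) < 0.02

    def test_unpaired_comparison_refused(self):
        panel, genes = _panel_with_genes(n=60, p=80, n_genes=1, seed=9)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 60)
        plan_a = make_genotype_folds(panel.genotype_ids, 5, 1, seed=1)
        plan_b = make_genotype_folds(panel.genotype_ids, 5, 1, seed=2)
        base_feats = FeatureSet(
            genotype_ids=panel.genotype_ids,
            K=compute_gaussian_kernel(panel, 0.5).K,
            X_fixed=np.ones((60, 1)))
        base = run_cv(FixedKernelRegressor(n_fixed=1, **MCMC_FAST), y,
                      base_feats, plan_a)
        with pytest.raises(ValueError, match="unpaired"):
            evaluate_single_marker_fixed("gene0", panel, genes, y, plan_b,
                                         base, mcmc=MCMC_FAST)


class TestStructureCovariates:
    def test_append_and_bounds(self, random_panel):
        structure = ordinate_genotypes(random_panel, "PCA", 5)
        X = np.ones((random_panel.n_genotypes, 1))
        assert add_structure_covariates(X, structure, 0) is X
        X5 = add_structure_covariates(X, structure, 5)
        assert X5.shape[1] == 6
        with pytest.raises(ValueError):
            add_structure_covariates(X, structure, 6)


class TestStrategyComparison:
    def test_shared_plan_and_labels(self):
        panel, genes = _panel_with_genes(n=60, p=80, n_genes=2, seed=30,
                                         effect=1.5)
        rng = np.random.default_rng(30)
        X = panel.dosage - panel.dosage.mean(0)
        g = X @ rng.normal(0, 1, 80)
        y = g / g.std() + 1.5 * (genes.calls @ np.ones(2)) + rng.normal(0, 1, 60)
        plan = make_genotype_folds(panel.genotype_ids, 5, 1, seed=30)
        structure = ordinate_genotypes(panel, "PCA", 5)
        out = run_strategy_comparison(panel, genes, y, plan, mcmc=MCMC_FAST,
                                      structure=structure)
        labels = set(out["results"])
        assert {"90K", "90K + Major genes",
                "90K + Major genes (fixed effect)",
                "90K + Selected Major genes (fixed effect)"} <= labels
        assert "PCA" in labels
        assert len(out["audit"]) == 2
        for res in out["results"].values():
            assert res.fold_test_indices.keys() == out["results"]["90K"].fold_test_indices.keys()

    def test_selection_optimism_is_quantifiable(self):
        """Selecting on the evaluation folds is at least as rosy as fresh folds."""
        same, fresh = [], []
        for seed in range(5):
            panel, genes = _panel_with_genes(n=60, p=80, n_genes=2,
                                             seed=80 + seed, effect=0.0)
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, 60)  # null trait: any gain is optimism
            plan = make_genotype_folds(panel.genotype_ids, 5, 1, seed=seed)
            plan2 = make_genotype_folds(panel.genotype_ids, 5, 1, seed=seed + 99)
            out_same = run_strategy_comparison(panel, genes, y, plan,
                                               mcmc=MCMC_FAST)
            out_fresh = run_strategy_comparison(panel, genes, y, plan,
                                                mcmc=MCMC_FAST,
                                                selection_plan=plan2)
            base = np.nanmedian(out_same["results"]["90K"].abilities)
            same.append(np.nanmedian(
                out_same["results"]["90K + Selected Major genes (fixed effect)"].abilities) - base)
            fresh.append(np.nanmedian(
                out_fresh["results"]["90K + Selected Major genes (fixed effect)"].abilities) - base)
        assert np.mean(same) >= np.mean(fresh) - 0.02
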