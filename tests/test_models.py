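"""Prediction models: hand oracles, cross-model equivalences, contracts."""

import numpy as np
import pandas as pd
import pytest

from wheatgs.models import (
    GBLUP,
    BayesianRidgeRegressor,
    PenalizedMarkerRegressor,
    RKHSRegressor,
    RandomForestWrapper,
    SVMRegressor,
    make_model,
)
from wheatgs.panel import MarkerPanel
from wheatgs.qc import compute_grm


def _random_panel(rng, n, p):
    freqs = rng.uniform(0.1, 0.9, p)
    X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    return X


def _grm(X):
    p = X.mean(axis=0) / 2
    c = 2 * np.sum(p * (1 - p))
    W = X - 2 * p
    return W @ W.T / c, W, c


class TestGBLUP:
    def test_interpolation_limit_recovers_observations(self):
        rng = np.random.default_rng(0)
        X = _random_panel(rng, 40, 120)
        G, _, _ = _grm(X)
        y = rng.normal(0, 1, 40)
        fit = GBLUP(var_ratio=1e6).fit(G + 1e-8 * np.eye(40), y)
        assert np.abs(fit.predict(G + 1e-8 * np.eye(40)) - y).max() < 1e-4

    def test_identity_relationship_shares_no_information(self):
        rng = np.random.default_rng(1)
        y = rng.normal(5, 1, 30)
        fit = GBLUP(var_ratio=1.0).fit(np.eye(30), y)
        # held-out genotype: zero relationship row -> prediction is mu_hat
        assert fit.predict(np.zeros((3, 30))) == pytest.approx(fit.mu_)
        # training BLUPs are shrunken deviations
        dev = y - fit.mu_
        assert (np.abs(fit.u_) <= np.abs(dev) + 1e-10).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_equivalence_with_ridge_marker_regression(self, seed):
        """GBLUP with G = WW'/c equals ridge on W at lam = c s2e/s2g."""
        rng = np.random.default_rng(100 + seed)
        X = _random_panel(rng, 50, 300)
        G, W, c = _grm(X)
        y = W @ rng.normal(0, 0.1, 300) + rng.normal(0, 1, 50)
        tr = np.arange(40)
        te = np.arange(40, 50)
        var_ratio = 2.0  # s2g / s2e
        fit = GBLUP(var_ratio=var_ratio).fit(G[np.ix_(tr, tr)], y[tr])
        pred_gblup = fit.predict(G[np.ix_(te, tr)])
        # independent oracle: closed-form ridge on centred dosages
        lam = c / var_ratio
        Wt = W[tr]
        beta = np.linalg.solve(Wt.T @ Wt + lam * np.eye(300), Wt.T @ (y[tr] - fit.mu_))
        pred_ridge = fit.mu_ + W[te] @ beta
        assert np.abs(pred_gblup - pred_ridge).max() < 1e-6

    def test_reml_recovers_variance_ratio_order(self):
        rng = np.random.default_rng(5)
        X = _random_panel(rng, 150, 400)
        G, W, c = _grm(X)
        g_true = W @ rng.normal(0, np.sqrt(3.0 / c), 400)
        y_high = g_true + rng.normal(0, 0.5, 150)
        y_low = g_true + rng.normal(0, 3.0, 150)
        hi = GBLUP().fit(G, y_high)
        lo = GBLUP().fit(G, y_low)
        assert hi.var_g_ / hi.var_e_ > lo.var_g_ / lo.var_e_
        assert (hi.pev_ > 0).all()

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            GBLUP().fit(bad, np.array([0.0, 1.0]))


class TestPenalized:
    def test_huge_lambda_shrinks_to_training_mean(self):
        rng = np.random.default_rng(2)
        X = _random_panel(rng, 30, 50)
        y = rng.normal(3, 1, 30)
        for pen in ("l1", "l2"):
            fit = PenalizedMarkerRegressor(pen, lambda_grid=[1e9]).fit(X, y)
            assert np.abs(fit.beta_).max() < 1e-6
            assert fit.predict(X) == pytest.approx(y.mean(), abs=1e-6)

    def test_l2_at_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(3)
        X = _random_panel(rng, 60, 10)
        y = rng.normal(0, 1, 60)
        fit = PenalizedMarkerRegressor("l2", lambda_grid=[0.0]).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        beta_ols, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
        assert np.abs(fit.beta_ - beta_ols).max() < 1e-8

    def test_l1_zeroes_null_markers_in_sparse_toy(self):
        rng = np.random.default_rng(4)
        X = _random_panel(rng, 100, 5)
        y = 4.0 * X[:, 2] + rng.normal(0, 0.3, 100)
        fit = PenalizedMarkerRegressor("l1", n_lambdas=50, random_state=7).fit(X, y)
        null_beta = np.delete(fit.beta_, 2)
        assert fit.beta_[2] != 0.0
        assert (null_beta == 0.0).sum() >= 3

    def test_l1_path_satisfies_subgradient_conditions(self):
        """KKT check: |x_j'r/n| <= lam for zero coefs, = lam at active ones."""
        rng = np.random.default_rng(5)
        X = _random_panel(rng, 50, 20)
        y = X[:, 0] - 2 * X[:, 5] + rng.normal(0, 0.5, 50)
        m = PenalizedMarkerRegressor("l1", n_lambdas=20)
        Xs, _, _ = m._standardize(X)
        yc = y - y.mean()
        grid = m._grid(Xs, yc)
        betas = m._path(Xs, yc, grid)
        for i, lam in enumerate(grid):
            b = betas[:, i]
            grad = Xs.T @ (yc - Xs @ b) / len(y)
            if (b == 0).any():
                assert np.abs(grad[b == 0]).max() <= lam + 1e-5
            if (b != 0).any():
                assert np.abs(np.abs(grad[b != 0]) - lam).max() < 1e-5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PenalizedMarkerRegressor("l2", lambda_grid=[]).fit(
                np.ones((4, 2)), np.zeros(4))


class TestBRR:
    def test_fixed_variances_match_ridge_solution(self):
        """With variances frozen the posterior mean is the ridge estimate."""
        rng = np.random.default_rng(6)
        X = _random_panel(rng, 60, 80)
        y = (X[:, 0] - X[:, 1]) * 0.7 + rng.normal(0, 1, 60)
        s2b, s2e = 0.05, 1.0
        fit = BayesianRidgeRegressor(
            n_iter=20000, burn_in=2000, thin=1, fix_variances=(s2b, s2e),
            random_state=11).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        lam = s2e / s2b
        ridge = np.linalg.solve(Xs.T @ Xs + lam * np.eye(80), Xs.T @ (y - y.mean()))
        rmse = np.sqrt(np.mean((fit.beta_ - ridge) ** 2))
        assert rmse < 0.02

    def test_null_response_gives_null_effects(self):
        rng = np.random.default_rng(7)
        X = _random_panel(rng, 50, 40)
        fit = BayesianRidgeRegressor(n_iter=3000, burn_in=1000,
                                     random_state=3).fit(X, np.zeros(50))
        assert np.abs(fit.beta_).max() < 0.05

    def test_seed_reproducibility_and_chain_stability(self):
        rng = np.random.default_rng(8)
        X = _random_panel(rng, 200, 500)
        y = X @ rng.normal(0, 0.05, 500) + rng.normal(0, 1, 200)
        kw = dict(n_iter=3000, burn_in=1000)
        a = BayesianRidgeRegressor(random_state=1, **kw).fit(X, y)
        b = BayesianRidgeRegressor(random_state=1, **kw).fit(X, y)
        c = BayesianRidgeRegressor(random_state=2, **kw).fit(X, y)
        np.testing.assert_array_equal(a.beta_, b.beta_)
        r = np.corrcoef(a.predict(X), c.predict(X))[0, 1]
        assert r > 0.99


class TestRKHS:
    def test_constant_kernel_collapses_to_intercept(self):
        rng = np.random.default_rng(9)
        y = rng.normal(4, 1, 30)
        K = np.ones((30, 30))
        fit = RKHSRegressor(n_iter=3000, burn_in=1000, random_state=1).fit(K, y)
        pred = fit.predict(np.ones((5, 30)))
        assert np.abs(pred - y.mean()).max() < 0.3
        assert np.std(pred) < 1e-8

    def test_linear_kernel_matches_gblup(self):
        rng = np.random.default_rng(10)
        X = _random_panel(rng, 80, 200)
        G, W, c = _grm(X)
        y = W @ rng.normal(0, 0.1, 200) + rng.normal(0, 0.8, 80)
        tr, te = np.arange(60), np.arange(60, 80)
        Gj = G + 1e-8 * np.eye(80)
        gb = GBLUP().fit(Gj[np.ix_(tr, tr)], y[tr])
        rk = RKHSRegressor(n_iter=6000, burn_in=2000, random_state=4,
                           fix_variances=(gb.var_g_, gb.var_e_)).fit(
            Gj[np.ix_(tr, tr)], y[tr])
        r = np.corrcoef(gb.predict(Gj[np.ix_(te, tr)]),
                        rk.predict(Gj[np.ix_(te, tr)]))[0, 1]
        assert r > 0.99

    def test_epistatic_trait_favors_gaussian_kernel(self):
        """Pairwise-product architecture: RKHS beats GBLUP on held-out lines."""
        from wheatgs.qc import compute_gaussian_kernel

        wins_margin = []
        n, p = 120, 30
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.binomial(2, rng.uniform(0.2, 0.8, p), size=(n, p)).astype(float)
            Xc = X - X.mean(0)  # centred products: purely non-additive signal
            inter = np.column_stack([
                Xc[:, i] * Xc[:, j]
                for i in range(10) for j in range(i + 1, 10)])
            y = inter @ rng.normal(0, 1.0, inter.shape[1])
            y = (y - y.mean()) / y.std() + rng.normal(0, 0.3, n)
            panel = MarkerPanel(
                X, pd.DataFrame({"marker": [f"m{j}" for j in range(p)],
                                 "chromosome": "1",
                                 "position_mb": np.arange(float(p))}),
                np.array([f"g{i}" for i in range(n)]), imputed=True)
            G = compute_grm(panel).G + 1e-8 * np.eye(n)
            K = compute_gaussian_kernel(panel, h=0.5).K
            tr, te = np.arange(n - 30), np.arange(n - 30, n)
            gb = GBLUP().fit(G[np.ix_(tr, tr)], y[tr])
            rk = RKHSRegressor(n_iter=1200, burn_in=400, random_state=seed).fit(
                K[np.ix_(tr, tr)], y[tr])
            r_gb = np.corrcoef(y[te], gb.predict(G[np.ix_(te, tr)]))[0, 1]
            r_rk = np.corrcoef(y[te], rk.predict(K[np.ix_(te, tr)]))[0, 1]
            wins_margin.append(r_rk - r_gb)
        assert np.mean(wins_margin) >= 0.0


class TestMLBaselines:
    def test_constant_response_predicted_everywhere(self):
        rng = np.random.default_rng(12)
        X = _random_panel(rng, 30, 20)
        y = np.full(30, 7.0)
        for model in (SVMRegressor(), RandomForestWrapper(n_trees=20)):
            pred = model.fit(X, y).predict(X + 1.0)
            assert pred == pytest.approx(7.0, abs=0.2)

    def test_single_tree_memorizes_noiseless_data(self):
        rng = np.random.default_rng(13)
        X = _random_panel(rng, 40, 15)
        X += rng.normal(0, 1e-3, X.shape)  # break ties so rows are unique
        y = rng.normal(0, 1, 40)
        fit = RandomForestWrapper(n_trees=1, mtry=15, bootstrap=False,
                                  random_state=0).fit(X, y)
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-10)

    def test_empty_marker_matrix_rejected(self):
        with pytest.raises(ValueError):
            SVMRegressor().fit(np.empty((5, 0)), np.zeros(5))


class TestCommonContract:
    @pytest.mark.parametrize("family", ["GBLUP", "RR", "LASSO"])
    def test_training_row_permutation_invariance(self, family):
        rng = np.random.default_rng(14)
        X = _random_panel(rng, 40, 60)
        G, _, _ = _grm(X)
        y = rng.normal(0, 1, 40)
        perm = rng.permutation(40)
        new = _random_panel(rng, 5, 60)
        if family == "GBLUP":
            a = GBLUP(var_ratio=1.0).fit(G, y)
            b = GBLUP(var_ratio=1.0).fit(G[np.ix_(perm, perm)], y[perm])
            rows = rng.normal(0, 0.1, (5, 40))
            p1, p2 = a.predict(rows), b.predict(rows[:, perm])
        else:
            m1 = make_model(family, random_state=0)
            m2 = make_model(family, random_state=0)
            a = m1.fit(X, y)
            # keep the inner-CV fold draw identical: permuting rows changes
            # which rows land in which inner fold, so pin lambda instead
            b = m2.set_params(lambda_grid=[a.lambda_]).fit(X[perm], y[perm])
            p1, p2 = a.predict(new), b.predict(new)
        assert np.abs(p1 - p2).max() < 1e-8

    def test_predictions_always_finite(self):
        rng = np.random.default_rng(15)
        X = _random_panel(rng, 30, 25)
        G, _, _ = _grm(X)
        y = rng.normal(0, 1, 30)
        fits = [
            GBLUP().fit(G + 1e-8 * np.eye(30), y),
            make_model("RR").fit(X, y),
            make_model("BRR", n_iter=500, burn_in=100).fit(X, y),
            make_model("SVM").fit(X, y),
            make_model("RF", n_trees=30).fit(X, y),
        ]
        for fit in fits:
            arg = G[:5, :] if isinstance(fit, GBLUP) else X[:5]
            assert np.isfinite(fit.predict(arg)).all()

    def test_accuracy_grows_with_training_size_toward_sqrt_h2(self):
        """Additive trait at h2 = 0.5: CV ability rises with n."""
        from wheatgs.cv import FeatureSet, make_genotype_folds, run_cv

        means = []
        for n in (100, 250, 500):
            abilities = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + 7 * seed + n)
                X = _random_panel(rng, n, 300)
                G, W, c = _grm(X)
                g = W @ rng.normal(0, 1, 300)
                g = g / g.std()
                y = g + rng.normal(0, 1, n)  # h2 = 0.5
                ids = np.array([f"g{i:04d}" for i in range(n)])
                feats = FeatureSet(genotype_ids=ids, G=G + 1e-8 * np.eye(n))
                plan = make_genotype_folds(ids, k=5, repeats=1, seed=seed)
                res = run_cv(GBLUP(), y, feats, plan)
                abilities.append(np.nanmean(res.abilities))
            means.append(np.mean(abilities))
        assert means[0] < means[1] < means[2]
        assert means[2] < np.sqrt(0.5) + 0.05


def test_unknown_family_rejected():
    with pytest.raises(KeyError):
        make_model("BayesZ")


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        from wheatgs.models import load_fit, save_fit

        rng = np.random.default_rng(21)
        X = _random_panel(rng, 40, 60)
        G, _, _ = _grm(X)
        y = rng.normal(0, 1, 40)
        new = rng.normal(0, 0.1, (4, 40))
        fit = GBLUP(var_ratio=1.5).fit(G, y)
        save_fit(fit, tmp_path / "gblup.json")
        back = load_fit(tmp_path / "gblup.json")
        np.testing.assert_allclose(back.predict(new), fit.predict(new))
        rrfit = PenalizedMarkerRegressor("l2", lambda_grid=[0.5]).fit(X, y)
        save_fit(rrfit, tmp_path / "rr.json")
        back = load_fit(tmp_path / "rr.json")
        np.testing.assert_allclose(back.predict(X[:5]), rrfit.predict(X[:5]))
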