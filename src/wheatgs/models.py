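"""Seven genomic prediction models under one scikit-learn fit/predict contract.

Families and their conventions (registry keys in parentheses):

* GBLUP — ``y = mu + Z g + e`` with ``g ~ N(0, G s2_g)``; spectral REML for
  (s2_g, s2_e) on the training block of the relationship matrix, BLUPs and
  per-genotype prediction error variance from the mixed-model equations.
  Held-out genotypes are predicted through their relationship rows.
* Ridge (RR) and LASSO — penalized marker regression with the shrinkage
  parameter chosen by seeded inner cross-validation minimizing MSE within the
  training set.  Ridge solves the path in closed form via SVD; LASSO uses
  cyclic coordinate descent with soft thresholding.
* BRR — Bayesian ridge regression: a Gibbs sampler with a common normal prior
  on marker effects and scaled-inverse-chi-square priors on the variances,
  run in the SVD basis of the marker matrix (one joint coefficient draw per
  iteration, identical stationary posterior to a per-marker scan).
* RKHS — Bayesian kernel regression ``y = mu + u + e``, ``u ~ N(0, K s2_u)``,
  sampled in the eigenbasis of K; held-out genotypes are predicted by kernel
  interpolation through the training-block (pseudo-)inverse.
* SVM and RF — nu-support-vector regression (RBF kernel) and random-forest
  regression, delegated to scikit-learn with the conventional genomic
  selection settings (C = 10, gamma = 0.001, nu = 0.5; 500 trees,
  mtry = p/3).

Estimators whose input is a (relationship or kernel) matrix follow the
scikit-learn "precomputed kernel" convention: ``fit`` receives the square
training block, ``predict`` the cross rows K(new, train).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GBLUP",
    "PenalizedMarkerRegressor",
    "BayesianRidgeRegressor",
    "RKHSRegressor",
    "SVMRegressor",
    "RandomForestWrapper",
    "MODEL_REGISTRY",
    "make_model",
    "save_fit",
    "load_fit",
    "fit_gblup",
    "fit_penalized",
    "fit_brr",
    "fit_rkhs",
    "fit_ml_baseline",
]


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input matrix")
    return X


def _as_y(y, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != n:
        raise ValueError(f"y has length {len(y)}, expected {n}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    return y


# --------------------------------------------------------------------------
# GBLUP
# --------------------------------------------------------------------------
class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP on a precomputed relationship matrix.

    Parameters
    ----------
    var_ratio
        Optional fixed s2_g/s2_e.  When None (default) the ratio is
        estimated by REML on the training block.
    jitter
        Ridge added to the training block diagonal if it is numerically
        singular.
    """

    input_kind = "grm"

    def __init__(self, var_ratio: float | None = None, jitter: float = 1e-8):
        self.var_ratio = var_ratio
        self.jitter = jitter

    def fit(self, X, y):
        K = _as_2d(X)
        n = K.shape[0]
        if K.shape[1] != n:
            raise ValueError("fit expects the square training relationship block")
        y = _as_y(y, n)
        w, Q = np.linalg.eigh((K + K.T) / 2.0)
        if w.min() < -1e-6 * max(1.0, abs(w.max())):
            raise ValueError("relationship matrix is not PSD within tolerance")
        w = np.maximum(w, 0.0)

        if self.var_ratio is None:
            lam = self._reml_ratio(y, w, Q)
        else:
            if self.var_ratio <= 0:
                raise ValueError("var_ratio must be positive")
            lam = float(self.var_ratio)

        # GLS intercept and residual variance at the chosen ratio
        d = lam * w + 1.0  # V / s2_e in the eigenbasis
        yt = Q.T @ y
        ones_t = Q.T @ np.ones(n)
        denom = float(np.sum(ones_t**2 / d))
        mu = float(np.sum(ones_t * yt / d) / denom)
        r = yt - mu * ones_t
        s2e = float(np.sum(r**2 / d) / max(n - 1, 1))
        if s2e <= 0:
            s2e = 1e-12
        s2g = lam * s2e

        # alpha such that g_hat(rows) = rows @ alpha for any K(new, train)
        Vinv_r = Q @ (r / d)  # V^{-1}(y - mu) * s2_e ... in original basis
        self.alpha_ = lam * Vinv_r  # = s2_g V^{-1} (y - mu 1) since V = s2_e(lam K + I)
        self.mu_ = mu
        self.var_g_ = s2g
        self.var_e_ = s2e
        self.u_ = K @ self.alpha_
        # PEV ignoring intercept uncertainty: diag(s2g K - s2g K V^-1 K s2g)
        pev_eig = s2g * w - (s2g * w) ** 2 / (s2g * w + s2e)
        self.pev_ = np.einsum("ij,j,ij->i", Q, pev_eig, Q)
        self.n_train_ = n
        return self

    @staticmethod
    def _reml_ratio(y: np.ndarray, w: np.ndarray, Q: np.ndarray) -> float:
        """Profile REML over log(s2_g/s2_e) with the intercept absorbed."""
        n = len(y)
        ones = np.ones(n)
        yt, ones_t = Q.T @ y, Q.T @ ones

        def neg_reml(log_lam: float) -> float:
            lam = np.exp(log_lam)
            d = lam * w + 1.0
            denom = np.sum(ones_t**2 / d)
            mu = np.sum(ones_t * yt / d) / denom
            r = yt - mu * ones_t
            rss = np.sum(r**2 / d)
            # -2 l_R up to constants: log|V| + log|1'V^-1 1| + (n-1) log(rss)
            return float(np.sum(np.log(d)) + np.log(denom) + (n - 1) * np.log(max(rss, 1e-300)))

        res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-8})
        return float(np.exp(res.x))

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        rows = _as_2d(X)
        if rows.shape[1] != self.n_train_:
            raise ValueError("predict expects K(new, train) rows")
        return self.mu_ + rows @ self.alpha_


# --------------------------------------------------------------------------
# Penalized marker regression (RR / LASSO)
# --------------------------------------------------------------------------
@njit(cache=False)
def _cd_lasso(XtX_diag, X, y, beta, lam, tol, max_sweeps):  # pragma: no cover - numba
    n, p = X.shape
    r = y - X @ beta
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho = rho / n + XtX_diag[j] * bj
            if rho > lam:
                new = (rho - lam) / XtX_diag[j]
            elif rho < -lam:
                new = (rho + lam) / XtX_diag[j]
            else:
                new = 0.0
            delta = new - bj
            if delta != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * delta
                beta[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return beta


class PenalizedMarkerRegressor(RegressorMixin, BaseEstimator):
    """Ridge (L2) or LASSO (L1) marker regression with inner-CV lambda choice.

    The objective is ``(1/2n)||y - mu - X b||^2 + lam * P(b)`` with
    ``P = ||b||_1`` (L1) or ``||b||_2^2 / 2`` (L2) on internally
    column-standardized markers.  The lambda grid defaults to 100 log-spaced
    values from lambda_max (the smallest lambda zeroing every L1
    coefficient) down four orders of magnitude; lambda is chosen by
    ``inner_folds``-fold CV minimizing validation MSE, then the model is
    refit on the full training set.
    """

    input_kind = "markers"

    def __init__(
        self,
        penalty: str = "l2",
        lambda_grid=None,
        n_lambdas: int = 100,
        inner_folds: int = 5,
        cd_tol: float = 1e-7,
        max_sweeps: int = 1000,
        random_state: int = 0,
    ):
        self.penalty = penalty
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.inner_folds = inner_folds
        self.cd_tol = cd_tol
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _standardize(self, X):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd, mu, sd

    def _grid(self, Xs, yc) -> np.ndarray:
        if self.lambda_grid is not None:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
            if len(grid) == 0:
                raise ValueError("lambda_grid is empty")
            if (grid < 0).any():
                raise ValueError("lambda values must be >= 0")
            return grid
        lam_max = np.abs(Xs.T @ yc).max() / len(yc)
        lam_max = max(lam_max, 1e-8)
        return np.logspace(np.log10(lam_max), np.log10(lam_max) - 4.0, self.n_lambdas)

    def _path(self, Xs, yc, grid) -> np.ndarray:
        """Coefficient path, one column per lambda (decreasing)."""
        n, p = Xs.shape
        if self.penalty == "l2":
            U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
            Uty = U.T @ yc
            betas = np.empty((p, len(grid)))
            for i, lam in enumerate(grid):
                betas[:, i] = Vt.T @ (d / (d**2 + n * lam) * Uty)
            return betas
        if self.penalty == "l1":
            diag = (Xs**2).sum(axis=0) / n
            diag = np.where(diag > 0, diag, 1.0)
            beta = np.zeros(p)
            betas = np.empty((p, len(grid)))
            for i, lam in enumerate(grid):
                beta = _cd_lasso(diag, Xs, yc, beta.copy(), lam,
                                 self.cd_tol, self.max_sweeps)
                betas[:, i] = beta
            return betas
        raise ValueError("penalty must be 'l1' or 'l2'")

    def fit(self, X, y):
        X = _as_2d(X)
        y = _as_y(y, X.shape[0])
        Xs, self.x_mean_, self.x_scale_ = self._standardize(X)
        self.mu_ = float(y.mean())
        yc = y - self.mu_
        grid = self._grid(Xs, yc)

        if len(grid) == 1:
            best = 0
        else:
            n = len(y)
            k = min(self.inner_folds, n)
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(n)
            folds = np.array_split(order, k)
            mse = np.zeros(len(grid))
            for hold in folds:
                tr = np.setdiff1d(order, hold, assume_unique=False)
                betas = self._path(Xs[tr], yc[tr] - yc[tr].mean(), grid)
                pred = Xs[hold] @ betas + yc[tr].mean()
                mse += ((yc[hold, None] - pred) ** 2).mean(axis=0)
            best = int(np.argmin(mse))  # ties resolve to the larger lambda
        self.lambda_ = float(grid[best])
        self.lambda_grid_ = grid
        self.beta_ = self._path(Xs, yc, grid[: best + 1])[:, -1]
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = _as_2d(X)
        Xs = (X - self.x_mean_) / self.x_scale_
        return self.mu_ + Xs @ self.beta_


# --------------------------------------------------------------------------
# Gibbs machinery shared by BRR / RKHS / fixed-effect kernel models
# --------------------------------------------------------------------------
def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw from the scaled-inverse-chi-square posterior (scale-sum form)."""
    return scale_sum / rng.chisquare(df)


class BayesianRidgeRegressor(RegressorMixin, BaseEstimator):
    """Bayesian ridge regression (common normal prior on marker effects).

    Priors: ``b_j ~ N(0, s2_b)``, with scaled-inverse-chi-square priors on
    ``s2_b`` and ``s2_e`` whose scales follow the R2-matched rule
    ``S_b = var(y) R2 (df0 + 2) / MSx`` (MSx = sum of marker column
    variances) and ``S_e = var(y) (1 - R2) (df0 + 2)``.  The Gibbs chain is
    run in the SVD basis of the standardized marker matrix; the component of
    the coefficient vector in the null space of X is integrated by a
    chi-square draw of its squared norm (it has no likelihood contribution).

    ``fix_variances=(s2_b, s2_e)`` freezes the variances, in which case the
    posterior mean of b equals the ridge solution at lam = s2_e/s2_b.
    """

    input_kind = "markers"

    def __init__(
        self,
        n_iter: int = 8000,
        burn_in: int = 2000,
        thin: int = 3,
        df0: float = 5.0,
        r2_prior: float = 0.5,
        fix_variances: tuple[float, float] | None = None,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2_prior = r2_prior
        self.fix_variances = fix_variances
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_2d(X)
        n, p = X.shape
        y = _as_y(y, n)
        mu0 = X.mean(axis=0)
        sd0 = X.std(axis=0)
        sd0 = np.where(sd0 > 0, sd0, 1.0)
        Xs = (X - mu0) / sd0
        self.x_mean_, self.x_scale_ = mu0, sd0

        vy = max(float(np.var(y)), 1e-12)
        msx = float((Xs.var(axis=0)).sum())
        S_b = vy * self.r2_prior * (self.df0 + 2.0) / max(msx, 1e-12)
        S_e = vy * (1.0 - self.r2_prior) * (self.df0 + 2.0)

        U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
        keep = d > max(d.max(), 1.0) * 1e-12 if d.size else np.zeros(0, bool)
        U, d, Vt = U[:, keep], d[keep], Vt[keep]
        r = len(d)

        rng = np.random.default_rng(self.random_state)
        fixed = self.fix_variances is not None
        if fixed:
            s2b, s2e = map(float, self.fix_variances)
        else:
            s2b, s2e = S_b / (self.df0 + 2.0), S_e / (self.df0 + 2.0)
        mu = float(y.mean())
        a = np.zeros(r)

        keep_iters = range(self.burn_in, self.n_iter, self.thin)
        n_keep = len(keep_iters)
        a_sum = np.zeros(r)
        mu_sum = 0.0
        s2b_draws = np.empty(n_keep)
        s2e_draws = np.empty(n_keep)
        kept = 0
        for it in range(self.n_iter):
            # coefficients in the row space (joint draw, diagonal posterior)
            lam = s2e / s2b
            prec = d**2 + lam
            mean = d * (U.T @ (y - mu)) / prec
            a = mean + rng.standard_normal(r) * np.sqrt(s2e / prec)
            fitted = U @ (d * a)
            resid = y - mu - fitted
            mu = float(rng.normal(resid.mean() + mu, np.sqrt(s2e / n)))
            resid = y - mu - fitted
            if not fixed:
                bb = float(a @ a)
                if p > r:
                    bb += s2b * rng.chisquare(p - r)
                s2b = _scaled_inv_chi2(rng, self.df0 + p, bb + S_b)
                s2e = _scaled_inv_chi2(rng, self.df0 + n, float(resid @ resid) + S_e)
            if not (np.isfinite(s2b) and np.isfinite(s2e) and np.isfinite(a).all()):
                raise FloatingPointError(f"non-finite Gibbs draw at iteration {it}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                a_sum += a
                mu_sum += mu
                s2b_draws[kept] = s2b
                s2e_draws[kept] = s2e
                kept += 1
        a_bar = a_sum / kept
        self.beta_ = Vt.T @ a_bar  # null-space posterior mean is zero
        self.mu_ = mu_sum / kept
        self.var_b_ = float(np.mean(s2b_draws[:kept])) if not fixed else s2b
        self.var_e_ = float(np.mean(s2e_draws[:kept])) if not fixed else s2e
        self.n_kept_ = kept
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = _as_2d(X)
        Xs = (X - self.x_mean_) / self.x_scale_
        return self.mu_ + Xs @ self.beta_


class RKHSRegressor(RegressorMixin, BaseEstimator):
    """Bayesian kernel regression on a precomputed (Gaussian) kernel.

    ``y = mu + u + e`` with ``u ~ N(0, K s2_u)``; the chain runs on the
    eigen-coordinates of the training kernel block with the same prior
    machinery as :class:`BayesianRidgeRegressor` (``S_u`` scaled by the mean
    kernel diagonal).  Held-out genotypes are predicted by kernel
    interpolation, ``u_new = K(new, train) K(train, train)^+ u_train``.
    """

    input_kind = "kernel"

    def __init__(
        self,
        n_iter: int = 8000,
        burn_in: int = 2000,
        thin: int = 3,
        df0: float = 5.0,
        r2_prior: float = 0.5,
        fix_variances: tuple[float, float] | None = None,
        psd_tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2_prior = r2_prior
        self.fix_variances = fix_variances
        self.psd_tol = psd_tol
        self.random_state = random_state

    def fit(self, X, y):
        K = _as_2d(X)
        n = K.shape[0]
        if K.shape[1] != n:
            raise ValueError("fit expects the square training kernel block")
        y = _as_y(y, n)
        w, Q = np.linalg.eigh((K + K.T) / 2.0)
        if w.min() < -self.psd_tol * max(1.0, abs(w.max())):
            raise ValueError("kernel is not PSD within tolerance")
        keep = w > max(w.max(), 1.0) * 1e-10
        w, Q = w[keep], Q[:, keep]
        r = len(w)
        sqw = np.sqrt(w)

        vy = max(float(np.var(y)), 1e-12)
        mean_diag = max(float(np.mean(np.diag(K))), 1e-12)
        S_u = vy * self.r2_prior * (self.df0 + 2.0) / mean_diag
        S_e = vy * (1.0 - self.r2_prior) * (self.df0 + 2.0)

        rng = np.random.default_rng(self.random_state)
        fixed = self.fix_variances is not None
        if fixed:
            s2u, s2e = map(float, self.fix_variances)
        else:
            s2u, s2e = S_u / (self.df0 + 2.0), S_e / (self.df0 + 2.0)
        mu = float(y.mean())
        delta = np.zeros(r)

        d_sum = np.zeros(r)
        mu_sum = 0.0
        s2u_sum = s2e_sum = 0.0
        kept = 0
        for it in range(self.n_iter):
            lam = s2e / s2u
            prec = w + lam
            wres = Q.T @ (y - mu)
            mean = sqw * wres / prec
            delta = mean + rng.standard_normal(r) * np.sqrt(s2e / prec)
            u = Q @ (sqw * delta)
            resid = y - mu - u
            mu = float(rng.normal(resid.mean() + mu, np.sqrt(s2e / n)))
            resid = y - mu - u
            if not fixed:
                s2u = _scaled_inv_chi2(rng, self.df0 + r, float(delta @ delta) + S_u)
                s2e = _scaled_inv_chi2(rng, self.df0 + n, float(resid @ resid) + S_e)
            if not (np.isfinite(s2u) and np.isfinite(s2e)):
                raise FloatingPointError(f"non-finite Gibbs draw at iteration {it}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                d_sum += delta
                mu_sum += mu
                s2u_sum += s2u
                s2e_sum += s2e
                kept += 1
        d_bar = d_sum / kept
        self.mu_ = mu_sum / kept
        self.var_u_ = s2u_sum / kept if not fixed else s2u
        self.var_e_ = s2e_sum / kept if not fixed else s2e
        self.u_ = Q @ (sqw * d_bar)
        # alpha = K_tt^+ u_hat, restricted to the kernel's range
        self.alpha_ = Q @ (d_bar / sqw)
        self.n_train_ = n
        self.n_kept_ = kept
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        rows = _as_2d(X)
        if rows.shape[1] != self.n_train_:
            raise ValueError("predict expects K(new, train) rows")
        return self.mu_ + rows @ self.alpha_


class SVMRegressor(RegressorMixin, BaseEstimator):
    """nu-SVR with RBF kernel on standardized markers (C=10, gamma=0.001)."""

    input_kind = "markers"

    def __init__(self, C: float = 10.0, gamma: float = 0.001, nu: float = 0.5):
        self.C = C
        self.gamma = gamma
        self.nu = nu

    def fit(self, X, y):
        X = _as_2d(X)
        if X.shape[1] == 0:
            raise ValueError("no markers")
        y = _as_y(y, X.shape[0])
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_scale_ = np.where(sd > 0, sd, 1.0)
        self.svr_ = NuSVR(C=self.C, gamma=self.gamma, nu=self.nu)
        self.svr_.fit((X - self.x_mean_) / self.x_scale_, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = _as_2d(X)
        return self.svr_.predict((X - self.x_mean_) / self.x_scale_)


class RandomForestWrapper(RegressorMixin, BaseEstimator):
    """Random-forest regression: 500 trees, mtry = floor(p/3) (min 1).

    ``mtry=None`` applies the p/3 rule; an integer overrides it (e.g. the
    full-memorization diagnostic with one unbootstrapped tree and mtry = p).
    """

    input_kind = "markers"

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 bootstrap: bool = True, random_state: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_2d(X)
        if X.shape[1] == 0:
            raise ValueError("no markers")
        y = _as_y(y, X.shape[0])
        mtry = self.mtry if self.mtry is not None else max(1, X.shape[1] // 3)
        self.rf_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=mtry,
            bootstrap=self.bootstrap,
            random_state=self.random_state,
        )
        self.rf_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "rf_")
        return self.rf_.predict(_as_2d(X))


# --------------------------------------------------------------------------
# Fit-state serialization (versioned JSON bundle)
# --------------------------------------------------------------------------
_BUNDLE_VERSION = 1


def save_fit(model, path) -> None:
    """Persist a fitted linear-state model (GBLUP/RR/LASSO/BRR/RKHS) as JSON.

    The bundle stores the constructor parameters and every fitted attribute
    (trailing underscore), with arrays as nested lists.  Tree/SVM wrappers
    hold third-party state and are not covered.
    """
    import json

    state = {}
    for key, val in vars(model).items():
        if not key.endswith("_") or key.startswith("_"):
            continue
        if isinstance(val, np.ndarray):
            state[key] = {"__array__": val.tolist()}
        elif isinstance(val, (int, float, np.floating, np.integer)):
            state[key] = float(val)
        else:
            continue  # non-serializable diagnostics are recomputable
    bundle = {
        "version": _BUNDLE_VERSION,
        "family": type(model).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()
                   if isinstance(v, (int, float, str, bool, tuple, type(None)))},
        "state": state,
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_fit(path):
    """Restore a model saved by :func:`save_fit`."""
    import json

    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {bundle.get('version')}")
    cls = {c.__name__: c for c in
           (GBLUP, PenalizedMarkerRegressor, BayesianRidgeRegressor,
            RKHSRegressor)}.get(bundle["family"])
    if cls is None:
        raise ValueError(f"cannot restore family {bundle['family']!r}")
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in bundle["params"].items()}
    model = cls(**params)
    for key, val in bundle["state"].items():
        if isinstance(val, dict) and "__array__" in val:
            setattr(model, key, np.asarray(val["__array__"]))
        else:
            setattr(model, key, val)
    return model


# --------------------------------------------------------------------------
# Registry and thin functional wrappers
# --------------------------------------------------------------------------
MODEL_REGISTRY: dict[str, type] = {
    "GBLUP": GBLUP,
    "RR": PenalizedMarkerRegressor,
    "LASSO": PenalizedMarkerRegressor,
    "BRR": BayesianRidgeRegressor,
    "RKHS": RKHSRegressor,
    "SVM": SVMRegressor,
    "RF": RandomForestWrapper,
}


def make_model(family: str, random_state: int = 0, **overrides):
    """Instantiate a registered model with its study-default hyperparameters."""
    if family not in MODEL_REGISTRY:
        raise KeyError(f"unknown model family {family!r}; choose from {sorted(MODEL_REGISTRY)}")
    cls = MODEL_REGISTRY[family]
    params: dict = {}
    if family == "RR":
        params["penalty"] = "l2"
    elif family == "LASSO":
        params["penalty"] = "l1"
    if "random_state" in cls().get_params():
        params["random_state"] = random_state
    params.update(overrides)
    return cls(**params)


def fit_gblup(y, G, var_ratio: float | None = None) -> GBLUP:
    return GBLUP(var_ratio=var_ratio).fit(G, y)


def fit_penalized(y, X_markers, penalty: str = "l2", lambda_grid=None,
                  inner_folds: int = 5, seed: int = 0) -> PenalizedMarkerRegressor:
    return PenalizedMarkerRegressor(
        penalty=penalty, lambda_grid=lambda_grid, inner_folds=inner_folds,
        random_state=seed,
    ).fit(X_markers, y)


def fit_brr(y, X_markers, seed: int = 0, **kw) -> BayesianRidgeRegressor:
    return BayesianRidgeRegressor(random_state=seed, **kw).fit(X_markers, y)


def fit_rkhs(y, K, seed: int = 0, **kw) -> RKHSRegressor:
    return RKHSRegressor(random_state=seed, **kw).fit(K, y)


def fit_ml_baseline(y, X_markers, kind: str = "SVM", seed: int = 0, **kw):
    if kind.upper() == "SVM":
        return SVMRegressor(**kw).fit(X_markers, y)
    if kind.upper() == "RF":
        return RandomForestWrapper(random_state=seed, **kw).fit(X_markers, y)
    raise ValueError("kind must be 'SVM' or 'RF'")
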