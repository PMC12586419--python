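"""Multi-environment mixed model: variance components, BLUPs, H2, LSD, CV.

The model for plot-level records is

    Y_ijk = mu + E_j + R_i(E_j) + G_k + (GE)_jk + eps_ijk

with every term except the intercept random and mutually independent:
E_j ~ N(0, s2_env), R_i(E_j) ~ N(0, s2_r), G_k ~ N(0, s2_g),
(GE)_jk ~ N(0, s2_ge), eps ~ N(0, s2_e).  Components are estimated by
EM-REML on the mixed-model equations with Aitken acceleration; unbalanced
(sparse-allocation) data are handled natively.  Genotype main-effect BLUPs
are reported on the trait scale as mu_hat + g_hat_k and serve as the pooled
phenotype for genomic prediction.

Broad-sense heritability on an entry-mean basis:

    H2 = s2_g / (s2_g + s2_ge / n_envs + s2_e / (n_reps * n_envs))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "MultiEnvFit",
    "fit_multi_env_model",
    "compute_h2",
    "compute_lsd_cv",
    "env_mean_contrast",
]

_RANDOM_TERMS = ("env", "rep_in_env", "genotype", "gxe")


@dataclass
class VarianceComponents:
    """REML variance components of the all-random multi-environment model."""

    var_g: float
    var_ge: float
    var_e: float
    var_r: float
    var_env: float
    mu: float
    n_envs: int
    n_reps: int
    df_error: int


@dataclass
class MultiEnvFit:
    """Fitted multi-environment model for one trait."""

    trait: str
    vc: VarianceComponents
    blups: pd.Series  # genotype -> mu_hat + g_hat (trait scale)
    genotype_effects: pd.Series  # shrunken deviations g_hat
    raw_means: pd.Series  # simple across-record genotype means
    converged: bool
    n_iter: int
    loglik: float
    loglik_trace: list

    @property
    def h2(self) -> float | None:
        return compute_h2(self.vc)


def _design(book: pd.DataFrame, trait: str):
    sub = book.loc[book["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if sub.duplicated(["genotype", "environment", "replicate"]).any():
        raise ValueError("duplicate (genotype, environment, replicate) records")
    y = sub["value"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype values must be finite")
    env_idx, envs = pd.factorize(sub["environment"], sort=True)
    rep_key = sub["environment"].astype(str) + "/" + sub["replicate"].astype(str)
    rep_idx, reps = pd.factorize(rep_key, sort=True)
    gen_idx, gens = pd.factorize(sub["genotype"], sort=True)
    ge_key = sub["genotype"].astype(str) + "/" + sub["environment"].astype(str)
    ge_idx, ges = pd.factorize(ge_key, sort=True)
    if len(gens) < 2:
        raise ValueError("need at least two genotypes")
    levels = {
        "env": (env_idx, len(envs)),
        "rep_in_env": (rep_idx, len(reps)),
        "genotype": (gen_idx, len(gens)),
        "gxe": (ge_idx, len(ges)),
    }
    n_reps = int(sub.groupby(["genotype", "environment"]).size().max())
    return sub, y, levels, list(gens), len(envs), n_reps


def _incidence(idx: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((len(idx), q))
    Z[np.arange(len(idx)), idx] = 1.0
    return Z


def fit_multi_env_model(
    book: pd.DataFrame,
    trait: str,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_var: float = 1e-10,
) -> MultiEnvFit:
    """EM-REML fit of the all-random model for one trait.

    Convergence is declared when the relative change in the REML
    log-likelihood drops below ``tol``; Aitken acceleration is attempted
    every few iterations (an accelerated step is kept only if it does not
    decrease the likelihood).  Component iterates falling below ``min_var``
    are clamped.  Raises on non-convergence, carrying the last iterate in
    the exception message.
    """
    sub, y, levels, genotype_ids, n_envs, n_reps = _design(book, trait)
    n = len(y)
    Zs = [_incidence(*levels[t]) for t in _RANDOM_TERMS]
    qs = [levels[t][1] for t in _RANDOM_TERMS]
    if n <= 6:
        raise ValueError("fewer records than model parameters")
    Z = np.hstack(Zs)
    X = np.ones((n, 1))
    M = np.hstack([X, Z])
    MtM = M.T @ M
    Mty = M.T @ y
    yty = float(y @ y)
    offsets = np.cumsum([1] + qs)  # block boundaries inside the MME, after mu

    # method-of-moments style initial values
    var_y = max(float(np.var(y)), 1e-8)
    cell = sub.assign(_y=y).groupby(["genotype", "environment"])["_y"]
    if n_reps > 1 and (cell.size() > 1).any():
        s2e0 = float(cell.var(ddof=1).dropna().mean())
        s2e0 = s2e0 if np.isfinite(s2e0) and s2e0 > 0 else 0.3 * var_y
    else:
        s2e0 = 0.3 * var_y
    s2e0 = min(s2e0, 0.95 * var_y)
    rest = max(var_y - s2e0, 0.05 * var_y)
    # order: env, rep_in_env, genotype, gxe
    sigma = np.array([0.3 * rest, 0.1 * rest, 0.4 * rest, 0.2 * rest])
    sigma = np.maximum(sigma, min_var)
    sigma_e = max(s2e0, min_var)

    def mme(sig: np.ndarray, sig_e: float):
        A = MtM.copy()
        for b, (q, s) in enumerate(zip(qs, sig)):
            lam = sig_e / s
            i0, i1 = offsets[b], offsets[b] + q
            A[np.arange(i0, i1), np.arange(i0, i1)] += lam
        cho = np.linalg.cholesky(A)
        sol = np.linalg.solve(A, Mty)
        logdetA = 2.0 * float(np.log(np.diag(cho)).sum())
        ypy = (yty - sol @ Mty) / sig_e
        gamma = sig / sig_e
        m2ll = (n - 1) * np.log(sig_e) + float(np.sum(np.array(qs) * np.log(gamma))) \
            + logdetA + ypy
        return A, sol, -0.5 * m2ll

    def em_step(sig: np.ndarray, sig_e: float):
        A, sol, ll = mme(sig, sig_e)
        Ainv_diag = np.diag(np.linalg.inv(A))
        new = np.empty_like(sig)
        for b, q in enumerate(qs):
            i0, i1 = offsets[b], offsets[b] + q
            u = sol[i0:i1]
            new[b] = (u @ u + sig_e * Ainv_diag[i0:i1].sum()) / q
        resid_ss = yty - sol @ Mty
        new_e = resid_ss / (n - 1)
        return np.maximum(new, min_var), max(new_e, min_var), sol, ll

    ll_prev = -np.inf
    trace: list[float] = []
    history: list[np.ndarray] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # em_step evaluates the likelihood at the *current* iterate, so
        # successive ll values compare genuinely different points
        sigma_new, sigma_e_new, _, ll = em_step(sigma, sigma_e)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) / max(abs(ll_prev), 1.0) < tol:
            converged = True
            break
        ll_prev = ll
        theta = np.append(sigma_new, sigma_e_new)
        history.append(theta)
        if len(history) >= 3 and it % 4 == 0:
            t0, t1, t2 = history[-3], history[-2], history[-1]
            d1, d2 = t1 - t0, t2 - t1
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(np.abs(d1) > 0, d2 / d1, 0.0)
            ok = (np.abs(r) < 1.0) & (r != 0)
            acc = np.where(ok, t1 + d2 / (1.0 - r), t2)
            acc = np.maximum(acc, min_var)
            _, _, ll_new = mme(sigma_new, sigma_e_new)
            _, _, ll_acc = mme(acc[:-1], acc[-1])
            if np.isfinite(ll_acc) and ll_acc >= ll_new:
                theta = acc
                ll_prev = ll_new  # keep successive comparisons at distinct points
        sigma, sigma_e = theta[:-1], theta[-1]
    if not converged and it >= max_iter:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations; "
            f"last iterate sigma={sigma}, sigma_e={sigma_e}"
        )

    _, sol, ll = mme(sigma, sigma_e)
    mu_hat = float(sol[0])
    i0 = offsets[_RANDOM_TERMS.index("genotype")]
    g_hat = sol[i0 : i0 + levels["genotype"][1]]
    blups = pd.Series(mu_hat + g_hat, index=genotype_ids, name=trait)
    effects = pd.Series(g_hat, index=genotype_ids, name=trait)
    raw = sub.groupby("genotype")["value"].mean().reindex(genotype_ids)
    n_cells = int(sub.groupby(["genotype", "environment"]).ngroups)
    vc = VarianceComponents(
        var_g=float(sigma[2]),
        var_ge=float(sigma[3]),
        var_e=float(sigma_e),
        var_r=float(sigma[1]),
        var_env=float(sigma[0]),
        mu=mu_hat,
        n_envs=n_envs,
        n_reps=n_reps,
        df_error=max(n - n_cells, 1),
    )
    return MultiEnvFit(
        trait=trait,
        vc=vc,
        blups=blups,
        genotype_effects=effects,
        raw_means=raw,
        converged=converged,
        n_iter=it,
        loglik=ll,
        loglik_trace=trace,
    )


def compute_h2(vc: VarianceComponents) -> float | None:
    """Entry-mean broad-sense heritability; None when all components vanish."""
    denom = vc.var_g + vc.var_ge / vc.n_envs + vc.var_e / (vc.n_reps * vc.n_envs)
    if denom <= 0:
        return None
    return vc.var_g / denom


def compute_lsd_cv(vc: VarianceComponents, alpha: float = 0.05) -> tuple[float, float | None]:
    """Across-environment LSD and CV% at the fitted components.

    LSD = t_(1-alpha/2, df_error) * sqrt(2 s2_e / (n_reps n_envs)) compares
    entry means across environments; CV% = 100 * sqrt(s2_e) / mu_hat.  CV is
    None (undefined) when the grand mean is zero.
    """
    t = float(stats.t.ppf(1.0 - alpha / 2.0, vc.df_error))
    lsd = t * np.sqrt(2.0 * vc.var_e / (vc.n_reps * vc.n_envs))
    cv = None if vc.mu == 0 else 100.0 * float(np.sqrt(vc.var_e)) / vc.mu
    return float(lsd), cv


def env_mean_contrast(book: pd.DataFrame, trait: str, env_a: str, env_b: str) -> float:
    """mean(trait | env_a) - mean(trait | env_b) over available records."""
    sub = book.loc[book["trait"] == trait]
    a = sub.loc[sub["environment"] == env_a, "value"]
    b = sub.loc[sub["environment"] == env_b, "value"]
    if a.empty or b.empty:
        raise ValueError(f"environment without records: {env_a if a.empty else env_b}")
    return float(a.mean() - b.mean())
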