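"""Major-gene fixed-effect integration strategies.

Known adaptation genes (FT/Ppd/Rht/Vrn-style KASP assays) can be promoted
from the anonymous random marker set into the fixed-effect design matrix of
the kernel prediction model

    y = X beta + Z u + e,   u ~ N(0, K s2_g),  e ~ N(0, I s2_e),

with flat priors on beta inside the Gibbs sampler.  Promotion removes the
panel SNP columns tagging those genes from the random universe, and the
kernel is recomputed from the reduced panel.  Four strategies mirror common
practice: the baseline panel, major genes appended as random markers, all
major genes as fixed effects, and a trait-specific subset of genes whose
individual paired CV improvement is positive.  Strategy comparisons always
share one fold plan so paired differences are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cv import CVResult, FeatureSet, FoldPlan, run_cv
from .panel import MarkerPanel
from .qc import StructureComponents, compute_gaussian_kernel
from .simulate import MajorGeneSet

__all__ = [
    "MarkerPromotion",
    "promote_markers_to_fixed",
    "FixedKernelRegressor",
    "fit_fixed_random",
    "evaluate_single_marker_fixed",
    "select_trait_specific_markers",
    "add_structure_covariates",
    "run_strategy_comparison",
    "STRATEGY_LABELS",
]

STRATEGY_LABELS = (
    "90K",
    "90K + Major genes",
    "90K + Major genes (fixed effect)",
    "90K + Selected Major genes (fixed effect)",
)


@dataclass
class MarkerPromotion:
    """Fixed-effect design built from promoted major-gene markers."""

    promoted_markers: list[str]
    removed_random_columns: list[str]
    dropped_aliased: list[str]
    X: np.ndarray  # genotypes x (1 + kept promoted [+ structure]) with intercept
    column_names: list[str]


def _clean_rank(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Greedy removal of collinear columns (intercept always kept)."""
    keep = [0]
    dropped = []
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def promote_markers_to_fixed(
    panel: MarkerPanel,
    genes: MajorGeneSet,
    marker_ids: list[str],
) -> tuple[MarkerPromotion, MarkerPanel]:
    """Build X = [1 | promoted gene dosages] and drop tagged SNPs from the panel.

    ``marker_ids`` are major-gene names from the gene set.  Heterozygous
    calls are already on the 0/1/2 dosage scale; missing calls are
    mean-imputed.  Perfectly collinear promoted columns are dropped with a
    log entry.  Promoting the same marker twice is an error.
    """
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("a marker cannot be promoted twice")
    unknown = [m for m in marker_ids if m not in genes.names]
    if unknown:
        raise ValueError(f"unknown major-gene markers: {unknown}")
    n = panel.n_genotypes
    cols = [np.ones(n)]
    names = ["intercept"]
    removed: list[str] = []
    for name in marker_ids:
        j = genes.names.index(name)
        call = genes.calls[:, j].astype(float).copy()
        if np.isnan(call).all():
            raise ValueError(f"marker {name} has no genotype calls")
        if np.isnan(call).any():
            call[np.isnan(call)] = np.nanmean(call)
        cols.append(call)
        names.append(name)
        tagged = genes.panel_marker.get(name)
        if tagged is not None:
            removed.append(tagged)
    X = np.column_stack(cols)
    X, kept_names, dropped = _clean_rank(X, names)
    keep_mask = ~np.isin(panel.marker_ids, removed)
    reduced = panel.select_markers(keep_mask) if len(removed) else panel.copy()
    promo = MarkerPromotion(
        promoted_markers=[m for m in kept_names if m != "intercept"],
        removed_random_columns=removed,
        dropped_aliased=dropped,
        X=X,
        column_names=kept_names,
    )
    return promo, reduced


class FixedKernelRegressor(RegressorMixin, BaseEstimator):
    """Kernel regression with fixed effects: ``y = X b + u + e``.

    The feature matrix passed to :meth:`fit` is ``[X_fixed | K_train]`` with
    ``n_fixed`` leading fixed-effect columns (intercept included);
    :meth:`predict` expects ``[X_fixed_new | K(new, train)]``.  Gibbs blocks:
    a joint GLS draw of b under a flat prior, the kernel random effect in
    the eigenbasis of K, and scaled-inverse-chi-square variance updates (the
    same prior machinery as the plain RKHS model).  With ``n_fixed = 1``
    (intercept only) the model reduces to plain RKHS regression.
    """

    input_kind = "kernel+fixed"

    def __init__(
        self,
        n_fixed: int = 1,
        n_iter: int = 8000,
        burn_in: int = 2000,
        thin: int = 3,
        df0: float = 5.0,
        r2_prior: float = 0.5,
        psd_tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_fixed = n_fixed
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2_prior = r2_prior
        self.psd_tol = psd_tol
        self.random_state = random_state

    def fit(self, F, y):
        F = np.asarray(F, dtype=float)
        q = self.n_fixed
        X, K = F[:, :q], F[:, q:]
        n = X.shape[0]
        if K.shape[1] != n:
            raise ValueError("expected [X_fixed | square K_train] feature block")
        y = np.asarray(y, dtype=float).ravel()
        w, Q = np.linalg.eigh((K + K.T) / 2.0)
        if w.min() < -self.psd_tol * max(1.0, abs(w.max())):
            raise ValueError("kernel is not PSD within tolerance")
        keep = w > max(w.max(), 1.0) * 1e-10
        w, Q = w[keep], Q[:, keep]
        r = len(w)
        sqw = np.sqrt(w)

        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX + 1e-12 * np.eye(q) * max(1.0, np.trace(XtX)))
        Lx = np.linalg.cholesky(XtX_inv)

        vy = max(float(np.var(y)), 1e-12)
        mean_diag = max(float(np.mean(np.diag(K))), 1e-12)
        S_u = vy * self.r2_prior * (self.df0 + 2.0) / mean_diag
        S_e = vy * (1.0 - self.r2_prior) * (self.df0 + 2.0)

        rng = np.random.default_rng(self.random_state)
        s2u = S_u / (self.df0 + 2.0)
        s2e = S_e / (self.df0 + 2.0)
        beta = XtX_inv @ (X.T @ y)
        u = np.zeros(n)

        b_sum = np.zeros(q)
        d_sum = np.zeros(r)
        s2u_sum = s2e_sum = 0.0
        kept = 0
        for it in range(self.n_iter):
            bhat = XtX_inv @ (X.T @ (y - u))
            beta = bhat + np.sqrt(s2e) * (Lx @ rng.standard_normal(q))
            target = y - X @ beta
            lam = s2e / s2u
            prec = w + lam
            wres = Q.T @ target
            delta = sqw * wres / prec + rng.standard_normal(r) * np.sqrt(s2e / prec)
            u = Q @ (sqw * delta)
            resid = target - u
            s2u = (float(delta @ delta) + S_u) / rng.chisquare(self.df0 + r)
            s2e = (float(resid @ resid) + S_e) / rng.chisquare(self.df0 + n)
            if not (np.isfinite(s2u) and np.isfinite(s2e) and np.isfinite(beta).all()):
                raise FloatingPointError(f"non-finite Gibbs draw at iteration {it}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                b_sum += beta
                d_sum += delta
                s2u_sum += s2u
                s2e_sum += s2e
                kept += 1
        d_bar = d_sum / kept
        self.beta_ = b_sum / kept
        self.var_u_ = s2u_sum / kept
        self.var_e_ = s2e_sum / kept
        self.u_ = Q @ (sqw * d_bar)
        self.alpha_ = Q @ (d_bar / sqw)
        self.n_train_ = n
        self.n_kept_ = kept
        return self

    def predict(self, F):
        check_is_fitted(self, "beta_")
        F = np.asarray(F, dtype=float)
        X, rows = F[:, : self.n_fixed], F[:, self.n_fixed :]
        if rows.shape[1] != self.n_train_:
            raise ValueError("predict expects [X_fixed_new | K(new, train)]")
        return X @ self.beta_ + rows @ self.alpha_


def fit_fixed_random(y, X, K, **mcmc) -> FixedKernelRegressor:
    """Fit ``y = X b + u + e`` with ``u ~ N(0, K s2_g)`` (thin wrapper)."""
    F = np.hstack([np.asarray(X, dtype=float), np.asarray(K, dtype=float)])
    return FixedKernelRegressor(n_fixed=np.asarray(X).shape[1], **mcmc).fit(F, y)


def _features_for_promotion(
    panel: MarkerPanel,
    genes: MajorGeneSet,
    promoted: list[str],
    h: float,
    structure: np.ndarray | None = None,
) -> tuple[FeatureSet, int]:
    """FeatureSet with the reduced-panel kernel and the promotion design."""
    if promoted:
        promo, reduced = promote_markers_to_fixed(panel, genes, promoted)
        X_fixed = promo.X
    else:
        reduced = panel
        X_fixed = np.ones((panel.n_genotypes, 1))
    if structure is not None:
        X_fixed, _, _ = _clean_rank(
            np.hstack([X_fixed, structure]),
            ["c%d" % i for i in range(X_fixed.shape[1] + structure.shape[1])],
        )
    K = compute_gaussian_kernel(reduced, h=h).K
    feats = FeatureSet(genotype_ids=panel.genotype_ids, K=K, X_fixed=X_fixed)
    return feats, X_fixed.shape[1]


def _assert_same_plan(a: CVResult, b: CVResult) -> None:
    for key, te in a.fold_test_indices.items():
        if key not in b.fold_test_indices or not np.array_equal(te, b.fold_test_indices[key]):
            raise ValueError("fold plans differ: refusing an unpaired comparison")


def evaluate_single_marker_fixed(
    gene: str,
    panel: MarkerPanel,
    genes: MajorGeneSet,
    y: np.ndarray,
    plan: FoldPlan,
    baseline_cv: CVResult,
    h: float = 0.5,
    mcmc: dict | None = None,
    trait: str = "",
) -> tuple[pd.DataFrame, float, CVResult]:
    """Paired CV improvement from promoting one gene to a fixed effect.

    Returns the per-(repeat, fold) paired deltas (single-gene-fixed minus
    baseline), their median, and the single-gene CV result.  Raises if the
    baseline was run on a different fold plan.
    """
    feats, n_fixed = _features_for_promotion(panel, genes, [gene], h=h)
    model = FixedKernelRegressor(n_fixed=n_fixed, **(mcmc or {}))
    res = run_cv(model, y, feats, plan, model_name=f"90K + {gene} (fixed)", trait=trait)
    _assert_same_plan(baseline_cv, res)
    merged = res.table.merge(
        baseline_cv.table, on=["repeat", "fold"], suffixes=("", "_base")
    )
    merged["delta"] = merged["ability"] - merged["ability_base"]
    deltas = merged[["repeat", "fold", "ability", "ability_base", "delta"]]
    return deltas, float(np.nanmedian(deltas["delta"])), res


def select_trait_specific_markers(
    deltas: dict[str, float], threshold: float = 0.0
) -> list[str]:
    """Genes whose median paired CV improvement is strictly positive.

    ``deltas`` maps gene -> median paired delta.  The subset may be empty,
    in which case the "selected" strategy equals the baseline.
    """
    return [g for g, d in deltas.items() if np.isfinite(d) and d > threshold]


def add_structure_covariates(
    X: np.ndarray, structure: StructureComponents, n: int = 5
) -> np.ndarray:
    """Append the first ``n`` ordination components to a fixed design matrix."""
    if n == 0:
        return X
    if n > structure.coordinates.shape[1]:
        raise ValueError(f"only {structure.coordinates.shape[1]} components available")
    out = np.hstack([X, structure.coordinates[:, :n]])
    names = [f"c{i}" for i in range(out.shape[1])]
    cleaned, _, _ = _clean_rank(out, names)
    return cleaned


def run_strategy_comparison(
    panel: MarkerPanel,
    genes: MajorGeneSet,
    y: np.ndarray,
    plan: FoldPlan,
    h: float = 0.5,
    mcmc: dict | None = None,
    trait: str = "",
    structure: StructureComponents | None = None,
    n_structure_components: int = 5,
    selection_plan: FoldPlan | None = None,
) -> dict:
    """Run the integration strategies on one shared fold plan.

    Returns a dict with per-strategy :class:`CVResult`, the per-gene paired
    deltas used for selection, and the selected subset.  ``selection_plan``
    lets the single-gene screening run on different folds than the final
    evaluation (the honest-selection variant); by default screening and
    evaluation share ``plan``.
    """
    mcmc = mcmc or {}
    results: dict[str, CVResult] = {}

    # baseline: kernel on the full panel, intercept-only fixed part
    base_feats, _ = _features_for_promotion(panel, genes, [], h=h)
    base_model = FixedKernelRegressor(n_fixed=1, **mcmc)
    results["90K"] = run_cv(base_model, y, base_feats, plan,
                            model_name="90K", trait=trait)

    # KASP calls appended to the random marker universe
    calls = genes.calls.astype(float).copy()
    if np.isnan(calls).any():
        mu = np.nanmean(calls, axis=0)
        idx = np.where(np.isnan(calls))
        calls[idx] = mu[idx[1]]
    aug = panel.copy()
    aug.dosage = np.hstack([aug.dosage, calls])
    aug.imputed = True
    aug.marker_map = pd.concat(
        [aug.marker_map,
         pd.DataFrame({"marker": genes.names, "chromosome": "KASP",
                       "position_mb": np.zeros(len(genes.names))})],
        ignore_index=True,
    )
    K_aug = compute_gaussian_kernel(aug, h=h).K
    feats_aug = FeatureSet(genotype_ids=panel.genotype_ids, K=K_aug,
                           X_fixed=np.ones((panel.n_genotypes, 1)))
    results["90K + Major genes"] = run_cv(
        FixedKernelRegressor(n_fixed=1, **mcmc), y, feats_aug, plan,
        model_name="90K + Major genes", trait=trait)

    # all genes as fixed effects
    feats_all, nf_all = _features_for_promotion(panel, genes, list(genes.names), h=h)
    results["90K + Major genes (fixed effect)"] = run_cv(
        FixedKernelRegressor(n_fixed=nf_all, **mcmc), y, feats_all, plan,
        model_name="90K + Major genes (fixed effect)", trait=trait)

    # single-gene screening -> trait-specific subset
    screen_plan = selection_plan if selection_plan is not None else plan
    if screen_plan is plan:
        screen_base = results["90K"]
    else:
        screen_base = run_cv(base_model, y, base_feats, screen_plan,
                             model_name="90K", trait=trait)
    deltas: dict[str, float] = {}
    audit_rows = []
    for gene in genes.names:
        _, med, _ = evaluate_single_marker_fixed(
            gene, panel, genes, y, screen_plan, screen_base, h=h, mcmc=mcmc,
            trait=trait)
        deltas[gene] = med
        audit_rows.append((trait, gene, med, med > 0))
    selected = select_trait_specific_markers(deltas)
    if selected:
        feats_sel, nf_sel = _features_for_promotion(panel, genes, selected, h=h)
        results["90K + Selected Major genes (fixed effect)"] = run_cv(
            FixedKernelRegressor(n_fixed=nf_sel, **mcmc), y, feats_sel, plan,
            model_name="90K + Selected Major genes (fixed effect)", trait=trait)
    else:  # empty subset: the selected strategy is the baseline
        results["90K + Selected Major genes (fixed effect)"] = results["90K"]

    if structure is not None:
        coords = structure.coordinates[:, :n_structure_components]
        feats_struct, nf_struct = _features_for_promotion(
            panel, genes, selected, h=h, structure=coords)
        results[structure.method] = run_cv(
            FixedKernelRegressor(n_fixed=nf_struct, **mcmc), y, feats_struct,
            plan, model_name=structure.method, trait=trait)

    audit = pd.DataFrame(audit_rows, columns=["trait", "marker", "median_delta", "kept"])
    return {"results": results, "deltas": deltas, "selected": selected, "audit": audit}
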