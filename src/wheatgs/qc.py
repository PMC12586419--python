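"""Marker QC, genomic relationship and kernel construction, ordination.

Filtering follows the conventional array-QC rules: drop markers with missing
rate strictly above 10% or minor allele frequency strictly below 5% (both
thresholds configurable; boundary values are retained).  The genomic
relationship matrix is the VanRaden construction
``G = WW' / (2 * sum_j p_j (1 - p_j))`` with W the dosage matrix centred by
twice the allele frequency.  The Gaussian kernel for RKHS regression is
``K_ij = exp(-h * d_ij)`` where ``d_ij`` is the squared Euclidean distance
between centred, unit-variance marker profiles divided by the number of
markers (so the default bandwidth h = 0.5 is meaningful regardless of panel
size).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MarkerPanel

__all__ = [
    "GenomicRelationship",
    "KernelMatrix",
    "StructureComponents",
    "filter_markers",
    "impute_mean",
    "compute_grm",
    "compute_gaussian_kernel",
    "ordinate_genotypes",
    "snp_density_summary",
    "structure_anova",
]


@dataclass
class GenomicRelationship:
    """VanRaden genomic relationship matrix with its scaling constant."""

    G: np.ndarray
    scaling_constant: float
    allele_freqs: np.ndarray
    genotype_ids: np.ndarray


@dataclass
class KernelMatrix:
    """Gaussian kernel on scaled marker distances (K_ii = 1)."""

    K: np.ndarray
    bandwidth_h: float
    genotype_ids: np.ndarray


@dataclass
class StructureComponents:
    """Low-dimensional genotype coordinates from PCA or classical MDS."""

    coordinates: np.ndarray  # genotypes x n_components, column-centred
    variance_explained: np.ndarray
    method: str
    genotype_ids: np.ndarray


def filter_markers(
    panel: MarkerPanel, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Drop markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Both rules are strict inequalities, so a marker at exactly the threshold
    is retained.  MAF is computed on non-missing calls only.  Returns the
    filtered panel and a per-marker QC log (missing rate, MAF, kept flag,
    drop reason).
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = panel.missing_rate()
    maf = panel.maf()
    drop_missing = miss > max_missing
    # all-missing markers have undefined MAF; they are dropped by the missing rule
    with np.errstate(invalid="ignore"):
        drop_maf = ~drop_missing & (np.nan_to_num(maf, nan=0.0) < min_maf)
    keep = ~(drop_missing | drop_maf)
    reason = np.where(drop_missing, "missing", np.where(drop_maf, "maf", ""))
    log = pd.DataFrame(
        {
            "marker": panel.marker_ids,
            "missing_rate": miss,
            "maf": maf,
            "kept": keep,
            "reason": reason,
        }
    )
    if not keep.any():
        raise ValueError("all markers were dropped by the QC filters")
    return panel.select_markers(keep), log


def impute_mean(panel: MarkerPanel) -> MarkerPanel:
    """Replace missing dosages by the marker's non-missing mean."""
    X = panel.dosage
    if not np.isnan(X).any():
        return replace(panel.copy(), imputed=True)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("marker with all calls missing cannot be mean-imputed")
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    out = panel.copy()
    out.dosage = X
    out.imputed = True
    return out


def compute_grm(panel: MarkerPanel) -> GenomicRelationship:
    """VanRaden G = WW' / (2 * sum p_j (1 - p_j)) from the panel itself."""
    X = panel.dosage
    if np.isnan(X).any():
        raise ValueError("impute the panel before computing the GRM")
    p = X.mean(axis=0) / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("panel is monomorphic: GRM scaling constant is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / c
    return GenomicRelationship(G=G, scaling_constant=c, allele_freqs=p,
                               genotype_ids=panel.genotype_ids)


def scale_markers(X: np.ndarray) -> np.ndarray:
    """Centre columns to zero mean and unit (population) variance.

    Zero-variance columns are excluded (cannot occur after the MAF filter).
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} zero-variance markers from distances")
    return (X[:, keep] - mu[keep]) / sd[keep]


def compute_gaussian_kernel(panel: MarkerPanel, h: float = 0.5) -> KernelMatrix:
    """K_ij = exp(-h d_ij), d_ij = squared Euclidean distance / n_markers."""
    if h < 0:
        raise ValueError("bandwidth h must be >= 0")
    X = panel.dosage
    if np.isnan(X).any():
        raise ValueError("impute the panel before computing the kernel")
    Z = scale_markers(X)
    sq = (Z**2).sum(axis=1)
    d = (sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)) / Z.shape[1]
    np.maximum(d, 0.0, out=d)
    np.fill_diagonal(d, 0.0)
    K = np.exp(-h * d)
    return KernelMatrix(K=K, bandwidth_h=h, genotype_ids=panel.genotype_ids)


def ordinate_genotypes(
    panel: MarkerPanel, method: str = "PCA", n_components: int = 5
) -> StructureComponents:
    """Genotype-space ordination by PCA or classical (metric) MDS.

    PCA eigen-decomposes the covariance of centred dosages; classical MDS
    double-centres the squared Euclidean distance matrix.  On complete
    Euclidean data the two agree up to sign.
    """
    X = panel.dosage
    if np.isnan(X).any():
        raise ValueError("impute the panel before ordination")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    method = method.upper()
    Xc = X - X.mean(axis=0)
    if method == "PCA":
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        coords = U[:, :n_components] * s[:n_components]
        var = s**2
    elif method == "MDS":
        sq = (Xc**2).sum(axis=1)
        D2 = sq[:, None] + sq[None, :] - 2.0 * (Xc @ Xc.T)
        B = -0.5 * D2
        B -= B.mean(axis=0)
        B -= B.mean(axis=1)[:, None]
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        w = np.maximum(w, 0.0)
        coords = V[:, :n_components] * np.sqrt(w[:n_components])
        var = w
    else:
        raise ValueError("method must be 'PCA' or 'MDS'")
    total = var.sum()
    ve = var[:n_components] / total if total > 0 else np.zeros(n_components)
    coords = coords - coords.mean(axis=0)
    return StructureComponents(coordinates=coords, variance_explained=ve,
                               method=method, genotype_ids=panel.genotype_ids)


def _genome_group(chrom: str) -> str | None:
    """Wheat-style genome group: trailing letter of labels like '2B'."""
    c = str(chrom)
    return c[-1] if c and c[-1].isalpha() else None


def snp_density_summary(
    panel: MarkerPanel, chromosome_lengths: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-chromosome (and per genome group) SNP count, density, spacing.

    density = count / span (SNPs per Mb); mean inter-SNP distance = 1/density.
    Span comes from the supplied chromosome-length table when given, else the
    maximum observed position (a lower bound on the physical span).
    """
    m = panel.marker_map
    rows = []
    for chrom, sub in m.groupby("chromosome", sort=False):
        span = (
            float(chromosome_lengths[str(chrom)])
            if chromosome_lengths and str(chrom) in chromosome_lengths
            else float(sub["position_mb"].max())
        )
        count = len(sub)
        density = count / span if span > 0 else np.nan
        distance = 1.0 / density if density and density > 0 else span
        if count < 2:
            distance = span
        rows.append(("chromosome", str(chrom), count, span, density, distance))
    grouped = m.assign(group=m["chromosome"].map(_genome_group)).dropna(subset=["group"])
    for grp, sub in grouped.groupby("group", sort=True):
        if chromosome_lengths:
            span = sum(
                float(chromosome_lengths[str(c)])
                for c in sub["chromosome"].unique()
                if str(c) in chromosome_lengths
            )
        else:
            span = float(sub.groupby("chromosome")["position_mb"].max().sum())
        count = len(sub)
        density = count / span if span > 0 else np.nan
        distance = 1.0 / density if density and density > 0 else span
        rows.append(("genome", str(grp), count, span, density, distance))
    return pd.DataFrame(
        rows, columns=["level", "name", "n_snps", "span_mb", "density_per_mb", "mean_distance_mb"]
    )


def structure_anova(
    trait_values: np.ndarray | pd.Series, group_labels: np.ndarray | pd.Series
) -> tuple[float, float]:
    """One-way ANOVA of a trait on group labels: (R^2, p-value).

    R^2 = SS_between / SS_total.  A constant trait yields R^2 = 0 with an
    undefined (NaN) p-value.
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(group_labels)
    groups = [y[g == lvl] for lvl in pd.unique(g)]
    if len(groups) < 2 or min(len(x) for x in groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0.0:
        return 0.0, float("nan")
    ss_between = float(sum(len(x) * (x.mean() - grand) ** 2 for x in groups))
    r2 = ss_between / ss_total
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pval = stats.f_oneway(*groups)
    return r2, float(pval)
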