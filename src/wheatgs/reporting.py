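"""Auxiliary summaries: climate tables, trait correlations/PCA, response ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "climate_monthly_summary",
    "trait_summary",
    "response_ratio",
]


def climate_monthly_summary(
    daily: pd.DataFrame,
    years_of_interest: list[int] | None = None,
    baseline_years: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Monthly precipitation totals and mean temperature from daily records.

    ``daily`` needs columns DATE (parseable), TMAX, TMIN (deg C), PRCP (mm).
    Daily mean temperature is (TMAX + TMIN) / 2.  Returns a ``monthly``
    table (year, month, prcp_total_mm, tmean_c, n_days) and, when a
    ``baseline_years`` window (inclusive) is given, a per-month ``baseline``
    of the across-year means.  Months with no records are simply absent
    (flagged by their absence); days with TMAX < TMIN are rejected.
    """
    df = daily.copy()
    df["DATE"] = pd.to_datetime(df["DATE"])
    if (df["TMAX"] < df["TMIN"]).any():
        raise ValueError("found a day with TMAX < TMIN")
    df["tmean"] = (df["TMAX"] + df["TMIN"]) / 2.0
    df["year"] = df["DATE"].dt.year
    df["month"] = df["DATE"].dt.month
    monthly = (
        df.groupby(["year", "month"])
        .agg(prcp_total_mm=("PRCP", "sum"), tmean_c=("tmean", "mean"),
             n_days=("DATE", "size"))
        .reset_index()
    )
    out: dict[str, pd.DataFrame] = {"monthly": monthly}
    if years_of_interest is not None:
        out["years_of_interest"] = monthly[monthly["year"].isin(years_of_interest)].copy()
    if baseline_years is not None:
        lo, hi = baseline_years
        base = monthly[(monthly["year"] >= lo) & (monthly["year"] <= hi)]
        if base.empty:
            raise ValueError("baseline window outside the data")
        out["baseline"] = (
            base.groupby("month")
            .agg(prcp_total_mm=("prcp_total_mm", "mean"), tmean_c=("tmean_c", "mean"),
                 n_years=("year", "nunique"))
            .reset_index()
        )
    return out


def trait_summary(trait_table: pd.DataFrame, n_components: int = 2) -> dict:
    """Pairwise Pearson correlations and PCA of a genotype x column table.

    Columns are trait-by-environment values (BLUP columns included);
    correlations use the genotypes common to each pair (pairwise complete),
    requiring at least 3.  Constant columns are flagged and excluded from
    the PCA, which runs on column-standardized complete rows and returns
    biplot coordinates (genotype scores and trait loadings).
    """
    num = trait_table.apply(pd.to_numeric)
    constant = [c for c in num.columns if num[c].dropna().nunique() <= 1]
    corr = num.corr(method="pearson", min_periods=3)
    usable = num.drop(columns=constant).dropna()
    scores = loadings = explained = None
    if usable.shape[1] >= 2 and usable.shape[0] >= 3:
        Z = (usable - usable.mean()) / usable.std(ddof=0)
        U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        k = min(n_components, len(s))
        scores = pd.DataFrame(U[:, :k] * s[:k], index=usable.index,
                              columns=[f"PC{i + 1}" for i in range(k)])
        loadings = pd.DataFrame(Vt[:k].T, index=usable.columns,
                                columns=[f"PC{i + 1}" for i in range(k)])
        explained = (s**2 / (s**2).sum())[:k]
    return {
        "correlations": corr,
        "constant_columns": constant,
        "pca_scores": scores,
        "pca_loadings": loadings,
        "pca_explained": explained,
    }


def response_ratio(ability_new: float, ability_base: float) -> float | None:
    """Relative expected selection response per cycle at fixed i, sigma_A, L.

    Under the breeder's equation R = i r sigma_A / L the response scales
    linearly with predictive accuracy r, so the ratio of abilities is the
    ratio of expected responses.  Undefined (None) for a non-positive
    baseline ability.
    """
    if ability_base <= 0:
        return None
    return float(ability_new / ability_base)
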