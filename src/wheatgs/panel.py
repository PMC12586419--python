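"""Marker panel container and plain-text I/O.

A :class:`MarkerPanel` holds the biallelic SNP dosage matrix (genotypes x
markers, coded 0/1/2 with ``NaN`` for missing calls), the marker map
(chromosome label, physical position in Mb), and optional per-genotype
source/subpopulation labels.  It is the random-effect marker universe that
every downstream stage (QC, relationship matrices, prediction models)
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MarkerPanel", "read_panel", "write_panel"]


@dataclass
class MarkerPanel:
    """Genotype dosage matrix plus marker map.

    Parameters
    ----------
    dosage
        ``(n_genotypes, n_markers)`` float array with entries in {0, 1, 2}
        and ``NaN`` marking missing calls.
    marker_map
        DataFrame with one row per marker and columns ``marker``,
        ``chromosome``, ``position_mb`` (aligned to dosage columns).
    genotype_ids
        Unique labels, one per dosage row.
    group_labels
        Optional per-genotype source/subpopulation labels.
    """

    dosage: np.ndarray
    marker_map: pd.DataFrame
    genotype_ids: np.ndarray
    group_labels: np.ndarray | None = None
    imputed: bool = False  # imputed panels may carry fractional dosages

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.genotype_ids = np.asarray(self.genotype_ids)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D genotypes x markers array")
        n, p = self.dosage.shape
        if len(self.genotype_ids) != n:
            raise ValueError(f"{len(self.genotype_ids)} genotype ids for {n} rows")
        if len(set(map(str, self.genotype_ids))) != n:
            raise ValueError("genotype_ids must be unique")
        if len(self.marker_map) != p:
            raise ValueError(f"marker map has {len(self.marker_map)} rows for {p} markers")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        # imputed panels carry fractional dosages; only raw panels are strict
        if not ok.all() and not getattr(self, "imputed", False):
            bad = self.dosage[~ok]
            if ((bad < 0) | (bad > 2)).any():
                raise ValueError("dosage entries must lie in [0, 2] or be NaN")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("group_labels length mismatch")

    # -- basic views -------------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_map["marker"].to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def select_markers(self, index: np.ndarray) -> "MarkerPanel":
        """New panel restricted to the given marker columns (bool or int index)."""
        return replace(
            self,
            dosage=self.dosage[:, index],
            marker_map=self.marker_map.iloc[np.atleast_1d(np.arange(self.n_markers)[index])]
            .reset_index(drop=True)
            .copy(),
        )

    def select_genotypes(self, index: np.ndarray) -> "MarkerPanel":
        return replace(
            self,
            dosage=self.dosage[index],
            genotype_ids=self.genotype_ids[index],
            group_labels=None if self.group_labels is None else self.group_labels[index],
        )

    def copy(self) -> "MarkerPanel":
        return replace(
            self,
            dosage=self.dosage.copy(),
            marker_map=self.marker_map.copy(),
            genotype_ids=self.genotype_ids.copy(),
            group_labels=None if self.group_labels is None else self.group_labels.copy(),
        )


def write_panel(panel: MarkerPanel, geno_path: str | Path, map_path: str | Path) -> None:
    """Write dosage TSV (genotypes x markers, 'NA' for missing) and sidecar map."""
    df = pd.DataFrame(panel.dosage, index=panel.genotype_ids, columns=panel.marker_ids)
    df.index.name = "genotype"
    df.to_csv(geno_path, sep="\t", na_rep="NA")
    panel.marker_map.to_csv(map_path, sep="\t", index=False)


def read_panel(
    geno_path: str | Path,
    map_path: str | Path | None = None,
    group_labels: np.ndarray | None = None,
) -> MarkerPanel:
    """Read a genotype TSV (first column = genotype id, header = marker ids).

    Accepts both the package's own TSV dialect and a plink RAW-style table
    (an id column followed by one numeric column per marker).  If no map file
    is given, markers are placed on a single dummy chromosome at their column
    index (Mb).
    """
    df = pd.read_csv(geno_path, sep=None, engine="python", na_values=["NA", "NaN", ""])
    df = df.set_index(df.columns[0])
    # plink RAW exports carry FID/IID/PAT/MAT/SEX/PHENOTYPE bookkeeping columns
    drop = [c for c in ("IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    df = df.drop(columns=drop)
    if map_path is not None:
        marker_map = pd.read_csv(map_path, sep=None, engine="python")
        marker_map.columns = ["marker", "chromosome", "position_mb"][: len(marker_map.columns)]
        df = df[[m for m in marker_map["marker"]]]
    else:
        marker_map = pd.DataFrame(
            {
                "marker": df.columns,
                "chromosome": "1",
                "position_mb": np.arange(df.shape[1], dtype=float),
            }
        )
    return MarkerPanel(
        dosage=df.to_numpy(dtype=float),
        marker_map=marker_map,
        genotype_ids=df.index.to_numpy(),
        group_labels=group_labels,
    )
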