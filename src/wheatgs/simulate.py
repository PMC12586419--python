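"""Synthetic spring-wheat panel generator.

Emulates the structure of a multi-environment genomic-selection study:
a structured genotype panel (~250 lines, ~5,000 SNPs on 21 chromosomes,
several subpopulations), a set of major adaptation-gene loci (FT/Ppd/Rht/Vrn
style) with known allelic effects, and plot-level phenotypes generated from
the all-random multi-environment model

    Y_ijk = mu + E_j + R_i(E_j) + G_k + (GE)_jk + eps_ijk

with G_k the sum of a polygenic term (i.i.d. marker effects, rescaled so the
in-sample polygenic variance equals ``var_g`` exactly) and the major-gene
terms.  Early environments receive only a random subset of lines
(sparse testing); late environments receive the full panel.

Population structure follows a Balding-Nichols-style hierarchical
allele-frequency model: ancestral frequencies are Uniform(0.05, 0.95) and
per-subpopulation frequencies are Beta-distributed around them with
dispersion controlled by a single F_ST-like divergence knob.

Every operation is a pure function of its inputs and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel

__all__ = [
    "SimConfig",
    "MajorGeneSpec",
    "MajorGeneSet",
    "SimTruth",
    "default_major_genes",
    "simulate_genotypes",
    "simulate_major_genes",
    "simulate_phenotypes",
    "allocate_sparse",
    "simulate_study",
]

PHENO_COLUMNS = ["genotype", "environment", "replicate", "trait", "value"]


@dataclass(frozen=True)
class MajorGeneSpec:
    """One major-gene locus with a known per-allele effect.

    ``effect_size`` is in trait units per copy of the favourable allele and
    applies to every trait in ``affected_traits``.
    """

    name: str
    chromosome: int
    allele_frequency: float
    effect_size: float
    affected_traits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_frequency < 1.0:
            raise ValueError(f"{self.name}: allele frequency must be in (0, 1)")
        if len(self.affected_traits) == 0:
            raise ValueError(f"{self.name}: affected_traits must be non-empty")


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the emulated study: 250 lines, 5,000 SNPs on 21
    chromosomes, sub-structured germplasm, 3 environments x 2 replicates with
    ~70% of lines allocated to early environments, and variance components
    sigma2_g=4, sigma2_ge=2, sigma2_e=2 on the trait scale.
    """

    n_genotypes: int = 250
    n_markers: int = 5000
    n_chromosomes: int = 21
    n_subpops: int = 3
    fst_like_divergence: float = 0.1
    major_genes: tuple[MajorGeneSpec, ...] = ()
    traits: tuple[str, ...] = ("trait",)
    h2_target: dict[str, float] | None = None
    var_g: float = 4.0
    var_ge: float = 2.0
    var_e: float = 2.0
    var_r: float = 0.25
    var_env: float = 1.0
    trait_means: dict[str, float] = field(default_factory=dict)
    n_envs: int = 3
    n_reps: int = 2
    n_early_envs: int = 1
    sparse_fraction: float = 0.7
    trait_envs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missing_rate: float = 0.02
    chromosome_length_mb: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_markers, self.n_chromosomes, self.n_subpops) <= 0:
            raise ValueError("panel dimensions must be positive")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError("fst_like_divergence must be in [0, 1)")
        if not 0.0 < self.sparse_fraction <= 1.0:
            raise ValueError("sparse_fraction must be in (0, 1]")
        for name, v in (
            ("var_g", self.var_g),
            ("var_ge", self.var_ge),
            ("var_e", self.var_e),
            ("var_r", self.var_r),
            ("var_env", self.var_env),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_markers < len(self.major_genes):
            raise ValueError("need at least as many markers as major genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_envs, self.n_reps) < 1:
            raise ValueError("n_envs and n_reps must be >= 1")

    @property
    def environments(self) -> list[str]:
        return [f"E{j + 1}" for j in range(self.n_envs)]

    @property
    def early_environments(self) -> list[str]:
        n_early = min(max(self.n_early_envs, 0), max(self.n_envs - 1, 0))
        return self.environments[:n_early]


@dataclass
class MajorGeneSet:
    """Realized major-gene loci: per-genotype calls plus true effects.

    ``panel_marker`` maps each gene to the panel SNP column it tags (or None
    when the locus was appended as a new KASP-style column), so fixed-effect
    promotion can remove the corresponding SNP from the random universe.
    """

    names: list[str]
    calls: np.ndarray  # genotypes x genes, dosage of the favourable allele
    effects: dict[str, dict[str, float]]  # gene -> trait -> effect size
    panel_marker: dict[str, str | None]
    genotype_ids: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.names)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.genotype_ids, columns=self.names)


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    true_polygenic_effects: dict[str, np.ndarray]  # trait -> per-marker effects
    true_major_effects: dict[str, dict[str, float]]  # gene -> trait -> effect
    true_genetic_values: pd.DataFrame  # genotype x trait, G_k
    true_genotype_values: dict[str, pd.DataFrame]  # trait -> genotype x env, G_k + (GE)_jk
    realized_h2: dict[str, float]
    components: dict[str, dict[str, float]]  # trait -> {var_g, var_ge, var_e, var_r}


def default_major_genes(
    traits: tuple[str, ...] = ("HD", "PHT", "tSNS", "TKW", "YLD"),
    effect_scale: float = 1.0,
) -> tuple[MajorGeneSpec, ...]:
    """Sixteen KASP-style loci in the FT/Ppd/Rht/Vrn families.

    Flowering-time (FT), photoperiod (Ppd) and vernalization (Vrn) loci act
    on heading date and spikelet number (and indirectly yield); reduced-height
    (Rht) loci act on plant height, kernel weight and yield.
    """
    flowering = tuple(t for t in ("HD", "tSNS", "YLD") if t in traits) or traits[:1]
    height = tuple(t for t in ("PHT", "TKW", "YLD") if t in traits) or traits[:1]
    fam = [
        ("FTA2", 7, 0.45, 1.0, flowering),
        ("FTA2_2", 7, 0.30, 0.6, flowering),
        ("FTB1", 14, 0.40, 0.9, flowering),
        ("FTD1", 21, 0.25, 0.7, flowering),
        ("PpdA1a", 2, 0.35, 0.8, flowering),
        ("PpdD1_1", 16, 0.50, 1.1, flowering),
        ("PpdD1_2", 16, 0.20, 0.5, flowering),
        ("Rht25a", 6, 0.30, 0.6, height),
        ("Rht25b", 6, 0.40, 0.9, height),
        ("RhtB1", 11, 0.45, 1.2, height),
        ("RhtD1", 18, 0.35, 1.1, height),
        ("VrnA1_1", 5, 0.40, 0.8, flowering),
        ("VrnA1_2", 5, 0.25, 0.4, flowering),
        ("VrnB1_1", 12, 0.30, 0.6, flowering),
        ("VrnB1_2", 12, 0.15, 0.3, flowering),
        ("VrnD1", 19, 0.20, 0.5, flowering),
    ]
    return tuple(
        MajorGeneSpec(name, chrom, af, eff * effect_scale, tuple(tr))
        for name, chrom, af, eff, tr in fam
    )


def simulate_genotypes(config: SimConfig) -> MarkerPanel:
    """Draw a structured dosage panel under the hierarchical frequency model.

    Returns a panel whose markers are sorted by (chromosome, position); the
    per-genotype subpopulation labels are stored in ``group_labels``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_genotypes, config.n_markers
    ancestral = rng.uniform(0.05, 0.95, size=p)

    f = config.fst_like_divergence
    if config.n_subpops == 1 or f == 0.0:
        subpop_freq = np.tile(ancestral, (config.n_subpops, 1))
    else:
        theta = (1.0 - f) / f
        subpop_freq = rng.beta(ancestral * theta, (1.0 - ancestral) * theta,
                               size=(config.n_subpops, p))
        subpop_freq = np.clip(subpop_freq, 1e-6, 1.0 - 1e-6)

    subpop = rng.integers(config.n_subpops, size=n)
    dosage = rng.binomial(2, subpop_freq[subpop, :]).astype(float)

    if config.missing_rate > 0:
        miss = rng.random(size=dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    chrom = rng.integers(1, config.n_chromosomes + 1, size=p)
    pos = rng.uniform(0.0, config.chromosome_length_mb, size=p)
    order = np.lexsort((pos, chrom))
    marker_map = pd.DataFrame(
        {
            "marker": [f"S{c}_{i}" for i, c in enumerate(chrom[order])],
            "chromosome": chrom[order].astype(str),
            "position_mb": pos[order],
        }
    )
    return MarkerPanel(
        dosage=dosage[:, order],
        marker_map=marker_map,
        genotype_ids=np.array([f"G{i + 1:04d}" for i in range(n)]),
        group_labels=np.array([f"subpop{s + 1}" for s in subpop]),
    )


def simulate_major_genes(
    panel: MarkerPanel,
    specs: tuple[MajorGeneSpec, ...] | list[MajorGeneSpec],
    seed: int,
    tag_panel_columns: bool = True,
) -> tuple[MarkerPanel, MajorGeneSet]:
    """Realize major-gene loci on (or alongside) the panel.

    By default each gene overwrites one panel SNP on its chromosome with
    dosages drawn at the specified allele frequency, and the correspondence
    gene -> panel column is recorded so fixed-effect promotion can later
    remove the tagged SNP from the random universe.  With
    ``tag_panel_columns=False`` the loci live only in the returned
    :class:`MajorGeneSet` (KASP assays absent from the array).
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate major-gene names")
    rng = np.random.default_rng(seed)
    panel = panel.copy()
    n = panel.n_genotypes
    chroms = panel.marker_map["chromosome"].to_numpy()

    calls = np.empty((n, len(specs)))
    correspondence: dict[str, str | None] = {}
    taken: set[int] = set()
    for j, spec in enumerate(specs):
        calls[:, j] = rng.binomial(2, spec.allele_frequency, size=n)
        if tag_panel_columns:
            candidates = np.flatnonzero(chroms == str(spec.chromosome))
            candidates = np.array([c for c in candidates if c not in taken])
            if candidates.size == 0:  # chromosome exhausted: fall back to any free column
                candidates = np.array([c for c in range(panel.n_markers) if c not in taken])
            col = int(rng.choice(candidates))
            taken.add(col)
            panel.dosage[:, col] = calls[:, j]
            correspondence[spec.name] = str(panel.marker_map.iloc[col]["marker"])
        else:
            correspondence[spec.name] = None

    genes = MajorGeneSet(
        names=names,
        calls=calls,
        effects={s.name: {t: s.effect_size for t in s.affected_traits} for s in specs},
        panel_marker=correspondence,
        genotype_ids=panel.genotype_ids,
    )
    return panel, genes


def allocate_sparse(
    genotype_ids: np.ndarray | list,
    environments: list[str],
    fraction_early: float,
    seed: int,
    early_environments: list[str] | None = None,
) -> pd.DataFrame:
    """Boolean genotype x environment allocation mask for sparse testing.

    Early environments receive ``round(fraction_early * n)`` randomly chosen
    lines; every other (late) environment receives the full panel.
    """
    if len(environments) == 0:
        raise ValueError("environment list is empty")
    if not 0.0 < fraction_early <= 1.0:
        raise ValueError("fraction_early must be in (0, 1]")
    genotype_ids = np.asarray(genotype_ids)
    n = len(genotype_ids)
    if early_environments is None:
        early_environments = []
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(True, index=genotype_ids, columns=environments)
    n_early = int(round(fraction_early * n))
    for env in environments:
        if env in early_environments and n_early < n:
            keep = rng.choice(n, size=n_early, replace=False)
            col = np.zeros(n, dtype=bool)
            col[keep] = True
            mask[env] = col
    return mask


def _solve_var_e(h2: float, var_g: float, var_ge: float, n_envs: int, n_reps: int) -> float:
    """Residual variance that makes the plug-in H2 equal the target."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2_target must be in (0, 1]")
    var_e = n_reps * n_envs * (var_g / h2 - var_g - var_ge / n_envs)
    if var_e < -1e-9:
        raise ValueError("h2_target unattainable with the given var_g/var_ge")
    return max(var_e, 0.0)


def simulate_phenotypes(
    panel: MarkerPanel,
    genes: MajorGeneSet | None,
    config: SimConfig,
    allocation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate plot-level phenotype records and the underlying truth.

    The genetic value of line k for a trait is the rescaled polygenic term
    plus the (mean-centred) major-gene contributions; environment, replicate-
    within-environment, GxE and plot residual effects are drawn i.i.d. normal
    with the configured variances.  Records are restricted to the sparse
    allocation.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = panel.n_genotypes
    envs = config.environments

    if allocation is None:
        if config.sparse_fraction < 1.0 and config.early_environments:
            allocation = allocate_sparse(
                panel.genotype_ids, envs, config.sparse_fraction,
                seed=config.seed + 2, early_environments=config.early_environments,
            )
        else:
            allocation = pd.DataFrame(True, index=panel.genotype_ids, columns=envs)
    missing_envs = [e for e in envs if e not in allocation.columns]
    if missing_envs:
        raise ValueError(f"allocation lacks environments {missing_envs}")

    # complete-data dosage for the genetic model (observational missingness only)
    X = panel.dosage.copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    Xc = X - X.mean(axis=0)

    poly_effects: dict[str, np.ndarray] = {}
    genetic = pd.DataFrame(0.0, index=panel.genotype_ids, columns=list(config.traits))
    components: dict[str, dict[str, float]] = {}
    for trait in config.traits:
        beta = rng.standard_normal(panel.n_markers)
        g = Xc @ beta
        sd = g.std()
        if config.var_g > 0 and sd > 0:
            scale = np.sqrt(config.var_g) / sd
        else:
            scale = 0.0
        beta = beta * scale
        g = g * scale
        poly_effects[trait] = beta
        if genes is not None:
            for j, gene in enumerate(genes.names):
                eff = genes.effects[gene].get(trait, 0.0)
                if eff != 0.0:
                    contrib = genes.calls[:, j] * eff
                    g = g + contrib - contrib.mean()
        genetic[trait] = g
        var_e = config.var_e
        if config.h2_target is not None and trait in config.h2_target:
            var_e = _solve_var_e(config.h2_target[trait], config.var_g,
                                 config.var_ge, config.n_envs, config.n_reps)
        components[trait] = {
            "var_g": config.var_g, "var_ge": config.var_ge,
            "var_e": var_e, "var_r": config.var_r,
        }

    records: list[tuple] = []
    ge_values: dict[str, pd.DataFrame] = {}
    realized_h2: dict[str, float] = {}
    for trait in config.traits:
        trait_envs = list(config.trait_envs.get(trait, envs))
        mu = config.trait_means.get(trait, 0.0)
        var_e = components[trait]["var_e"]
        env_eff = rng.normal(0.0, np.sqrt(config.var_env), size=len(trait_envs))
        rep_eff = rng.normal(0.0, np.sqrt(config.var_r),
                             size=(len(trait_envs), config.n_reps))
        ge = rng.normal(0.0, np.sqrt(config.var_ge), size=(n, len(trait_envs)))
        g = genetic[trait].to_numpy()
        ge_values[trait] = pd.DataFrame(
            g[:, None] + ge, index=panel.genotype_ids, columns=trait_envs
        )
        for j, env in enumerate(trait_envs):
            active = allocation[env].to_numpy()
            for i in range(config.n_reps):
                eps = rng.normal(0.0, np.sqrt(var_e), size=n)
                vals = mu + env_eff[j] + rep_eff[j, i] + g + ge[:, j] + eps
                for k in np.flatnonzero(active):
                    records.append(
                        (panel.genotype_ids[k], env, f"R{i + 1}", trait, vals[k])
                    )
        g_var = float(np.var(g))
        denom = (g_var + config.var_ge / len(trait_envs)
                 + var_e / (config.n_reps * len(trait_envs)))
        realized_h2[trait] = g_var / denom if denom > 0 else 0.0

    book = pd.DataFrame(records, columns=PHENO_COLUMNS)
    truth = SimTruth(
        true_polygenic_effects=poly_effects,
        true_major_effects={} if genes is None else genes.effects,
        true_genetic_values=genetic,
        true_genotype_values=ge_values,
        realized_h2=realized_h2,
        components=components,
    )
    return book, truth


def simulate_study(config: SimConfig) -> tuple[MarkerPanel, MajorGeneSet | None, pd.DataFrame, SimTruth]:
    """Panel + major genes + phenotypes in one call (the usual entry point)."""
    panel = simulate_genotypes(config)
    genes = None
    if config.major_genes:
        panel, genes = simulate_major_genes(panel, config.major_genes, seed=config.seed + 10)
    book, truth = simulate_phenotypes(panel, genes, config)
    return panel, genes, book, truth
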