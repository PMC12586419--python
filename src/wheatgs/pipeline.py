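"""End-to-end pipeline: simulate -> QC -> BLUP -> model CV -> strategies.

A :class:`RunConfig` (loadable from YAML) drives the stages; every stage
writes plain-text tables into the run directory and the manifest logs the
exact seeds, so a rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blup as blup_mod
from . import qc as qc_mod
from .cv import FeatureSet, make_genotype_folds, run_cv, summarize_cv
from .fixedfx import run_strategy_comparison
from .models import MODEL_REGISTRY, make_model
from .panel import write_panel
from .simulate import SimConfig, default_major_genes, simulate_study

log = logging.getLogger("wheatgs")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    outdir: str = "wheatgs_run"
    seed: int = 1
    n_genotypes: int = 250
    n_markers: int = 2000
    n_envs: int = 3
    n_reps: int = 2
    n_subpops: int = 3
    fst_like_divergence: float = 0.1
    sparse_fraction: float = 0.7
    traits: tuple[str, ...] = ("HD", "PHT", "YLD")
    var_g: float = 4.0
    var_ge: float = 2.0
    var_e: float = 2.0
    var_r: float = 0.25
    use_major_genes: bool = True
    major_gene_effect_scale: float = 1.0
    models: tuple[str, ...] = ("GBLUP", "RR", "LASSO", "BRR", "RKHS", "SVM", "RF")
    cv_folds: int = 5
    cv_repeats: int = 5
    rkhs_bandwidth: float = 0.5
    mcmc_iter: int = 1500
    mcmc_burn_in: int = 500
    mcmc_thin: int = 3
    run_strategies: bool = True
    strategy_repeats: int = 3

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ValueError(f"unknown model(s): {unknown}")
        if not self.traits:
            raise ValueError("trait list is empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for f in ("traits", "models"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg


def _mcmc_params(cfg: RunConfig) -> dict:
    return {"n_iter": cfg.mcmc_iter, "burn_in": cfg.mcmc_burn_in, "thin": cfg.mcmc_thin}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages, persisting every table; returns the run directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": asdict(cfg)}
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time() - t_all}

    try:
        stage("simulate")
        sim = SimConfig(
            n_genotypes=cfg.n_genotypes, n_markers=cfg.n_markers,
            n_envs=cfg.n_envs, n_reps=cfg.n_reps, n_subpops=cfg.n_subpops,
            fst_like_divergence=cfg.fst_like_divergence,
            sparse_fraction=cfg.sparse_fraction, traits=tuple(cfg.traits),
            var_g=cfg.var_g, var_ge=cfg.var_ge, var_e=cfg.var_e, var_r=cfg.var_r,
            major_genes=default_major_genes(tuple(cfg.traits), cfg.major_gene_effect_scale)
            if cfg.use_major_genes else (),
            seed=cfg.seed,
        )
        panel, genes, book, truth = simulate_study(sim)
        write_panel(panel, outdir / "genotypes.tsv", outdir / "marker_map.tsv")
        book.to_csv(outdir / "phenotypes.csv", index=False)
        truth.true_genetic_values.to_csv(outdir / "true_genetic_values.csv")
        if genes is not None:
            genes.calls_frame().to_csv(outdir / "major_gene_calls.csv")

        stage("qc")
        filtered, qc_log = qc_mod.filter_markers(panel)
        qc_log.to_csv(outdir / "qc_report.csv", index=False)
        imputed = qc_mod.impute_mean(filtered)
        qc_mod.snp_density_summary(imputed).to_csv(outdir / "snp_density.csv", index=False)
        grm = qc_mod.compute_grm(imputed)
        kern = qc_mod.compute_gaussian_kernel(imputed, h=cfg.rkhs_bandwidth)
        structure = qc_mod.ordinate_genotypes(imputed, "PCA",
                                              n_components=min(5, cfg.n_genotypes - 1))

        stage("blup")
        blup_rows = []
        blups = {}
        for trait in cfg.traits:
            fit = blup_mod.fit_multi_env_model(book, trait)
            h2 = blup_mod.compute_h2(fit.vc)
            lsd, cvpc = blup_mod.compute_lsd_cv(fit.vc)
            blup_rows.append((trait, fit.vc.var_g, fit.vc.var_ge, fit.vc.var_r,
                              fit.vc.var_e, h2, lsd, cvpc))
            blups[trait] = fit.blups
        pd.DataFrame(blup_rows, columns=["trait", "var_g", "var_ge", "var_r",
                                         "var_e", "H2", "LSD", "CV_pct"]
                     ).to_csv(outdir / "variance_components.csv", index=False)
        blup_table = pd.DataFrame(blups).reindex(panel.genotype_ids)
        blup_table.to_csv(outdir / "blups.csv")

        stage("cv")
        feats = FeatureSet(genotype_ids=panel.genotype_ids,
                           X=imputed.dosage, G=grm.G, K=kern.K)
        plan = make_genotype_folds(panel.genotype_ids, k=cfg.cv_folds,
                                   repeats=cfg.cv_repeats, seed=cfg.seed)
        all_results = []
        for trait in cfg.traits:
            y = blup_table[trait].to_numpy()
            for fam in cfg.models:
                over = _mcmc_params(cfg) if fam in ("BRR", "RKHS") else {}
                model = make_model(fam, random_state=cfg.seed, **over)
                res = run_cv(model, y, feats, plan, model_name=fam, trait=trait)
                all_results.append(res)
        raw = pd.concat([r.table for r in all_results], ignore_index=True)
        raw.to_csv(outdir / "cv_abilities.csv", index=False)
        summarize_cv(raw).to_csv(outdir / "cv_summary.csv", index=False)

        if cfg.run_strategies and genes is not None:
            stage("fixedfx")
            splan = make_genotype_folds(panel.genotype_ids, k=cfg.cv_folds,
                                        repeats=cfg.strategy_repeats,
                                        seed=cfg.seed + 1)
            strat_rows = []
            for trait in cfg.traits:
                y = blup_table[trait].to_numpy()
                out = run_strategy_comparison(
                    imputed, genes, y, splan, h=cfg.rkhs_bandwidth,
                    mcmc=_mcmc_params(cfg), trait=trait, structure=structure)
                out["audit"].to_csv(outdir / f"marker_selection_{trait}.csv",
                                    index=False)
                for label, res in out["results"].items():
                    s = res.summary()
                    strat_rows.append((trait, label, s["median"], s["mean"], s["sd"]))
            pd.DataFrame(strat_rows, columns=["trait", "strategy", "median",
                                              "mean", "sd"]
                         ).to_csv(outdir / "strategy_summary.csv", index=False)
    except Exception as exc:  # persist what we have, then surface the stage
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["elapsed_s"] = time.time() - t_all
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
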