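"""End-to-end orchestration of the neutrophil severity analysis.

One call chains every stage on a synthetic cohort: simulation → QC →
first-pass clustering (the neutrophil compartment is the dominant
cluster) → second-step subtype clustering with the subsample/ARI
stability scan → functional scoring with mixture-model apoptosis calling
→ consensus NMF metagene modules in the severity-associated subtype →
pseudobulk deconvolution → association statistics (correlations with
Holm correction, shock AUCs, interaction logistic model).

A single global seed fans out to per-stage seeds by fixed offsets, so any
stage can be re-run in isolation and two runs with the same configuration
are bit-identical. The ``RunReport`` gathers every stage's parameters and
key metrics and serializes to JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (adjusted_rand_index, cluster, embed_pca, find_markers,
                         select_resolution, stability_scan)
from .deconv import build_signature_matrix, deconvolve, evaluate_deconv
from .io import write_matrix_10x, write_table
from .nmf import (aggregate_usage, consensus_metrics, module_usage,
                  nmf_factorize, select_rank, top_genes)
from .qc import compute_qc, filter_cells, normalize_log, select_hvg
from .scoring import SignatureSet, classify_apoptotic, fit_gmm_1d, score_mean, score_weighted_z
from .simulate import (ShockModel, SimulationConfig, simulate_atlas,
                       simulate_clinical_table, simulate_pseudobulk)
from .stats import holm_adjust, logistic_irls, pearson_test, roc_auc

log = logging.getLogger("neutroscope")

# fixed per-stage seed offsets (global seed + offset)
SEED_OFFSETS = {
    "simulate": 0, "first_pass": 1000, "scan": 2000, "gmm": 3000,
    "nmf": 4000, "pseudobulk": 5000, "clinical": 6000,
}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's printed values where
    they exist (QC 200/2500/10%, first-pass resolution 0.15, subtype
    resolution grid around 0.2, 90% subsamples, 20 iterations)."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    #: marker panel used to call the neutrophil compartment after the first
    #: pass (user-supplied for real data; auto-filled from the generator's
    #: planted neutrophil panel for synthetic runs). None -> largest cluster.
    neutrophil_markers: tuple | None = None
    # qc
    min_features: int = 200
    max_features: int = 2500
    max_mito_pct: float = 10.0
    n_hvg: int = 2000
    # clustering
    first_pass_resolution: float = 0.15
    scan_resolutions: tuple = (0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.6)
    subsample_fraction: float = 0.9
    scan_iterations: int = 20
    decline_delta: float = 0.05
    knn: int = 15
    n_pcs: int = 30
    subtype_n_hvg: int = 1000
    # nmf
    nmf_ranks: tuple = (2, 3, 4, 5, 6, 7)
    nmf_runs: int = 30
    nmf_n_hvg: int = 500
    nmf_max_iter: int = 300
    # deconvolution
    deconv_markers_per_type: int = 50
    pseudobulk_noise_cv: float = 0.1
    # stats
    clinical_n_patients: int = 2000
    # stage toggles
    run_scoring: bool = True
    run_nmf: bool = True
    run_deconv: bool = True
    run_stats: bool = True

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        shock_raw = sim_raw.pop("shock_model", None)
        sim_kwargs = dict(sim_raw)
        if shock_raw is not None:
            sim_kwargs["shock_model"] = ShockModel(**shock_raw)
        cfg = cls(sim=SimulationConfig(**sim_kwargs), **raw)
        cfg.sim.seed = cfg.stage_seed("simulate")
        return cfg


def fixture_config(seed: int = 0) -> PipelineConfig:
    """The packaged desk-scale fixture: same generative structure as the
    full cohort at a size a laptop CPU can run end-to-end in minutes."""
    sim = SimulationConfig(
        n_samples=12, n_cells_per_sample=450, n_genes=1200,
        markers_per_type=16, seed=seed + SEED_OFFSETS["simulate"],
    )
    return PipelineConfig(
        sim=sim, seed=seed, n_hvg=600, subtype_n_hvg=400,
        scan_resolutions=(0.1, 0.2, 0.4, 0.6), scan_iterations=8,
        nmf_ranks=(2, 3, 4, 5), nmf_runs=10, nmf_n_hvg=300, nmf_max_iter=200,
        deconv_markers_per_type=12, clinical_n_patients=800,
    )


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    elapsed_s: float = 0.0

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash,
                "version": self.version, "elapsed_s": round(self.elapsed_s, 2),
                "stages": self.stages}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def _marker_positive_clusters(norm, labels, panel) -> list:
    """Clusters whose mean panel score clears the midpoint of the
    cluster-score range — the marker-based annotation step that names the
    neutrophil compartment (which may span several first-pass clusters)."""
    panel = [g for g in panel if g in norm.var_names]
    if not panel:
        return []
    score = np.asarray(norm[:, panel].X.mean(axis=1)).ravel()
    uniq = np.unique(labels)
    means = np.array([score[labels == u].mean() for u in uniq])
    if means.max() - means.min() < 1e-12:
        return [int(u) for u in uniq]
    midpoint = 0.5 * (means.max() + means.min())
    return [int(u) for u, m in zip(uniq, means) if m > midpoint]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute all enabled stages in dependency order.

    When ``out_dir`` is given, every tabular artifact is written there
    with a provenance header. Failures halt with a ``PipelineError``
    naming the stage.
    """
    t0 = time.time()
    meta = {"version": __version__, "seed": config.seed,
            "config_hash": config.config_hash()}
    report = RunReport(seed=config.seed, config_hash=meta["config_hash"],
                       version=__version__)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(df, name, index=True):
        if out is not None:
            write_table(df, out / name, meta=meta, index=index)

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        config.sim.seed = config.stage_seed("simulate")
        adata, samples, truth = simulate_atlas(config.sim)
        log.info("simulate: %d cells x %d genes, seed %d",
                 adata.n_obs, adata.n_vars, config.sim.seed)
        report.stages[stage] = {
            "seed": config.sim.seed, "n_cells": int(adata.n_obs),
            "n_genes": int(adata.n_vars), "n_samples": int(len(samples)),
        }
        if out is not None:
            write_matrix_10x(adata, out / "counts")
            emit(samples, "samples.csv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- qc -------------------------------------------------------------
    stage = "qc"
    try:
        metrics = compute_qc(adata)
        mask = filter_cells(metrics, config.min_features, config.max_features,
                            config.max_mito_pct)
        kept = adata[mask].copy()
        norm = normalize_log(kept)
        hvg = select_hvg(norm, n_top=min(config.n_hvg, norm.n_vars))
        emit(metrics, "qc_metrics.csv")
        report.stages[stage] = {
            "cells_in": int(adata.n_obs), "cells_kept": int(mask.sum()),
            "cells_removed": int((~mask).sum()), "n_hvg": len(hvg),
        }
        log.info("qc: kept %d / %d cells", mask.sum(), adata.n_obs)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- first-pass clustering -----------------------------------------
    stage = "first_pass"
    try:
        seed = config.stage_seed("first_pass")
        emb = embed_pca(norm[:, hvg].X, n_pcs=config.n_pcs, seed=seed)
        first = cluster(emb, config.first_pass_resolution, seed=seed,
                        k=config.knn, is_embedding=True)
        panel = config.neutrophil_markers
        if panel is None:
            panel = tuple(g for g, (t, _) in truth.marker_gene_assignment.items()
                          if t == "Neutrophil")
        neu_clusters = _marker_positive_clusters(norm, first.labels, panel)
        if not neu_clusters:  # fall back to the dominant cluster
            neu_clusters = [int(np.bincount(first.labels).argmax())]
        neu_mask = np.isin(first.labels, neu_clusters)
        truth_major = kept.obs["cell_type"].to_numpy()
        neu_purity = float((truth_major[neu_mask] == "Neutrophil").mean())
        report.stages[stage] = {
            "seed": seed, "resolution": config.first_pass_resolution,
            "n_clusters": first.n_clusters,
            "neutrophil_clusters": [int(c) for c in neu_clusters],
            "neutrophil_cells": int(neu_mask.sum()),
            "neutrophil_compartment_purity": neu_purity,
        }
        log.info("first pass: %d clusters; neutrophil cluster has %d cells",
                 first.n_clusters, neu_mask.sum())
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- subtype clustering with stability scan ------------------------
    stage = "subtypes"
    try:
        seed = config.stage_seed("scan")
        norm_neu = norm[neu_mask].copy()
        hvg_neu = select_hvg(norm_neu, n_top=min(config.subtype_n_hvg, norm_neu.n_vars))
        emb_neu = embed_pca(norm_neu[:, hvg_neu].X, n_pcs=config.n_pcs, seed=seed)
        table = stability_scan(
            emb_neu, config.scan_resolutions,
            subsample_fraction=config.subsample_fraction,
            n_iterations=config.scan_iterations, seed=seed,
            k=config.knn, is_embedding=True,
        )
        chosen = select_resolution(table, delta=config.decline_delta)
        subtype = cluster(emb_neu, chosen, seed=seed, k=config.knn,
                          is_embedding=True)
        truth_sub = norm_neu.obs["neutrophil_subtype"].astype(str).to_numpy()
        ari_truth = adjusted_rand_index(subtype.labels, truth_sub)
        emit(table.rows, "stability.csv", index=False)
        labels_df = pd.DataFrame(
            {"cluster": subtype.labels}, index=norm_neu.obs_names)
        emit(labels_df, "subtype_labels.csv")
        if subtype.n_clusters >= 2:
            markers = find_markers(norm_neu, subtype.labels)
            emit(markers, "subtype_markers.csv", index=False)
        report.stages[stage] = {
            "seed": seed, "selected_resolution": chosen,
            "n_subtypes": subtype.n_clusters,
            "mean_ari_curve": table.summary["mean_ari"].round(4).to_dict(),
            "ari_vs_truth": round(float(ari_truth), 4),
        }
        log.info("subtypes: resolution %.2f -> %d clusters (ARI vs truth %.3f)",
                 chosen, subtype.n_clusters, ari_truth)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # per-sample subtype fractions (used by nmf + stats stages)
    neu_samples = norm_neu.obs["sample"].to_numpy()
    frac = (pd.crosstab(pd.Series(neu_samples, name="sample"),
                        pd.Series(subtype.labels, name="cluster"), normalize="index")
            .reindex(samples.index).fillna(0.0))
    sev = samples["severity"]
    sub_corr = {
        c: float(np.corrcoef(frac[c], sev)[0, 1]) if frac[c].std() > 0 else 0.0
        for c in frac.columns
    }
    neu1_like = max(sub_corr, key=sub_corr.get)  # severity-associated subtype

    # ---- scoring + apoptosis mixture -----------------------------------
    if config.run_scoring:
        stage = "scoring"
        try:
            sigs = truth.signature_genes
            scores = {}
            for name in ("apoptosis", "maturation", "azurophil", "ifn_response"):
                scores[name] = score_mean(norm_neu, SignatureSet(name, sigs[name]))
            aging_genes = sigs["maturation"] + sigs["gelatinase"]
            aging_weights = {g: 1 for g in sigs["maturation"]}
            aging_weights.update({g: -1 for g in sigs["gelatinase"]})
            scores["aging"] = score_weighted_z(
                norm_neu, SignatureSet("aging", aging_genes, aging_weights))
            score_df = pd.DataFrame(scores, index=norm_neu.obs_names)
            emit(score_df, "scores.csv")

            fit = fit_gmm_1d(scores["apoptosis"], seed=config.stage_seed("gmm"))
            apo_labels, apo_frac = classify_apoptotic(fit)
            acc = float((apo_labels == norm_neu.obs["apoptotic"].to_numpy()).mean())
            emit(pd.DataFrame({"posterior_apoptotic": fit.responsibilities[:, 1],
                               "apoptotic": apo_labels}, index=norm_neu.obs_names),
                 "apoptosis.csv")
            report.stages[stage] = {
                "seed": config.stage_seed("gmm"),
                "gmm_means": fit.means.round(4).tolist(),
                "gmm_weights": fit.weights.round(4).tolist(),
                "apoptotic_fraction": round(apo_frac, 4),
                "apoptotic_accuracy_vs_truth": round(acc, 4),
                "gmm_converged": fit.converged,
            }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- NMF metagene modules in the severity-associated subtype -------
    usage_by_sample = None
    if config.run_nmf:
        stage = "nmf"
        try:
            seed = config.stage_seed("nmf")
            m1 = subtype.labels == neu1_like
            norm_m1 = norm_neu[m1].copy()
            hvg_m1 = select_hvg(norm_m1, n_top=min(config.nmf_n_hvg, norm_m1.n_vars))
            V = np.asarray(norm_m1[:, hvg_m1].X.todense()).T  # genes x cells
            ranks = [r for r in config.nmf_ranks if r < min(V.shape)]
            metrics_nmf = consensus_metrics(V, ranks, n_runs=config.nmf_runs,
                                            seed=seed, max_iter=config.nmf_max_iter)
            rank = select_rank(metrics_nmf)
            fit = nmf_factorize(V, rank, seed=seed, max_iter=config.nmf_max_iter)
            usage = module_usage(fit.H)
            usage_by_sample = aggregate_usage(usage, norm_m1.obs["sample"].to_numpy())
            usage_by_sample = usage_by_sample.reindex(samples.index).dropna()
            mods = top_genes(fit.W, hvg_m1, n=20)
            emit(metrics_nmf.table, "rank_metrics.csv")
            emit(pd.DataFrame(fit.W, index=hvg_m1,
                              columns=[f"module_{k}" for k in range(rank)]), "W.csv")
            emit(pd.DataFrame(usage, index=norm_m1.obs_names,
                              columns=[f"module_{k}" for k in range(rank)]), "usage.csv")
            usage_sev = {}
            for c in usage_by_sample.columns:
                if usage_by_sample[c].std() > 0:
                    res = pearson_test(usage_by_sample[c],
                                       sev.loc[usage_by_sample.index])
                    usage_sev[c] = {"r": round(res.estimate, 4), "p": res.p}
            report.stages[stage] = {
                "seed": seed, "neu1_like_cluster": int(neu1_like),
                "n_cells": int(m1.sum()), "selected_rank": int(rank),
                "cophenetic": metrics_nmf.table["cophenetic"].round(4).to_dict(),
                "usage_severity": usage_sev,
                "top_genes_module_0": mods[0][:5],
            }
            log.info("nmf: selected rank %d on %d cells", rank, m1.sum())
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- pseudobulk deconvolution --------------------------------------
    deconv_est = None
    if config.run_deconv:
        stage = "deconv"
        try:
            # truth-free labels: first-pass clusters, neutrophils split by subtype
            labels_all = np.array([f"c{l}" for l in first.labels], dtype=object)
            labels_all[neu_mask] = [f"n{l}" for l in subtype.labels]
            bulk, true_frac = simulate_pseudobulk(
                kept, labels_all, kept.obs["sample"].to_numpy(),
                noise_cv=config.pseudobulk_noise_cv,
                seed=config.stage_seed("pseudobulk"))
            signature = build_signature_matrix(
                norm, labels_all, markers_per_type=config.deconv_markers_per_type)
            deconv_est = deconvolve(bulk, signature)
            ev = evaluate_deconv(deconv_est, true_frac)
            emit(signature.profiles, "signature.csv")
            emit(deconv_est.fractions, "fractions.csv")
            neu1_col = f"n{neu1_like}"
            r_neu1 = float(ev.loc[neu1_col, "pearson_r"]) if neu1_col in ev.index else np.nan
            report.stages[stage] = {
                "seed": config.stage_seed("pseudobulk"),
                "n_signature_genes": len(signature.genes),
                "noise_cv": config.pseudobulk_noise_cv,
                "mean_rmse": round(float(ev.loc["overall", "rmse"]), 4),
                "r_neu1_fraction": round(r_neu1, 4) if np.isfinite(r_neu1) else None,
            }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- association statistics ----------------------------------------
    if config.run_stats:
        stage = "stats"
        try:
            tests = []
            for c in frac.columns:
                if frac[c].std() == 0:
                    continue
                res = pearson_test(frac[c], samples["sofa_circulation"])
                tests.append({"test": f"pearson_subtype{c}_vs_sofa_circ",
                              "estimate": res.estimate, "p": res.p})
            shock = samples["shock"].astype(int).to_numpy()
            stats_block = {}
            if shock.min() == 0 and shock.max() == 1:
                stats_block["auc_neu1_fraction_shock"] = round(
                    roc_auc(frac[neu1_like].to_numpy(), shock), 4)
                if usage_by_sample is not None and len(usage_by_sample) == len(samples):
                    coupled = max(
                        usage_by_sample.columns,
                        key=lambda c: abs(np.corrcoef(usage_by_sample[c], sev)[0, 1]))
                    stats_block["auc_coupled_module_usage_shock"] = round(
                        roc_auc(usage_by_sample[coupled].to_numpy(), shock), 4)
            if tests:
                padj = holm_adjust([t["p"] for t in tests])
                for t, pa in zip(tests, padj):
                    t["p_holm"] = pa
            clin = simulate_clinical_table(config.sim, config.clinical_n_patients,
                                           seed=config.stage_seed("clinical"))
            logit = logistic_irls(clin)
            stats_block.update({
                "interaction_coef": round(float(logit.params["neu_x_mono"]), 4),
                "interaction_se": round(float(logit.bse["neu_x_mono"]), 4),
                "interaction_p": float(logit.pvalues["neu_x_mono"]),
                "tests": tests,
            })
            emit(pd.DataFrame(tests), "stats_tests.csv", index=False)
            report.stages[stage] = stats_block
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    report.elapsed_s = time.time() - t0
    if out is not None:
        report.to_json(out / "run_report.json")
    return report
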