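"""End-to-end orchestration from a single validated configuration.

Stage order: synth (or cohort loading) -> preprocess -> peaks -> screening ->
bench -> interpret -> clinical -> cluster. Every stage writes its tables
under the output directory and appends to a run manifest; re-running the
same configuration reproduces identical CSV/JSON outputs. A single global
seed fans out to per-stage seeds through a fixed integer derivation so the
stages stay independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import bench, clinical, cluster, interpret, screening, synth
from .peaks import (FeatureMatrix, collapse_replicates, detect_peaks,
                    flag_matrix_region, greedy_align, impute_missing)
from .preprocess import PreprocessParams, preprocess_spectrum

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "build_feature_matrix"]

STAGES = ("synth", "preprocess", "peaks", "screening", "bench", "interpret",
          "clinical", "cluster")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthBlock(_Block):
    n_cancer: int = 60
    n_healthy: int = 60
    replicates_per_sample: int = 3
    mz_min: float = 1000.0
    mz_max: float = 15000.0
    grid_step: float = 1.0
    n_peaks: int = 120
    peak_width_sigma: float = 2.5
    n_up: int = 0
    n_down: int = 0
    log2fc_up: float = 2.5
    log2fc_down: float = -2.5
    intensity_cv: float = 0.15
    replicate_cv: float = 0.05
    baseline_amplitude: float = 5.0
    noise_sd: float = 0.3
    mass_jitter_ppm: float = 1500.0
    matrix_artifact_rate: float = 0.05
    paper_default: bool = False  # overrides the fields above with the frozen cohort


class PreprocessBlock(_Block):
    savgol_window: int = 21
    savgol_polyorder: int = 10
    median_window: int = 10
    tophat_element: int = 11


class PeaksBlock(_Block):
    min_height_frac: float = 0.03
    min_width: int = 5
    tol_ppm: float = 2500.0
    impute: Literal["zero", "interpolate"] = "zero"
    exclude_matrix_region: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.tol_ppm <= 0:
            raise ValueError("peaks.tol_ppm must be positive")
        return self


class ScreeningBlock(_Block):
    p_thresh: float = 0.001
    fc_thresh: float = 1.0
    fdr: bool = False
    top_k: int = 20


class BenchBlock(_Block):
    models: list[str] = list(bench.MODEL_NAMES)
    k_folds: int = 5
    test_frac: float = 0.2


class InterpretBlock(_Block):
    k_consensus: int = 20
    top_m_intersection: int = 10
    n_background: int = 200
    explain_samples: int = 8
    shap_budget: Optional[int] = None
    lime_perturbations: int = 5000


class ClinicalBlock(_Block):
    model: str = "random_forest"
    k_folds: int = 5
    treat_all_variant: Literal["as_printed", "standard"] = "as_printed"
    n_single_features: int = 5


class ClusterBlock(_Block):
    birch_threshold: float = 0.5
    birch_branching_factor: int = 50
    embedding: Literal["pca", "kpca", "tsne", "umap"] = "umap"
    use_differential_features: bool = True


class PipelineConfig(_Block):
    seed: int
    outdir: str = "results/pipeline"
    input_dir: Optional[str] = None
    synth: Optional[SynthBlock] = None
    preprocess: PreprocessBlock = PreprocessBlock()
    peaks: PeaksBlock = PeaksBlock()
    screening: ScreeningBlock = ScreeningBlock()
    bench: BenchBlock = BenchBlock()
    interpret: InterpretBlock = InterpretBlock()
    clinical: ClinicalBlock = ClinicalBlock()
    cluster: ClusterBlock = ClusterBlock()

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_dir is None) == (self.synth is None):
            raise ValueError("exactly one of input_dir or synth must be given")
        return self


def validate_config(raw: str) -> PipelineConfig:
    """Parse and validate a YAML configuration document."""
    doc = yaml.safe_load(raw)
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a YAML mapping")
    try:
        return PipelineConfig(**doc)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{key}: {err['msg']}")
        raise ValueError("invalid configuration: " + "; ".join(lines)) from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation from the single global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def build_feature_matrix(spectra, pre: PreprocessParams | None = None,
                         min_height_frac: float = 0.03, min_width: int = 5,
                         tol_ppm: float = 2500.0, impute: str = "zero",
                         exclude_matrix_region: bool = False) -> FeatureMatrix:
    """Preprocess -> detect -> flag -> align -> impute -> collapse replicates."""
    peaklists = []
    for s in spectra:
        cleaned = preprocess_spectrum(s, pre)
        pl = detect_peaks(cleaned, min_height_frac=min_height_frac,
                          min_width_points=min_width)
        peaklists.append(flag_matrix_region(pl, exclude=exclude_matrix_region))
    fm = greedy_align(peaklists, tol_ppm=tol_ppm)
    fm = impute_missing(fm, mode=impute)
    return collapse_replicates(fm)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write tables plus a manifest under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            cfg.model_dump_json().encode()).hexdigest()[:16],
        "stages": {},
    }

    def done(stage: str, **info):
        manifest["stages"][stage] = {"status": "completed", **info}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        # ---- synth / load -------------------------------------------------
        if cfg.synth is not None:
            if cfg.synth.paper_default:
                scfg = synth.paper_default_config(seed=stage_seed(cfg.seed, "synth"))
            else:
                scfg = synth.SynthConfig(**cfg.synth.model_dump(exclude={"paper_default"}),
                                         seed=stage_seed(cfg.seed, "synth"))
            spectra, labels, truth = synth.generate_cohort(scfg)
            done("synth", n_spectra=len(spectra), n_samples=len(labels))
        else:
            spectra, labels, truth = synth.read_cohort(cfg.input_dir)
            done("synth", source=cfg.input_dir, n_spectra=len(spectra))

        # ---- preprocess + peaks ------------------------------------------
        pre = PreprocessParams(**cfg.preprocess.model_dump())
        fm = build_feature_matrix(
            spectra, pre, min_height_frac=cfg.peaks.min_height_frac,
            min_width=cfg.peaks.min_width, tol_ppm=cfg.peaks.tol_ppm,
            impute=cfg.peaks.impute,
            exclude_matrix_region=cfg.peaks.exclude_matrix_region)
        del spectra
        fm.write_csv(outdir / "feature_matrix.csv")
        done("preprocess", params=cfg.preprocess.model_dump())
        done("peaks", n_features=fm.n_features, n_samples=fm.n_samples)

        # ---- screening ----------------------------------------------------
        dt = screening.differential_test(fm, fdr=cfg.screening.fdr,
                                         p_thresh=cfg.screening.p_thresh,
                                         fc_thresh=cfg.screening.fc_thresh)
        dt.table.to_csv(outdir / "differential_table.csv", index=False)
        up, down = screening.volcano_filter(dt, cfg.screening.p_thresh,
                                            cfg.screening.fc_thresh)
        screening.top_k(dt, by="abs_log2fc", k=min(cfg.screening.top_k, len(dt.table))
                        ).to_csv(outdir / "top_by_fc.csv", index=False)
        screening.top_k(dt, by="p", k=min(cfg.screening.top_k, len(dt.table))
                        ).to_csv(outdir / "top_by_p.csv", index=False)
        done("screening", n_up=len(up), n_down=len(down))

        # ---- bench ----------------------------------------------------
        bseed = stage_seed(cfg.seed, "bench")
        bench_out = {}
        for name in cfg.bench.models:
            ev = bench.crossval_evaluate(fm, name, k=cfg.bench.k_folds, seed=bseed)
            bench_out[name] = {
                "macro_mean_auc": ev.macro_mean_auc,
                "macro_sd_auc": ev.macro_sd_auc,
                "mean_auc": ev.mean_auc, "sd_auc": ev.sd_auc,
                "confusion": ev.confusion, "metrics": ev.metrics,
            }
        (outdir / "bench.json").write_text(json.dumps(bench_out, indent=1))
        done("bench", models=list(bench_out))

        # ---- interpret ----------------------------------------------------
        iseed = stage_seed(cfg.seed, "interpret")
        names = [f"{mz:.2f}" for mz in fm.feature_mzs]
        y = (np.asarray(fm.labels) == "cancer").astype(int)
        rf = bench.make_model("random_forest", seed=iseed)
        rf.fit(fm.values, y)
        gini = interpret.model_importances(rf, names)
        bg = interpret.draw_background(
            fm.values, n=min(cfg.interpret.n_background, fm.n_samples), seed=iseed)
        rng = np.random.default_rng(iseed)
        explain_idx = rng.choice(fm.n_samples,
                                 size=min(cfg.interpret.explain_samples, fm.n_samples),
                                 replace=False)
        model_fn = lambda X: rf.predict_proba(X)[:, 1]
        phi, base = interpret.shap_attributions(model_fn, bg, fm.values[explain_idx],
                                                budget=cfg.interpret.shap_budget,
                                                seed=iseed)
        shap_r = interpret.shap_ranking(phi, names)
        lime_r = interpret.lime_rankings(model_fn, fm.values, names,
                                         explain_idx=explain_idx,
                                         n_perturbations=cfg.interpret.lime_perturbations,
                                         seed=iseed)
        cons = interpret.consensus_top_k([gini, shap_r, lime_r],
                                         k=cfg.interpret.k_consensus)
        inter = interpret.cross_validated_importance_intersection(
            fm, top_m=cfg.interpret.top_m_intersection, seed=iseed)
        for r in (gini, shap_r, lime_r):
            pd.DataFrame({"feature": r.feature_names, "score": r.scores,
                          "rank": r.ranks}).to_csv(
                outdir / f"importance_{r.method}.csv", index=False)
        (outdir / "consensus.json").write_text(json.dumps({
            "selected": cons.selected, "votes": cons.votes,
            "shap_base_value": base,
            "tree_importance_intersection": sorted(inter)}, indent=1))
        done("interpret", consensus_size=len(cons.selected),
             intersection=sorted(inter))

        # ---- clinical ----------------------------------------------------
        cseed = stage_seed(cfg.seed, "clinical")
        dca = clinical.dca_crossval(fm, cfg.clinical.model, k=cfg.clinical.k_folds,
                                    seed=cseed,
                                    treat_all_variant=cfg.clinical.treat_all_variant)
        pd.DataFrame({"threshold": dca.thresholds, "nb_model": dca.nb_model,
                      "nb_low": dca.nb_ci_low, "nb_high": dca.nb_ci_high,
                      "nb_all": dca.nb_all}).to_csv(outdir / "dca_model.csv",
                                                    index=False)
        shortlist = screening.top_k(dt, by="p",
                                    k=min(cfg.clinical.n_single_features, len(dt.table)))
        singles = []
        for row in shortlist.itertuples():
            j = int(np.argmin(np.abs(fm.feature_mzs - row.mz)))
            vals = fm.values[:, j]
            _, _, auc, direction = clinical.single_feature_roc(vals, fm.labels)
            oriented = vals if direction == "high" else -vals
            yr = clinical.youden_optimize(oriented, fm.labels)
            sdca = clinical.single_feature_dca(vals, fm.labels, direction,
                                               treat_all_variant=cfg.clinical.treat_all_variant)
            singles.append({"mz": float(row.mz), "auc": auc, "direction": direction,
                            "youden_j": yr.optimal_j,
                            "youden_threshold": yr.optimal_threshold,
                            "dca_benefit_area": sdca.benefit_area})
        pd.DataFrame(singles).to_csv(outdir / "single_feature_clinical.csv",
                                     index=False)
        done("clinical", model_benefit_area=dca.benefit_area,
             n_single_features=len(singles))

        # ---- cluster ----------------------------------------------------
        kseed = stage_seed(cfg.seed, "cluster")
        if cfg.cluster.use_differential_features and (len(up) + len(down)) >= 2:
            keep_mz = np.concatenate([up["mz"].to_numpy(), down["mz"].to_numpy()])
            cols = [int(np.argmin(np.abs(fm.feature_mzs - mz))) for mz in keep_mz]
            Xc = fm.values[:, sorted(set(cols))]
        else:
            Xc = fm.values
        reports = {}
        for method, assign in (
                ("bisecting_kmeans", cluster.bisecting_kmeans(Xc, k=2, seed=kseed)),
                ("birch", cluster.birch_cluster(
                    Xc, threshold=cfg.cluster.birch_threshold,
                    branching_factor=cfg.cluster.birch_branching_factor, k=2))):
            rand, ami = cluster.concordance(assign, fm.labels)
            reports[method] = {"rand": rand, "ami": ami}
            pd.DataFrame({"sample_id": fm.sample_ids, "cluster": assign,
                          "group": fm.labels}).to_csv(
                outdir / f"clusters_{method}.csv", index=False)
        coords = cluster.embed(Xc, method=cfg.cluster.embedding, dims=2, seed=kseed)
        pd.DataFrame({"sample_id": fm.sample_ids, "x": coords[:, 0],
                      "y": coords[:, 1], "group": fm.labels}).to_csv(
            outdir / "embedding.csv", index=False)
        done("cluster", **reports)
    except Exception as exc:
        manifest["stages"]["__failure__"] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    return manifest
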