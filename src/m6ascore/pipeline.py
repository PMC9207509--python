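"""End-to-end pipeline: simulate/ingest -> batch-correct -> cluster -> DE ->
signature -> survival -> enrichment -> response.

Every stage writes plain TSV/JSON artifacts into the output directory so any
stage can be inspected or re-run from its predecessor's outputs, and the
summary embeds the seed and a config hash so a run is replayable
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import diffexpr as _diffexpr
from . import enrich as _enrich
from . import signature as _signature
from . import survstat as _survstat
from .dataio import (ClinicalTable, ExpressionMatrix, combat_adjust,
                     merge_expression, read_clinical, read_expression, read_gmt)
from .syndata import (SimulationConfig, config_from_dict, generate_cohort,
                      generate_response_cohort)

log = logging.getLogger("m6ascore")


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; defaults mirror the study's thresholds
    (DE adjusted p < 0.01, Cox filter p < 0.05, cutpoint minprop 0.1,
    |NES| > 1 with nominal p < 0.05, k scanned over 2..10)."""

    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    simulate: bool = True
    expression_paths: list = field(default_factory=list)  # (path, batch) pairs
    clinical_path: str = None
    kmax: int = 10
    cluster_reps: int = 1000
    related_cluster_reps: int = 200
    subsample: float = 0.8
    kmeans_restarts: int = 20
    de_alpha: float = 0.01
    cox_alpha: float = 0.05
    rf_trees: int = 500
    cutpoint_minprop: float = 0.1
    gsea_nes_min: float = 1.0
    gsea_alpha: float = 0.05
    gsea_permutations: int = 1000
    roc_horizons: tuple = (5.0, 10.0, 15.0)
    gmt_path: str = None
    marker_gmt_path: str = None
    tis_genes: list = None
    with_response: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "cox_alpha", "cutpoint_minprop", "gsea_alpha",
                     "subsample"):
            v = getattr(self, name)
            if not (0 < v < 1 or (name == "subsample" and v == 1)):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")
        if self.cluster_reps < 2:
            raise ValueError("cluster_reps must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("input")
def _load_inputs(config: PipelineConfig, out_dir: str):
    if config.simulate:
        sim = config_from_dict({"seed": config.seed, **config.simulation})
        cohort = generate_cohort(sim)
        cohort.write(os.path.join(out_dir, "cohort"))
        return cohort.expression, cohort.clinical, cohort
    mats = [read_expression(p, batch_label=b) for p, b in config.expression_paths]
    expr = merge_expression(mats)
    clinical = read_clinical(config.clinical_path)
    return expr, clinical.aligned_to(expr.samples), None


@_stage("batch-correct")
def _batch_correct(expr: ExpressionMatrix, out_dir: str):
    adjusted, model = combat_adjust(expr)
    adjusted.to_tsv(os.path.join(out_dir, "expression_adjusted.tsv"))
    model.to_json(os.path.join(out_dir, "batch_model.json"), genes=expr.genes)
    return adjusted


@_stage("cluster")
def _cluster_regulators(expr, clinical, config: PipelineConfig, out_dir: str):
    panel = [g for g in _cluster.RegulatorPanel().all_genes if g in expr.genes]
    if len(panel) < 2:
        raise ValueError("regulator panel absent from the expression matrix")
    res = _cluster.consensus_cluster(
        expr.subset_genes(panel), kmax=config.kmax, reps=config.cluster_reps,
        subsample=config.subsample, seed=config.seed,
        n_init=config.kmeans_restarts,
    )
    chosen = _cluster.select_k(res)
    k_used = 2  # the two-signature comparison downstream is pairwise
    labels = res.labels_series(k_used)
    mapping = _cluster.label_m6a_clusters(labels, clinical)
    named = _cluster.apply_cluster_names(labels, mapping)
    named.rename("m6a_cluster").to_frame().to_csv(
        os.path.join(out_dir, "m6a_clusters.tsv"), sep="\t"
    )
    with open(os.path.join(out_dir, "consensus_summary.json"), "w") as fh:
        json.dump(
            {
                "chosen_k": int(chosen),
                "pac": {str(k): v for k, v in res.pac.items()},
                "delta_area": {str(k): v for k, v in res.delta_area.items()},
            },
            fh, indent=1,
        )
    return named, chosen, res


@_stage("differential-expression")
def _de(expr, named, config: PipelineConfig, out_dir: str):
    de = _diffexpr.moderated_de(expr, named, alpha_adj=config.de_alpha)
    de.to_csv(os.path.join(out_dir, "de_results.tsv"), sep="\t")
    degs = _diffexpr.significant_genes(de)
    return de, degs


@_stage("related-clusters")
def _related_clusters(expr, clinical, degs, config: PipelineConfig, out_dir: str):
    if len(degs) < 2:
        log.warning("fewer than 2 DEGs; skipping m6A-related clustering")
        return None
    res = _cluster.consensus_cluster(
        expr.subset_genes(degs), kmax=min(config.kmax, 6),
        reps=config.related_cluster_reps, subsample=config.subsample,
        seed=config.seed + 1, n_init=max(4, config.kmeans_restarts // 4),
    )
    labels = res.labels_series(2)
    mapping = _cluster.label_m6a_clusters(labels, clinical)
    named = _cluster.apply_cluster_names(labels, mapping)
    named.rename("m6a_related_cluster").to_frame().to_csv(
        os.path.join(out_dir, "m6a_related_clusters.tsv"), sep="\t"
    )
    return named


@_stage("signature")
def _build_signature(expr, clinical, named, degs, config: PipelineConfig,
                     out_dir: str):
    deg_expr = expr.subset_genes(degs)
    kept = _signature.rf_redundancy_filter(
        deg_expr, named, n_trees=config.rf_trees, seed=config.seed
    )
    prognostic = _signature.cox_univariate_filter(
        expr, clinical, kept, alpha=config.cox_alpha
    )
    if len(prognostic) < 2:
        raise ValueError(
            f"only {len(prognostic)} prognostic genes survive the filters"
        )
    model = _signature.fit_signature(expr, prognostic)
    scores = _signature.score_samples(expr, model, training=True)
    cutoff = _signature.optimal_cutoff(
        scores, clinical, minprop=config.cutpoint_minprop
    )
    model.cutoff = cutoff
    scores = _signature.ScoreTable(scores=scores.scores, cutoff=cutoff)
    scores = _signature.orient_score(scores, clinical, model)
    model.to_json(os.path.join(out_dir, "signature_model.json"))
    scores.to_tsv(os.path.join(out_dir, "m6a_scores.tsv"))
    return model, scores, kept, prognostic


@_stage("survival")
def _survival(scores, clinical, config: PipelineConfig, out_dir: str):
    clin = clinical.aligned_to(scores.scores.index).table
    times = clin["os_time"].to_numpy(float)
    events = clin["os_event"].to_numpy(int)
    groups = scores.group.to_numpy()
    stat, p = _survstat.logrank_test(times, events, groups)
    medians = {}
    for grp in ("low", "high"):
        m = groups == grp
        medians[grp] = _survstat.km_median_or_rmst(times[m], events[m])
    cov = pd.DataFrame({"low_score": (groups == "low").astype(float)})
    if "age" in clin:
        cov["age"] = clin["age"].to_numpy(float)
    if "ldh" in clin:
        cov["ldh_high"] = (clin["ldh"] == "high").astype(float).to_numpy()
    cox = _survstat.cox_fit(times, events, cov)
    horizons = [h for h in config.roc_horizons if h <= times.max()]
    troc = None
    if horizons and events.sum() > 0:
        # higher risk = lower score; use the negated score as the marker
        troc = _survstat.time_roc(times, events, -scores.scores.to_numpy(), horizons)
    result = {
        "logrank_statistic": stat,
        "logrank_p": p,
        "median_low": medians["low"],
        "median_high": medians["high"],
        "cox_converged": cox.converged,
        "cox_hr_low_score": (
            cox.hazard_ratio("low_score") if cox.converged else None
        ),
        "time_auc": (
            {str(h): float(a) for h, a in zip(troc.horizons, troc.auc)}
            if troc is not None else {}
        ),
    }
    with open(os.path.join(out_dir, "survival_summary.json"), "w") as fh:
        json.dump(result, fh, indent=1)
    return result


@_stage("enrichment")
def _enrichment(expr, named, scores, config: PipelineConfig, out_dir: str):
    out = {}
    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        gsea = _enrich.gsea_two_group(
            expr, named, sets, n_perm=config.gsea_permutations,
            seed=config.seed, nes_min=config.gsea_nes_min,
            alpha=config.gsea_alpha,
        )
        gsea.table.to_csv(os.path.join(out_dir, "gsea_results.tsv"), sep="\t")
        out["n_significant_sets"] = int(gsea.table["significant"].sum())
    if config.marker_gmt_path:
        marker_sets = read_gmt(config.marker_gmt_path)
        cell_scores, report = _enrich.immune_marker_scores(
            expr, marker_sets, scores=scores.scores, groups=scores.group
        )
        cell_scores.to_csv(os.path.join(out_dir, "immune_scores.tsv"), sep="\t")
        if report is not None:
            report.to_csv(os.path.join(out_dir, "immune_report.tsv"), sep="\t")
        out["n_marker_sets"] = len(marker_sets)
    return out


@_stage("response")
def _response(model, config: PipelineConfig, out_dir: str):
    sim = config_from_dict({"seed": config.seed + 101, **config.simulation})
    cohort = generate_response_cohort(sim)
    scores = _signature.score_samples(cohort.expression, model)
    clin = cohort.clinical.table
    # low score predicts response: use the negated score as the marker
    auc, _ = _survstat.binary_roc(clin["response"].to_numpy(), -scores.scores.to_numpy())
    rho, rho_p = _survstat.spearman(
        scores.scores.to_numpy(), clin["neoantigen_burden"].to_numpy()
    )
    result = {
        "response_auc": auc,
        "neoantigen_spearman_rho": rho,
        "neoantigen_spearman_p": rho_p,
        "n": int(len(clin)),
    }
    scores.to_tsv(os.path.join(out_dir, "response_scores.tsv"))
    with open(os.path.join(out_dir, "response_summary.json"), "w") as fh:
        json.dump(result, fh, indent=1)
    return result


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute every stage in order and return the summary dict.

    The summary (also written as ``summary.json``) records the seed, config
    hash, chosen k, DEG and signature-gene counts, score cutoff, group
    survival medians, log-rank p, the multivariate hazard ratio of the
    low-score group, time-dependent AUCs and, when enabled, the response
    AUC of a held-out simulated immunotherapy cohort.
    """
    os.makedirs(out_dir, exist_ok=True)
    expr, clinical, cohort = _load_inputs(config, out_dir)
    if expr.batch.nunique() >= 2:
        expr = _batch_correct(expr, out_dir)
    named, chosen_k, _cons = _cluster_regulators(expr, clinical, config, out_dir)
    de, degs = _de(expr, named, config, out_dir)
    related = _related_clusters(expr, clinical, degs, config, out_dir)
    model, scores, kept, prognostic = _build_signature(
        expr, clinical, named, degs, config, out_dir
    )
    surv = _survival(scores, clinical, config, out_dir)
    enr = _enrichment(expr, named, scores, config, out_dir)
    resp = _response(model, config, out_dir) if config.with_response else {}

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": int(expr.n_samples),
        "n_genes": int(expr.n_genes),
        "chosen_k": int(chosen_k),
        "n_degs": int(len(degs)),
        "n_rf_retained": int(len(kept)),
        "n_signature_genes": int(len(prognostic)),
        "signature_genes": list(prognostic),
        "cutoff": float(model.cutoff),
        **surv,
        **enr,
        **resp,
    }
    if cohort is not None:
        from sklearn.metrics import adjusted_rand_score

        summary["cluster_ari_vs_truth"] = float(adjusted_rand_score(
            cohort.truth.cluster.to_numpy(), named.to_numpy()
        ))
        rho, _ = _survstat.spearman(
            scores.scores.to_numpy(), cohort.truth.latent_score.to_numpy()
        )
        summary["score_latent_spearman"] = rho
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
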