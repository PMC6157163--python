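"""End-to-end orchestration: preprocess -> DE selection -> scores -> classifier sweep.

The pipeline sequences the five analysis stages, derives one
deterministic seed per stage from the master seed, logs every threshold
with before/after counts, and writes per-stage outputs plus a
machine-readable run report.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bnc import (ModelAssessment, build_bnc_structure, cv_assess, fit_clg,
                  pareto_order)
from .de_stability import bootstrap_rankings, select_genes_cdf
from .functional import score_edges
from .io import (EnsembleGraph, ExpressionMatrix, FeatureRole, PhenotypeVector,
                 PredictionGraph, ScoredEdge, export_graph, read_edge_lists,
                 read_expression, read_phenotype, write_edge_list)
from .preprocess import filter_presence, impute_knn, normalize
from .structural import ensemble_structural_scores, pairwise_weights
from .synthetic import SimulationConfig, simulate_dataset, simulate_engines

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "de_select", "structural", "functional", "ensemble")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for one run."""

    mirna_path: str | None = None
    gene_path: str | None = None
    phenotype_path: str | None = None
    edge_list_paths: list[str] = field(default_factory=list)
    out_dir: str = "miregnet_run"
    # preprocess
    min_presence: float = 0.9
    knn: int = 3
    log2: bool = False
    quantile_normalize: bool = True
    # differential expression
    de_method: str = "sam"
    bootstrap_B: int = 100
    alpha: float = 0.05
    de_quantile: float = 0.95
    cdf_mode: str = "unique"
    n_permutations: int = 100
    # functional score
    grid_size: int = 128
    log_base: str = "e"
    # model sweep
    max_edges: int = 100
    cv_repeats: int = 5
    cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    selected_genes: set[str]
    weights: dict[tuple[int, int], float]
    ensemble: EnsembleGraph
    assessment: ModelAssessment
    optimal_edges: list[ScoredEdge]
    report: dict


def _preprocess_matrix(m: ExpressionMatrix, cfg: PipelineConfig) -> ExpressionMatrix:
    n0 = len(m.feature_ids)
    if m.n_missing:
        m = filter_presence(m, cfg.min_presence)
        logger.info("presence filter (> %.2f): %d -> %d features",
                    cfg.min_presence, n0, len(m.feature_ids))
        m = impute_knn(m, cfg.knn)
        logger.info("KNN imputation (k=%d) complete; %d missing remain",
                    cfg.knn, m.n_missing)
    if cfg.quantile_normalize or cfg.log2:
        m = normalize(m, log2_first=cfg.log2)
    return m


def run_pipeline(
    cfg: PipelineConfig,
    m_mirna: ExpressionMatrix | None = None,
    m_gene: ExpressionMatrix | None = None,
    phen: PhenotypeVector | None = None,
    graphs: list[PredictionGraph] | None = None,
    truth: set[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run all five stages; inputs come from the config paths unless given in memory.

    Writes per-stage TSVs, the per-threshold metrics table, the optimal
    network in GraphML and a JSON run report to ``cfg.out_dir``.  When a
    planted ``truth`` edge set is supplied (synthetic studies), the report
    additionally carries precision/recall of the optimal network.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stages": {},
    }
    try:
        result = _run_stages(cfg, report, out, m_mirna, m_gene, phen, graphs, truth)
    except Exception as exc:
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return result


def _run_stages(cfg, report, out, m_mirna, m_gene, phen, graphs, truth):
    # ---- load -----------------------------------------------------------
    if m_mirna is None:
        m_mirna = read_expression(cfg.mirna_path, FeatureRole.MIRNA)
    if m_gene is None:
        m_gene = read_expression(cfg.gene_path, FeatureRole.GENE)
    if phen is None:
        phen = read_phenotype(cfg.phenotype_path)
    if graphs is None:
        graphs = read_edge_lists(cfg.edge_list_paths)

    # ---- stage 1: preprocess -------------------------------------------
    report["stages"]["preprocess"] = stage = {}
    stage["mirna_features_in"] = len(m_mirna.feature_ids)
    stage["gene_features_in"] = len(m_gene.feature_ids)
    m_mirna = _preprocess_matrix(m_mirna, cfg)
    m_gene = _preprocess_matrix(m_gene, cfg)
    stage["mirna_features_out"] = len(m_mirna.feature_ids)
    stage["gene_features_out"] = len(m_gene.feature_ids)

    # ---- stage 2: differential-expression selection --------------------
    report["stages"]["de_select"] = stage = {}
    run = bootstrap_rankings(
        m_gene, phen, method=cfg.de_method, B=cfg.bootstrap_B,
        seed=stage_seed(cfg.seed, "de_select"),
        n_permutations=cfg.n_permutations,
    )
    sel = select_genes_cdf(run, alpha=cfg.alpha, quantile=cfg.de_quantile,
                           mode=cfg.cdf_mode)
    stage["method"] = cfg.de_method
    stage["bootstrap_B"] = cfg.bootstrap_B
    stage["cutoff"] = sel.cutoff
    stage["genes_selected"] = len(sel.selected)
    logger.info("CDF filter (alpha=%.2f, q=%.2f): %d -> %d genes (cutoff %.2f)",
                cfg.alpha, cfg.de_quantile, len(m_gene.feature_ids),
                len(sel.selected), sel.cutoff)
    if not sel.selected:
        raise RuntimeError("differential-expression filter selected no genes")
    selected_genes = sel.selected
    m_gene_sel = m_gene.copy_with(m_gene.data.loc[sorted(selected_genes)])
    pd.Series(sorted(selected_genes)).to_csv(out / "selected_genes.tsv",
                                             sep="\t", index=False, header=False)

    # ---- stage 3: structural score -------------------------------------
    report["stages"]["structural"] = stage = {}
    mirna_ids = set(m_mirna.feature_ids)
    restricted = []
    for gph in graphs:
        kept = frozenset(e for e in gph.edges
                         if e[0] in mirna_ids and e[1] in selected_genes)
        logger.info("engine %s: %d -> %d edges after feature restriction",
                    gph.engine_name, len(gph.edges), len(kept))
        restricted.append(PredictionGraph(engine_name=gph.engine_name, edges=kept))
    # the consistency universe is the full candidate grid (every possible
    # miRNA-gene interaction among the retained features), not just the
    # union of predictions: engine overlaps are sparse and the union
    # universe would drive most consistencies negative
    grid_size = len(mirna_ids) * len(selected_genes)
    gs = pairwise_weights(restricted, universe_size=grid_size)
    b_scores = ensemble_structural_scores(gs)
    stage["universe_edges"] = len(gs.universe)
    stage["scored_edges"] = len(b_scores)
    if not b_scores:
        raise RuntimeError("no edge is supported by two or more engines")
    weights_frame = pd.DataFrame(
        [(gs.graphs[i].engine_name, gs.graphs[j].engine_name, w)
         for (i, j), w in sorted(gs.weights.items())],
        columns=["engine_i", "engine_j", "weight"],
    )
    weights_frame.to_csv(out / "pairwise_weights.tsv", sep="\t", index=False)

    # ---- stage 4: functional score -------------------------------------
    report["stages"]["functional"] = stage = {}
    candidates = sorted(b_scores)
    d_scores = score_edges(candidates, m_mirna, m_gene_sel, phen,
                           grid_size=cfg.grid_size, log_base=cfg.log_base)
    stage["edges_scored"] = len(d_scores)
    clamped = {e: max(v, -1e-6) for e, v in d_scores.items()}
    n_clamped = sum(1 for e in d_scores if d_scores[e] < -1e-6)
    if n_clamped:
        logger.warning("%d functional scores below -1e-6 floored", n_clamped)
    edges = [ScoredEdge(m, g, b_scores[(m, g)], clamped[(m, g)])
             for (m, g) in candidates]
    export_graph(edges, out / "scored_edges.tsv", fmt="tsv")

    # ---- stage 5: ensemble sweep ----------------------------------------
    report["stages"]["ensemble"] = stage = {}
    ensemble = pareto_order(edges)
    T = min(cfg.max_edges, len(ensemble.ordered_edges))
    assessment = cv_assess(
        ensemble, m_mirna, m_gene_sel, phen, T=T,
        seed=stage_seed(cfg.seed, "ensemble"),
        repeats=cfg.cv_repeats, folds=cfg.cv_folds,
    )
    t_opt = assessment.t_optimal
    stage["candidate_pool"] = len(ensemble.ordered_edges)
    stage["T"] = T
    stage["t_optimal"] = t_opt
    stage["concordant"] = assessment.concordant
    for metric in ("auc", "accuracy", "bic", "loglik"):
        stage[f"{metric}_at_optimum"] = float(
            assessment.mean[metric][assessment.t_values.index(t_opt)])

    metrics_frame = pd.DataFrame({
        "t": assessment.t_values,
        **{f"{m}_{s}": (assessment.mean[m] if s == "mean" else assessment.sd[m])
           for m in ("auc", "accuracy", "bic", "loglik") for s in ("mean", "sd")},
    })
    metrics_frame.to_csv(out / "metrics.tsv", sep="\t", index=False,
                         float_format="%.6f")

    optimal_edges = ensemble.ordered_edges[:t_opt]
    model = build_bnc_structure(
        EnsembleGraph(ordered_edges=ensemble.ordered_edges, t=t_opt,
                      front_index=ensemble.front_index),
        t_opt, phen.classes,
    )
    fit_clg(model, m_mirna, m_gene_sel, phen)
    export_graph(optimal_edges, out / "optimal_network.graphml", fmt="graphml")
    write_edge_list([(e.mirna_id, e.gene_id) for e in optimal_edges],
                    out / "optimal_edges.tsv")

    if truth is not None:
        found = {(e.mirna_id, e.gene_id) for e in optimal_edges}
        tp = len(found & truth)
        stage["precision"] = tp / len(found) if found else 0.0
        stage["recall"] = tp / len(truth) if truth else 0.0

    report["completed_stages"] = list(STAGES)
    return PipelineResult(
        config=cfg,
        selected_genes=selected_genes,
        weights=gs.weights,
        ensemble=ensemble,
        assessment=assessment,
        optimal_edges=optimal_edges,
        report=report,
    )


def recover_planted(seed: int = 0, sim: SimulationConfig | None = None,
                    out_dir: str | Path | None = None) -> dict:
    """Full pipeline on a strong-signal simulation; returns the recovery report.

    Simulates expression data and engine graphs with planted regulations,
    runs all five stages, and reports precision/recall of the optimal
    network against the planted truth together with the headline metrics.
    """
    sim = sim if sim is not None else SimulationConfig.strong_signal(seed)
    m_mirna, m_gene, phen, truth = simulate_dataset(sim)
    graphs = simulate_engines(truth, sim)
    cfg = PipelineConfig(
        out_dir=str(out_dir) if out_dir else f"scratch/recovery_seed{seed}",
        quantile_normalize=False,
        cdf_mode="all",
        bootstrap_B=100,
        n_permutations=100,
        max_edges=25,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cfg, m_mirna=m_mirna, m_gene=m_gene, phen=phen,
                              graphs=graphs, truth=truth)
    stage = result.report["stages"]["ensemble"]
    return {
        "seed": seed,
        "precision": stage["precision"],
        "recall": stage["recall"],
        "t_optimal": stage["t_optimal"],
        "concordant": stage["concordant"],
        "auc": stage["auc_at_optimum"],
        "accuracy": stage["accuracy_at_optimum"],
        "genes_selected": result.report["stages"]["de_select"]["genes_selected"],
        "scored_edges": result.report["stages"]["structural"]["scored_edges"],
    }
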