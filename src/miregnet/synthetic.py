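"""Seeded generator of class-labelled expression data with planted regulations.

The generator emulates the statistical structure the pipeline assumes:
miRNA profiles are Gaussian with class-shifted means and unit within-
class standard deviation; each planted gene depends linearly on its
regulating miRNA with class-specific intercept and slope plus Gaussian
noise; non-planted features are pure noise.  K prediction engines are
noisy views of the planted edge set (per-engine true- and false-positive
rates over the full miRNA x gene candidate grid).  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (EnsembleGraph, ExpressionMatrix, FeatureRole, PhenotypeVector,
                 PredictionGraph, ScoredEdge)

Edge = tuple[int, int]


def _default_planted() -> dict[Edge, dict]:
    """13 planted regulations over 7 miRNAs and 13 genes."""
    pairs = [(0, 0), (0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6),
             (3, 7), (4, 8), (4, 9), (5, 10), (5, 11), (6, 12)]
    return {p: {} for p in pairs}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``planted_edges`` maps (miRNA index, gene index) to optional per-edge
    overrides of ``beta`` / ``intercept`` (each a class -> value map).
    Defaults mirror the study scale: two classes of ~20 samples, a
    13-edge planted truth over 7 miRNAs, five discordant engines.
    """

    n_mirna: int = 8
    n_gene: int = 40
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"control": 20, "case": 20})
    planted_edges: dict[Edge, dict] = field(default_factory=_default_planted)
    beta: dict[str, float] = field(
        default_factory=lambda: {"control": 2.0, "case": 2.0})
    intercept: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "case": 0.0})
    mirna_shift: float = 1.0
    noise_sd: float = 0.5
    null_gene_sd: float = 1.0
    n_engines: int = 5
    tpr: float = 0.85
    fpr: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (i, j) in self.planted_edges:
            if not (0 <= i < self.n_mirna and 0 <= j < self.n_gene):
                raise ValueError(f"planted edge ({i}, {j}) outside the feature grid")
        genes = [j for (_, j) in self.planted_edges]
        if len(set(genes)) != len(genes):
            raise ValueError("each planted gene may have exactly one regulating miRNA")
        if not (0 <= self.tpr <= 1 and 0 <= self.fpr <= 1):
            raise ValueError("tpr and fpr must be probabilities")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def classes(self) -> list[str]:
        return sorted(self.n_samples)

    def mirna_id(self, i: int) -> str:
        return f"mir{i:03d}"

    def gene_id(self, j: int) -> str:
        return f"g{j:03d}"

    @property
    def truth_ids(self) -> set[tuple[str, str]]:
        return {(self.mirna_id(i), self.gene_id(j)) for (i, j) in self.planted_edges}

    @classmethod
    def strong_signal(cls, seed: int = 0) -> "SimulationConfig":
        """The strong-signal validation condition for end-to-end recovery.

        Two differentially expressed hub miRNAs drive the 13 planted
        genes, so the joint class signal stays redundant across genes
        sharing a hub and classification does not saturate before the
        full truth is in the model, while every planted gene still
        carries a marginal shift large enough (given the cohort size)
        for the bootstrap CDF filter to separate it from the luckiest of
        ~300 null genes.  Regulations are tight (residual sd 0.3 against
        unit miRNA sd) and the gene pool is dominated by nulls,
        mirroring the ~5% selection rate the CDF filter is built for.
        """
        hubs = {(0, j): {} for j in range(7)}
        hubs.update({(1, j): {} for j in range(7, 13)})
        return cls(
            n_mirna=8,
            n_gene=300,
            n_samples={"control": 150, "case": 150},
            planted_edges=hubs,
            beta={"control": 1.0, "case": 1.0},
            intercept={"control": -0.06, "case": 0.06},
            mirna_shift=0.65,
            noise_sd=0.3,
            n_engines=5,
            tpr=0.85,
            fpr=0.05,
            seed=seed,
        )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PhenotypeVector, set[tuple[str, str]]]:
    """Draw one dataset: miRNA matrix, gene matrix, phenotype, planted truth.

    MiRNAs appearing in planted edges get class-shifted means of
    +-``mirna_shift``/2 (the second class in sorted order is shifted up);
    other miRNAs are standard normal in both classes.  Planted genes
    follow the class-specific linear model; other genes are
    Normal(0, null_gene_sd).  ``missing_rate`` masks miRNA cells at
    random.  Bit-identical output for identical configs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    classes = cfg.classes
    labels: list[str] = []
    sample_ids: list[str] = []
    for c in classes:
        for k in range(cfg.n_samples[c]):
            sample_ids.append(f"{c}{k:03d}")
            labels.append(c)
    n = len(sample_ids)
    label_arr = np.asarray(labels, dtype=object)
    shift_sign = {classes[0]: -0.5, classes[1]: +0.5}
    planted_mirnas = {i for (i, _) in cfg.planted_edges}
    gene_parent = {j: i for (i, j) in cfg.planted_edges}

    mirna = np.empty((cfg.n_mirna, n))
    for i in range(cfg.n_mirna):
        mu = np.zeros(n)
        if i in planted_mirnas:
            for c in classes:
                mu[label_arr == c] = shift_sign[c] * cfg.mirna_shift
        mirna[i] = mu + rng.standard_normal(n)

    gene = np.empty((cfg.n_gene, n))
    for j in range(cfg.n_gene):
        if j in gene_parent:
            i = gene_parent[j]
            override = cfg.planted_edges[(i, j)]
            beta = override.get("beta", cfg.beta)
            intercept = override.get("intercept", cfg.intercept)
            b = np.array([beta[c] for c in label_arr], dtype=float)
            b0 = np.array([intercept[c] for c in label_arr], dtype=float)
            gene[j] = b0 + b * mirna[i] + cfg.noise_sd * rng.standard_normal(n)
        else:
            gene[j] = cfg.null_gene_sd * rng.standard_normal(n)

    if cfg.missing_rate > 0:
        mask = rng.random(mirna.shape) < cfg.missing_rate
        mirna = np.where(mask, np.nan, mirna)

    m_mirna = ExpressionMatrix(
        data=pd.DataFrame(mirna, index=[cfg.mirna_id(i) for i in range(cfg.n_mirna)],
                          columns=sample_ids),
        role=FeatureRole.MIRNA,
    )
    m_gene = ExpressionMatrix(
        data=pd.DataFrame(gene, index=[cfg.gene_id(j) for j in range(cfg.n_gene)],
                          columns=sample_ids),
        role=FeatureRole.GENE,
    )
    phen = PhenotypeVector(sample_ids=sample_ids, labels=dict(zip(sample_ids, labels)))
    return m_mirna, m_gene, phen, cfg.truth_ids


def simulate_engines(
    truth: set[tuple[str, str]],
    cfg: SimulationConfig,
) -> list[PredictionGraph]:
    """K noisy engine views of the planted edge set.

    Each engine includes every true edge with probability ``tpr`` and
    every false candidate on the miRNA x gene grid with probability
    ``fpr``, independently.  Reproducible from the config seed.
    """
    if cfg.n_engines < 2:
        raise ValueError("need at least two engines")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    grid = [(cfg.mirna_id(i), cfg.gene_id(j))
            for i in range(cfg.n_mirna) for j in range(cfg.n_gene)]
    graphs = []
    for k in range(cfg.n_engines):
        edges = set()
        for e in grid:
            p = cfg.tpr if e in truth else cfg.fpr
            if rng.random() < p:
                edges.add(e)
        graphs.append(PredictionGraph(engine_name=f"engine{k + 1}",
                                      edges=frozenset(edges)))
    return graphs


def model_selection_fixture(
    seed: int = 0,
    n_true: int = 13,
    n_noise: int = 17,
    n_per_class: int = 40,
    residual_sd: float = 0.005,
    mirna_shift: float = 0.45,
    gene_separation: float = 0.5,
) -> tuple[EnsembleGraph, ExpressionMatrix, ExpressionMatrix, PhenotypeVector,
           set[tuple[str, str]]]:
    """Benchmark for complexity selection: planted edges first, noise after.

    Builds an ensemble graph whose first ``n_true`` edges are real
    regulations (near-deterministic: ``residual_sd`` against unit miRNA
    sd, so a correctly added gene node raises held-out likelihood) and
    whose remaining ``n_noise`` edges connect fresh pure-noise features.
    Per-feature class separations are modest (``mirna_shift`` sds for a
    miRNA, ``gene_separation`` residual sds for a gene's conditional) so
    the discrimination criteria keep improving up to the planted
    complexity instead of saturating early, while fresh noise features
    degrade them through parameter-estimation noise at the study's small
    sample size.  Scores (b, d) are assigned in decreasing order purely
    to fix the edge order.
    """
    if n_true > 13:
        raise ValueError("the planted truth has 13 edges")
    true_pairs = list(_default_planted())[:n_true]
    n_true_mirna = len({i for i, _ in true_pairs})
    cfg = SimulationConfig(
        n_mirna=n_true_mirna + n_noise,
        n_gene=n_true + n_noise,
        n_samples={"control": n_per_class, "case": n_per_class},
        planted_edges={p: {} for p in true_pairs},
        beta={"control": 1.0, "case": 1.0},
        intercept={"control": -0.5 * gene_separation * residual_sd,
                   "case": 0.5 * gene_separation * residual_sd},
        mirna_shift=mirna_shift,
        noise_sd=residual_sd,
        seed=seed,
    )
    m_mirna, m_gene, phen, truth = simulate_dataset(cfg)
    edges = []
    rank = 0
    for (i, j) in true_pairs:
        rank += 1
        edges.append(ScoredEdge(cfg.mirna_id(i), cfg.gene_id(j),
                                b=1.0 - 0.01 * rank, d=1.0 - 0.01 * rank))
    for k in range(n_noise):
        rank += 1
        edges.append(ScoredEdge(cfg.mirna_id(n_true_mirna + k),
                                cfg.gene_id(n_true + k),
                                b=1.0 - 0.01 * rank, d=1.0 - 0.01 * rank))
    g = EnsembleGraph(ordered_edges=edges, t=1,
                      front_index=list(range(1, len(edges) + 1)))
    return g, m_mirna, m_gene, phen, truth
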