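"""Conditional linear Gaussian network classifiers over the ensemble graph.

Candidate edges carrying a structural score b and a functional score d
are ordered by Pareto non-domination (both scores maximized).  For a
complexity threshold t, the classifier structure takes the endpoints of
the first t edges, orients every edge miRNA -> gene, and adds the class
node as parent of every feature; the construction is acyclic because
feature arcs only run across the bipartition.

Each feature node X_i with continuous parents Y_i follows, per class c,

    X_i | y_i, c  ~  Normal(beta0_{i,c} + beta_{i,c}^T y_i, sigma2_{i,c}),

with coefficients obtained from the class-conditional mean vector and
covariance blocks (the regression-on-parents decomposition of a joint
Gaussian).  Classification uses the maximum a posteriori rule on
log-space posteriors.  Model complexity is selected by sweeping t under
repeated stratified cross-validation and scoring AUC, accuracy, BIC and
held-out log-likelihood.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .io import EnsembleGraph, ExpressionMatrix, PhenotypeVector, ScoredEdge

logger = logging.getLogger(__name__)

CLASS_NODE = "__class__"
VARIANCE_FLOOR = 1e-8
_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# Pareto ordering
# ---------------------------------------------------------------------------

def pareto_order(edges: list[ScoredEdge]) -> EnsembleGraph:
    """Order edges by Pareto front on (b, d), both maximized.

    Edge e dominates e' when b_e >= b_e' and d_e >= d_e' with at least one
    strict inequality.  Fronts are peeled iteratively; within a front the
    order is descending b, then descending d, then lexicographic ids, so
    the "first t edges" notion is a deterministic total order.
    """
    remaining = list(edges)
    ordered: list[ScoredEdge] = []
    fronts: list[int] = []
    front = 0
    while remaining:
        front += 1
        rem = sorted(remaining,
                     key=lambda e: (-e.b, -e.d, e.mirna_id, e.gene_id))
        nondom: list[ScoredEdge] = []
        dominated: list[ScoredEdge] = []
        best_d_strict_b = -math.inf   # max d among strictly larger b
        run_b = None
        run_head_d = -math.inf        # max d of the current equal-b run
        for e in rem:
            if run_b is None or e.b < run_b:
                best_d_strict_b = max(best_d_strict_b, run_head_d)
                run_b = e.b
                run_head_d = e.d
            is_dom = (best_d_strict_b >= e.d) or (run_head_d > e.d)
            if is_dom:
                dominated.append(e)
            else:
                nondom.append(e)
        ordered.extend(nondom)
        fronts.extend([front] * len(nondom))
        remaining = dominated
    return EnsembleGraph(ordered_edges=ordered, t=1 if ordered else 1,
                         front_index=fronts)


# ---------------------------------------------------------------------------
# Structure and parameters
# ---------------------------------------------------------------------------

@dataclass
class ClgNodeParams:
    """Per-class linear Gaussian parameters of one feature node."""

    node_id: str
    beta0: dict[str, float]
    beta: dict[str, np.ndarray]
    sigma2: dict[str, float]


@dataclass
class BNClassifier:
    """DAG (class node + features) with per-class linear Gaussian parameters."""

    dag: nx.DiGraph
    classes: list[str]
    priors: dict[str, float] = field(default_factory=dict)
    params: dict[str, ClgNodeParams] = field(default_factory=dict)
    positive_class: str | None = None

    @property
    def feature_nodes(self) -> list[str]:
        return sorted(n for n in self.dag.nodes if n != CLASS_NODE)

    def continuous_parents(self, node: str) -> list[str]:
        return sorted(p for p in self.dag.predecessors(node) if p != CLASS_NODE)

    @property
    def dim(self) -> int:
        """Number of free parameters: class priors plus, per node and class,
        an intercept, a variance and one coefficient per continuous parent."""
        k = len(self.classes)
        total = k - 1
        for node in self.feature_nodes:
            total += k * (2 + len(self.continuous_parents(node)))
        return total


def build_bnc_structure(g: EnsembleGraph, t: int, classes: list[str]) -> BNClassifier:
    """Instantiate the classifier DAG for the first t ordered edges."""
    if not 1 <= t <= len(g.ordered_edges):
        raise ValueError(f"t={t} out of range [1, {len(g.ordered_edges)}]")
    dag = nx.DiGraph()
    dag.add_node(CLASS_NODE, type="class")
    for e in g.ordered_edges[:t]:
        dag.add_node(e.mirna_id, type="miRNA")
        dag.add_node(e.gene_id, type="gene")
        dag.add_edge(e.mirna_id, e.gene_id, b=e.b, d=e.d)
    for node in list(dag.nodes):
        if node != CLASS_NODE:
            dag.add_edge(CLASS_NODE, node)
    assert nx.is_directed_acyclic_graph(dag)
    return BNClassifier(dag=dag, classes=sorted(classes))


class _NodeData:
    """Feature rows stacked over both matrices, aligned to one sample order."""

    def __init__(self, m_mirna: ExpressionMatrix, m_gene: ExpressionMatrix,
                 sample_ids: list[str]):
        self.sample_ids = list(sample_ids)
        self._rows: dict[str, np.ndarray] = {}
        for m in (m_mirna, m_gene):
            sub = m.data[self.sample_ids]
            for fid in m.feature_ids:
                self._rows[fid] = sub.loc[fid].to_numpy(dtype=float)

    def row(self, node: str) -> np.ndarray:
        try:
            return self._rows[node]
        except KeyError:
            raise KeyError(f"no expression profile for node {node!r}") from None


def _fit_node(x: np.ndarray, parents: np.ndarray | None) -> tuple[float, np.ndarray, float]:
    """ML linear-Gaussian fit of one node on one class's samples.

    ``parents`` is (q, n) or None.  Returns (beta0, beta, sigma2) from the
    class-conditional covariance blocks; a singular parent covariance
    falls back to the pseudo-inverse with a warning.
    """
    if parents is None or parents.shape[0] == 0:
        mu = float(x.mean())
        return mu, np.empty(0), max(float(x.var()), VARIANCE_FLOOR)
    n = x.size
    mu_x = x.mean()
    mu_y = parents.mean(axis=1)
    xc = x - mu_x
    yc = parents - mu_y[:, None]
    s_yy = (yc @ yc.T) / n
    s_yx = (yc @ xc) / n
    s_xx = float(xc @ xc) / n
    if np.linalg.cond(s_yy) > _COND_LIMIT:
        warnings.warn("singular parent covariance; using pseudo-inverse", stacklevel=3)
        beta = np.linalg.pinv(s_yy) @ s_yx
    else:
        beta = np.linalg.solve(s_yy, s_yx)
    beta0 = float(mu_x - beta @ mu_y)
    sigma2 = max(float(s_xx - s_yx @ beta), VARIANCE_FLOOR)
    return beta0, beta, sigma2


def fit_clg(
    model: BNClassifier,
    m_mirna: ExpressionMatrix,
    m_gene: ExpressionMatrix,
    y: PhenotypeVector,
) -> BNClassifier:
    """Estimate priors and per-class node parameters by maximum likelihood."""
    data = _NodeData(m_mirna, m_gene, y.sample_ids)
    labels = y.label_array()
    counts = y.class_counts
    n = len(y.sample_ids)
    model.priors = {c: counts[c] / n for c in model.classes}
    if model.positive_class is None:
        model.positive_class = model.classes[-1]
    masks = {c: labels == c for c in model.classes}
    for node in model.feature_nodes:
        pa = model.continuous_parents(node)
        need = len(pa) + 2
        beta0, beta, sigma2 = {}, {}, {}
        for c in model.classes:
            if counts[c] < need:
                raise ValueError(
                    f"class {c!r} has {counts[c]} samples; node {node!r} with "
                    f"{len(pa)} parent(s) needs at least {need}"
                )
            x = data.row(node)[masks[c]]
            pmat = (np.vstack([data.row(p)[masks[c]] for p in pa]) if pa else None)
            b0, b, s2 = _fit_node(x, pmat)
            beta0[c], beta[c], sigma2[c] = b0, b, s2
        model.params[node] = ClgNodeParams(node_id=node, beta0=beta0,
                                           beta=beta, sigma2=sigma2)
    return model


# ---------------------------------------------------------------------------
# Inference and metrics
# ---------------------------------------------------------------------------

def _log_likelihood_matrix(model: BNClassifier, data: _NodeData) -> np.ndarray:
    """(n_classes, n_samples) matrix of sum_i log f(x_i | y_i, c)."""
    n = len(data.sample_ids)
    ll = np.zeros((len(model.classes), n))
    for node in model.feature_nodes:
        par = model.params[node]
        pa = model.continuous_parents(node)
        x = data.row(node)
        pmat = np.vstack([data.row(p) for p in pa]) if pa else None
        for ci, c in enumerate(model.classes):
            mean = par.beta0[c] + (par.beta[c] @ pmat if pmat is not None else 0.0)
            s2 = par.sigma2[c]
            ll[ci] += -0.5 * (np.log(2 * np.pi * s2) + (x - mean) ** 2 / s2)
    return ll


def classify(model: BNClassifier, sample: dict[str, float]) -> tuple[dict[str, float], str]:
    """MAP classification of one sample; posteriors computed in log-space.

    Ties in the posterior break toward the lexicographically first class.
    """
    missing = [n for n in model.feature_nodes if n not in sample]
    if missing:
        raise ValueError(f"sample is missing a value for node {missing[0]!r}")
    log_post = np.empty(len(model.classes))
    for ci, c in enumerate(model.classes):
        lp = math.log(model.priors[c])
        for node in model.feature_nodes:
            par = model.params[node]
            pa = model.continuous_parents(node)
            mean = par.beta0[c] + sum(
                b * sample[p] for b, p in zip(par.beta[c], pa)
            )
            s2 = par.sigma2[c]
            lp += -0.5 * (math.log(2 * math.pi * s2) + (sample[node] - mean) ** 2 / s2)
        log_post[ci] = lp
    log_post -= logsumexp(log_post)
    post = {c: float(np.exp(v)) for c, v in zip(model.classes, log_post)}
    predicted = model.classes[int(np.argmax(log_post))]
    return post, predicted


def trapezoidal_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    ``scores`` rank samples (higher = more positive); ``positive`` is a
    boolean array.  Tied scores collapse to a single ROC step, which
    makes the trapezoid sum identical to the Mann-Whitney statistic
    U/(n1*n0) with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes in the test set")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp = np.concatenate([[0], np.cumsum(pos)[np.append(boundaries - 1, pos.size - 1)]])
    fp = np.concatenate([[0], np.cumsum(~pos)[np.append(boundaries - 1, pos.size - 1)]])
    tpr = tp / n_pos
    fpr = fp / n_neg
    return float(np.trapezoid(tpr, fpr))


def evaluate_metrics(
    model: BNClassifier,
    m_mirna: ExpressionMatrix,
    m_gene: ExpressionMatrix,
    y: PhenotypeVector,
) -> dict[str, float]:
    """AUC, accuracy, BIC and joint log-likelihood on a test set.

    Accuracy is the MAP-correct fraction; AUC is the trapezoid sum over
    the ROC of the positive-class posterior; the log-likelihood sums
    log f(x, c) over test samples at their observed class; BIC subtracts
    log(N)/2 per free parameter.
    """
    data = _NodeData(m_mirna, m_gene, y.sample_ids)
    labels = y.label_array()
    ll = _log_likelihood_matrix(model, data)
    log_prior = np.log([model.priors[c] for c in model.classes])
    log_joint = ll + log_prior[:, None]
    log_post = log_joint - logsumexp(log_joint, axis=0)
    pred_idx = np.argmax(log_post, axis=0)
    predicted = np.asarray(model.classes, dtype=object)[pred_idx]
    accuracy = float(np.mean(predicted == labels))
    pos = model.positive_class or model.classes[-1]
    pos_idx = model.classes.index(pos)
    auc = trapezoidal_auc(np.exp(log_post[pos_idx]), labels == pos)
    class_idx = np.array([model.classes.index(c) for c in labels])
    loglik = float(log_joint[class_idx, np.arange(labels.size)].sum())
    bic = loglik - (math.log(labels.size) / 2.0) * model.dim
    return {"auc": auc, "accuracy": accuracy, "bic": bic, "loglik": loglik}


# ---------------------------------------------------------------------------
# Cross-validated complexity sweep
# ---------------------------------------------------------------------------

@dataclass
class ModelAssessment:
    """Mean +- sd over CV folds of each criterion, for t = 1..T."""

    t_values: list[int]
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    t_optimal: int = 0
    concordant: bool = False

    def criterion_argmax(self, criterion: str) -> int:
        """Complexity maximizing the mean criterion; ties favour smaller t."""
        values = self.mean[criterion]
        return self.t_values[int(np.argmax(values))]


def _sweep_metrics(
    g: EnsembleGraph,
    t_values: list[int],
    train_mirna, train_gene, y_train,
    test_mirna, test_gene, y_test,
    classes: list[str],
) -> dict[int, dict[str, float]]:
    """Evaluate all thresholds on one train/test split.

    Node parameters and per-node test log-densities depend only on the
    node's parent set, which is nested in t, so both are memoized on
    (node, parents) instead of refit for every t.
    """
    train = _NodeData(train_mirna, train_gene, y_train.sample_ids)
    test = _NodeData(test_mirna, test_gene, y_test.sample_ids)
    labels_tr = y_train.label_array()
    counts = y_train.class_counts
    priors = {c: counts[c] / len(y_train.sample_ids) for c in classes}
    masks = {c: labels_tr == c for c in classes}
    labels_te = y_test.label_array()
    n_te = len(y_test.sample_ids)

    param_cache: dict[tuple[str, tuple[str, ...]], dict] = {}
    ll_cache: dict[tuple[str, tuple[str, ...]], np.ndarray] = {}

    def node_test_ll(node: str, parents: tuple[str, ...]) -> np.ndarray:
        key = (node, parents)
        if key in ll_cache:
            return ll_cache[key]
        if key not in param_cache:
            fitted = {}
            for c in classes:
                if counts[c] < len(parents) + 2:
                    raise ValueError(
                        f"class {c!r} too small to fit node {node!r} "
                        f"with {len(parents)} parent(s)"
                    )
                x = train.row(node)[masks[c]]
                pmat = (np.vstack([train.row(p)[masks[c]] for p in parents])
                        if parents else None)
                fitted[c] = _fit_node(x, pmat)
            param_cache[key] = fitted
        fitted = param_cache[key]
        out = np.empty((len(classes), n_te))
        x = test.row(node)
        pmat = np.vstack([test.row(p) for p in parents]) if parents else None
        for ci, c in enumerate(classes):
            b0, b, s2 = fitted[c]
            mean = b0 + (b @ pmat if pmat is not None else 0.0)
            out[ci] = -0.5 * (np.log(2 * np.pi * s2) + (x - mean) ** 2 / s2)
        ll_cache[key] = out
        return out

    log_prior = np.log([priors[c] for c in classes])
    pos_idx = len(classes) - 1
    class_idx = np.array([classes.index(c) for c in labels_te])
    results: dict[int, dict[str, float]] = {}
    for t in t_values:
        # parent sets induced by the first t edges
        parent_sets: dict[str, set[str]] = {}
        for e in g.ordered_edges[:t]:
            parent_sets.setdefault(e.mirna_id, set())
            parent_sets.setdefault(e.gene_id, set()).add(e.mirna_id)
        ll = log_prior[:, None] + np.zeros((len(classes), n_te))
        dim = len(classes) - 1
        for node in sorted(parent_sets):
            parents = tuple(sorted(parent_sets[node]))
            ll = ll + node_test_ll(node, parents)
            dim += len(classes) * (2 + len(parents))
        log_post = ll - logsumexp(ll, axis=0)
        pred = np.asarray(classes, dtype=object)[np.argmax(log_post, axis=0)]
        accuracy = float(np.mean(pred == labels_te))
        loglik = float(ll[class_idx, np.arange(n_te)].sum())
        bic = loglik - (math.log(n_te) / 2.0) * dim
        metrics = {"accuracy": accuracy, "loglik": loglik, "bic": bic}
        try:
            metrics["auc"] = trapezoidal_auc(
                np.exp(log_post[pos_idx]), labels_te == classes[pos_idx]
            )
        except ValueError:
            warnings.warn("single-class test fold: AUC excluded", stacklevel=3)
            metrics["auc"] = np.nan
        results[t] = metrics
    return results


def cv_assess(
    g: EnsembleGraph,
    m_mirna: ExpressionMatrix,
    m_gene: ExpressionMatrix,
    y: PhenotypeVector,
    T: int,
    seed: int = 0,
    repeats: int = 5,
    folds: int = 5,
) -> ModelAssessment:
    """Repeated stratified cross-validation of classifiers for t = 1..T.

    For each of ``repeats`` x ``folds`` stratified splits, models for every
    threshold are fit on the training fold and all four criteria are
    measured on the held-out fold; the assessment records mean +- sd over
    folds.  Deterministic given ``seed``.
    """
    if T < 1 or T > len(g.ordered_edges):
        raise ValueError(f"T={T} out of range [1, {len(g.ordered_edges)}]")
    classes = y.classes
    min_class = min(y.class_counts.values())
    folds_eff = min(folds, min_class)
    if folds_eff < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds to {folds_eff}",
            stacklevel=2,
        )
    if folds_eff < 2:
        raise ValueError("cannot stratify fewer than 2 folds")
    t_values = list(range(1, T + 1))
    per_metric: dict[str, list[list[float]]] = {
        m: [[] for _ in t_values] for m in ("auc", "accuracy", "bic", "loglik")
    }
    labels = y.label_array(m_mirna.sample_ids)
    sample_ids = np.asarray(m_mirna.sample_ids, dtype=object)
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds_eff, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        for train_idx, test_idx in skf.split(sample_ids, labels):
            tr_ids = [str(s) for s in sample_ids[train_idx]]
            te_ids = [str(s) for s in sample_ids[test_idx]]
            res = _sweep_metrics(
                g, t_values,
                m_mirna.copy_with(m_mirna.data[tr_ids]),
                m_gene.copy_with(m_gene.data[tr_ids]),
                y.subset(tr_ids),
                m_mirna.copy_with(m_mirna.data[te_ids]),
                m_gene.copy_with(m_gene.data[te_ids]),
                y.subset(te_ids),
                classes,
            )
            for ti, t in enumerate(t_values):
                for metric, value in res[t].items():
                    per_metric[metric][ti].append(value)
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for metric, rows in per_metric.items():
        arr = [np.asarray(r, dtype=float) for r in rows]
        mean[metric] = np.array([np.nanmean(a) for a in arr])
        sd[metric] = np.array([np.nanstd(a, ddof=1) for a in arr])
    assessment = ModelAssessment(t_values=t_values, mean=mean, sd=sd)
    return select_optimal(assessment)


def select_optimal(a: ModelAssessment) -> ModelAssessment:
    """Pick t maximizing mean AUC (ties to smaller t) and flag concordance.

    The concordance indicator records whether accuracy, BIC and held-out
    log-likelihood peak at the same complexity as AUC.
    """
    a.t_optimal = a.criterion_argmax("auc")
    others = [a.criterion_argmax(m) for m in ("accuracy", "bic", "loglik")]
    a.concordant = all(t == a.t_optimal for t in others)
    logger.info("optimal complexity t=%d (concordant=%s)", a.t_optimal, a.concordant)
    return a
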