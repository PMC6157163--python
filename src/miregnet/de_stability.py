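"""Bootstrap stability of differential-expression rankings and the CDF gene filter.

A single ranking of features by a two-class test statistic is fragile at
microarray sample sizes.  The pipeline therefore (i) repeats the ranking
over class-balanced bootstrap resamples, (ii) scores each method's
stability as the weighted Spearman similarity between bootstrap rankings,
and (iii) keeps the genes whose bootstrap count of significant p-values
exceeds a high quantile of the count distribution.

Five ranking methods are available: Student t, Wilcoxon rank-sum
(normal approximation with tie correction), an exhaustive/random label
permutation test on the mean difference, SAM (moderated d-statistic with
a fudge factor and permutation p-values), and an empirical-Bayes
moderated t standing in for a full linear-model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, PhenotypeVector

METHODS = ("t_test", "wilcoxon", "permutation", "sam", "moderated_t")

_EXHAUSTIVE_LIMIT = 20_000  # enumerate label splits below this count


@dataclass
class RankingRun:
    """B bootstrap rankings plus per-bootstrap p-values for one method."""

    method: str
    rankings: list[list[str]]
    p_values: list[dict[str, float]]

    @property
    def B(self) -> int:
        return len(self.rankings)

    @property
    def feature_ids(self) -> list[str]:
        return sorted(self.rankings[0])


@dataclass
class CdfFilterResult:
    counts: dict[str, int]
    cutoff: float
    selected: set[str]


def _two_groups(m: ExpressionMatrix, y: PhenotypeVector) -> tuple[np.ndarray, np.ndarray]:
    classes = y.classes
    if len(classes) != 2:
        raise ValueError(f"differential ranking needs a binary phenotype, got {classes}")
    labels = y.label_array(m.sample_ids)
    x = m.values
    g0 = x[:, labels == classes[0]]
    g1 = x[:, labels == classes[1]]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError("each class needs at least two samples")
    return g0, g1


def _pooled_se(g0: np.ndarray, g1: np.ndarray) -> np.ndarray:
    n0, n1 = g0.shape[1], g1.shape[1]
    v0 = g0.var(axis=1, ddof=1)
    v1 = g1.var(axis=1, ddof=1)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    return np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))


def _t_test(g0, g1, rng):
    se = _pooled_se(g0, g1)
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    df = g0.shape[1] + g1.shape[1] - 2
    stat = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance feature(s) under t-test; p set to 1",
            stacklevel=3,
        )
    stat[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df)
    return stat, p


def _wilcoxon(g0, g1, rng):
    n0, n1 = g0.shape[1], g1.shape[1]
    both = np.concatenate([g0, g1], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r1 = ranks[:, n0:].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n0 * n1 / 2.0
    # tie-corrected variance of U
    n = n0 + n1
    tie_term = np.zeros(both.shape[0])
    for i in range(both.shape[0]):
        _, cnt = np.unique(both[i], return_counts=True)
        tie_term[i] = np.sum(cnt**3 - cnt)
    sigma2 = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    stat = np.zeros_like(u)
    p = np.ones_like(u)
    ok = sigma2 > 0
    stat[ok] = (u[ok] - mu) / np.sqrt(sigma2[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(stat[ok]))
    return stat, p


def _label_splits(n: int, n1: int, rng, n_permutations: int):
    """Yield boolean masks assigning samples to group 1, plus the divisor."""
    from math import comb

    total = comb(n, n1)
    if total <= _EXHAUSTIVE_LIMIT:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks, total, True
    masks = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        masks[i, rng.choice(n, size=n1, replace=False)] = True
    return masks, n_permutations, False


def _perm_pvalues(both: np.ndarray, n1: int, statistic, observed: np.ndarray,
                  rng, n_permutations: int) -> np.ndarray:
    masks, total, exhaustive = _label_splits(both.shape[1], n1, rng, n_permutations)
    count = np.zeros(both.shape[0])
    for mask in masks:
        s = statistic(both[:, ~mask], both[:, mask])
        count += np.abs(s) >= np.abs(observed) - 1e-12
    if exhaustive:
        return count / total
    return (1.0 + count) / (1.0 + total)


def _permutation(g0, g1, rng, n_permutations=200):
    diff = lambda a, b: b.mean(axis=1) - a.mean(axis=1)
    observed = diff(g0, g1)
    both = np.concatenate([g0, g1], axis=1)
    p = _perm_pvalues(both, g1.shape[1], diff, observed, rng, n_permutations)
    return observed, p


def _sam(g0, g1, rng, n_permutations=200):
    """Two-class unpaired SAM d-statistic with fudge factor s0.

    s0 is the median of the gene-wise pooled standard errors; significance
    comes from label permutations of |d| with s0 held fixed.
    """
    se = _pooled_se(g0, g1)
    s0 = float(np.median(se))

    def d_stat(a, b):
        return (b.mean(axis=1) - a.mean(axis=1)) / (_pooled_se(a, b) + s0)

    observed = d_stat(g0, g1)
    both = np.concatenate([g0, g1], axis=1)
    p = _perm_pvalues(both, g1.shape[1], d_stat, observed, rng, n_permutations)
    return observed, p


def _moderated_t(g0, g1, rng, prior_df: float = 4.0):
    """Empirical-Bayes moderated t: gene variances shrunk toward their mean."""
    n0, n1 = g0.shape[1], g1.shape[1]
    df = n0 + n1 - 2
    v0 = g0.var(axis=1, ddof=1)
    v1 = g1.var(axis=1, ddof=1)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df
    prior_var = float(np.mean(sp2))
    post = (prior_df * prior_var + df * sp2) / (prior_df + df)
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    se = np.sqrt(post * (1.0 / n0 + 1.0 / n1))
    stat = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se > 0
    stat[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df + prior_df)
    return stat, p


_DISPATCH = {
    "t_test": _t_test,
    "wilcoxon": _wilcoxon,
    "permutation": _permutation,
    "sam": _sam,
    "moderated_t": _moderated_t,
}


def rank_statistic(
    m: ExpressionMatrix,
    y: PhenotypeVector,
    method: str = "sam",
    seed: int = 0,
    n_permutations: int = 200,
) -> tuple[list[str], dict[str, float]]:
    """Rank features by ascending p-value under a two-class test.

    Ties are broken by descending absolute statistic, then by feature id,
    so the ranking is a deterministic complete permutation of the feature
    set.  Returns ``(ranking, p_values)``.
    """
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    g0, g1 = _two_groups(m, y)
    rng = np.random.default_rng(seed)
    if method in ("permutation", "sam"):
        stat, p = _DISPATCH[method](g0, g1, rng, n_permutations=n_permutations)
    else:
        stat, p = _DISPATCH[method](g0, g1, rng)
    ids = np.asarray(m.feature_ids, dtype=object)
    order = np.lexsort((ids, -np.abs(stat), p))
    ranking = [str(f) for f in ids[order]]
    return ranking, {str(f): float(pv) for f, pv in zip(ids, p)}


def bootstrap_rankings(
    m: ExpressionMatrix,
    y: PhenotypeVector,
    method: str = "sam",
    B: int = 100,
    seed: int = 0,
    n_permutations: int = 200,
) -> RankingRun:
    """Rank features on B class-balanced bootstrap resamples.

    Each replicate samples with replacement within each class, preserving
    the class sizes; a replicate in which some class collapses to a single
    distinct sample is redrawn (at most 100 retries).  Fully reproducible
    from ``seed``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    labels = y.label_array(m.sample_ids)
    classes = y.classes
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    root = np.random.SeedSequence(seed)
    rankings: list[list[str]] = []
    pvals: list[dict[str, float]] = []
    for child in root.spawn(B):
        rng = np.random.default_rng(child)
        for _ in range(100):
            cols = np.concatenate(
                [rng.choice(class_idx[c], size=class_idx[c].size, replace=True)
                 for c in classes]
            )
            if all(np.unique(cols[np.isin(cols, class_idx[c])]).size > 1
                   for c in classes):
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        mb = m.copy_with(
            m.data.iloc[:, cols].set_axis(
                [f"bs{i}" for i in range(cols.size)], axis=1
            )
        )
        yb = PhenotypeVector(
            sample_ids=[f"bs{i}" for i in range(cols.size)],
            labels={f"bs{i}": str(labels[c]) for i, c in enumerate(cols)},
        )
        method_seed = int(rng.integers(0, 2**31 - 1))
        r, p = rank_statistic(mb, yb, method=method, seed=method_seed,
                              n_permutations=n_permutations)
        rankings.append(r)
        pvals.append(p)
    return RankingRun(method=method, rankings=rankings, p_values=pvals)


def weighted_spearman(rank_a: list[str], rank_b: list[str]) -> float:
    """Top-weighted Spearman similarity between two complete rankings.

    Each feature gets a linear top-emphasis weight proportional to
    ``p - i + 1`` at rank position ``i`` (averaged over the two rankings);
    the score is the weighted Pearson correlation of the two rank-position
    vectors.  Identical rankings score 1; an exact reversal scores -1.
    """
    if sorted(rank_a) != sorted(rank_b):
        raise ValueError("rankings must permute the same feature set")
    p = len(rank_a)
    pos_a = {f: i + 1 for i, f in enumerate(rank_a)}
    features = sorted(rank_a)
    ra = np.array([pos_a[f] for f in features], dtype=float)
    pos_b = {f: i + 1 for i, f in enumerate(rank_b)}
    rb = np.array([pos_b[f] for f in features], dtype=float)
    w = ((p - ra + 1) + (p - rb + 1)) / 2.0
    w = w / w.sum()
    ma, mb = np.sum(w * ra), np.sum(w * rb)
    cov = np.sum(w * (ra - ma) * (rb - mb))
    va = np.sum(w * (ra - ma) ** 2)
    vb = np.sum(w * (rb - mb) ** 2)
    if va == 0 or vb == 0:
        return 1.0 if np.array_equal(ra, rb) else 0.0
    return float(cov / np.sqrt(va * vb))


def stability_score(
    run: RankingRun,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Six-number summary of pairwise weighted-Spearman similarities.

    All B(B-1)/2 ranking pairs are scored when feasible; otherwise
    ``n_pairs`` distinct pairs are sampled uniformly without replacement.
    """
    B = run.B
    total = B * (B - 1) // 2
    rng = np.random.default_rng(seed)
    if total <= n_pairs:
        pairs = list(combinations(range(B), 2))
    else:
        flat = rng.choice(total, size=n_pairs, replace=False)
        pairs = []
        for k in flat:
            # invert the triangular index
            i = int((2 * B - 1 - np.sqrt((2 * B - 1) ** 2 - 8 * k)) // 2)
            j = int(k - i * (2 * B - i - 1) // 2 + i + 1)
            pairs.append((i, j))
    scores = np.array(
        [weighted_spearman(run.rankings[i], run.rankings[j]) for i, j in pairs]
    )
    q1, med, q3 = np.percentile(scores, [25, 50, 75])
    return {
        "min": float(scores.min()),
        "q1": float(q1),
        "median": float(med),
        "mean": float(scores.mean()),
        "q3": float(q3),
        "max": float(scores.max()),
    }


def select_genes_cdf(
    run: RankingRun,
    alpha: float = 0.05,
    quantile: float = 0.95,
    mode: str = "unique",
) -> CdfFilterResult:
    """Keep features whose bootstrap significance count clears a quantile cutoff.

    For every feature, count the bootstrap runs with p <= ``alpha``.  The
    cutoff is the ``quantile`` empirical quantile (linear interpolation)
    of the count distribution -- over its unique values when
    ``mode='unique'`` (the default) or over the full per-feature count
    vector when ``mode='all'`` -- and the selection keeps counts strictly
    above the cutoff.
    """
    if not 0 < alpha < 1 or not 0 < quantile < 1:
        raise ValueError("alpha and quantile must lie in (0, 1)")
    if mode not in ("unique", "all"):
        raise ValueError(f"mode must be 'unique' or 'all', got {mode!r}")
    features = run.feature_ids
    counts = {f: 0 for f in features}
    for p in run.p_values:
        for f in features:
            if p[f] <= alpha:
                counts[f] += 1
    vec = np.array([counts[f] for f in features], dtype=float)
    pool = np.unique(vec) if mode == "unique" else vec
    cutoff = float(np.quantile(pool, quantile))
    if not vec.any():
        warnings.warn("all bootstrap significance counts are zero; empty selection",
                      stacklevel=2)
        return CdfFilterResult(counts=counts, cutoff=cutoff, selected=set())
    selected = {f for f in features if counts[f] > cutoff}
    return CdfFilterResult(counts=counts, cutoff=cutoff, selected=selected)
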