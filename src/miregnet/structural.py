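"""Ensemble structural score for miRNA-gene target predictions.

Target-prediction engines disagree substantially, so a single engine's
edge list is unreliable and a plain union over-weights prolific engines.
The ensemble score treats each engine's edge set as a feature subset of a
common universe (the union of all predicted edges) and compares engines
pairwise with a cardinality-corrected consistency index

    CI(A, B) = (r*n - k_M^2) / (k_M * (n - k_M)),

where r = |A ∩ B|, k_M = max(|A|, |B|) and n is the universe size.  CI
ranges from -k_M to 1; 1 is a perfect match.  Positive consistencies,
normalized to sum to one, become pairwise weights w_{i-j}, and an edge's
structural score b is the sum of w_{i-j} over the engine pairs that both
predict it.  Edges predicted by a single engine are discarded as
spurious; an edge predicted by every engine scores b = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import PredictionGraph

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass(frozen=True)
class ConsistencyPair:
    i: int
    j: int
    r: int
    k_M: int
    n: int
    ci: float


@dataclass
class PredictionGraphSet:
    """K engine graphs plus their pairwise consistency weights."""

    graphs: list[PredictionGraph]
    universe: frozenset[Edge]
    pairs: list[ConsistencyPair]
    weights: dict[tuple[int, int], float]


def consistency_index(a: frozenset[Edge] | set[Edge], b: frozenset[Edge] | set[Edge],
                      n: int) -> float:
    """Cardinality-corrected similarity of two edge subsets of an n-edge universe.

    Both sets must be nonempty proper subsets of the universe; a set
    covering the whole universe makes the index undefined (zero division)
    and raises.
    """
    if not a or not b:
        raise ValueError("consistency index requires nonempty edge sets")
    k_m = max(len(a), len(b))
    if k_m >= n:
        raise ValueError(
            f"consistency index undefined: max cardinality {k_m} must be "
            f"smaller than the universe size {n}"
        )
    r = len(set(a) & set(b))
    return (r * n - k_m**2) / (k_m * (n - k_m))


def pairwise_weights(
    graphs: list[PredictionGraph],
    universe_size: int | None = None,
) -> PredictionGraphSet:
    """Compute all pairwise consistency indices and normalize them to weights.

    ``universe_size`` is the number of possible interactions n in the
    consistency index.  By default it is the size of the union of edges
    across all graphs -- the minimal well-defined universe.  Note that
    with exactly two engines the union universe makes CI algebraically
    non-positive (r*n <= k_M^2 whenever n = |A ∪ B|), so two-engine
    ensembles should pass the size of the full candidate grid instead.
    Negative consistencies contribute zero to the normalization (logged
    when triggered); if no pair is positively consistent the ensemble is
    meaningless and an error is raised.  Weights sum to one.
    """
    K = len(graphs)
    if K < 2:
        raise ValueError("need at least two prediction graphs")
    universe: frozenset[Edge] = frozenset().union(*(g.edges for g in graphs))
    n = len(universe) if universe_size is None else int(universe_size)
    if n < len(universe):
        raise ValueError(
            f"universe_size {n} smaller than the union of edges {len(universe)}"
        )
    pairs: list[ConsistencyPair] = []
    clipped: dict[tuple[int, int], float] = {}
    for i in range(K):
        for j in range(i + 1, K):
            if not graphs[i].edges or not graphs[j].edges:
                ci = 0.0  # an empty engine is consistent with nothing
            else:
                ci = consistency_index(graphs[i].edges, graphs[j].edges, n)
            r = len(graphs[i].edges & graphs[j].edges)
            k_m = max(len(graphs[i].edges), len(graphs[j].edges))
            pairs.append(ConsistencyPair(i=i, j=j, r=r, k_M=k_m, n=n, ci=ci))
            if ci < 0:
                logger.info(
                    "negative consistency %.4f between %s and %s floored at 0",
                    ci, graphs[i].engine_name, graphs[j].engine_name,
                )
            clipped[(i, j)] = max(ci, 0.0)
    total = sum(clipped.values())
    if total <= 0:
        raise ValueError("no consistent pair of engines (all consistencies <= 0)")
    weights = {k: v / total for k, v in clipped.items()}
    return PredictionGraphSet(graphs=list(graphs), universe=universe,
                              pairs=pairs, weights=weights)


def ensemble_structural_scores(gs: PredictionGraphSet) -> dict[Edge, float]:
    """Structural score b for every edge predicted by at least two engines.

    b_e sums the pairwise weights of all engine pairs that both predict e.
    Single-engine edges are absent from the output; edges whose only
    supporting pairs were floored to zero weight are likewise dropped,
    preserving the b > 0 contract.  Iteration is lexicographic so logs
    and outputs are byte-stable.
    """
    membership = {
        e: frozenset(i for i, g in enumerate(gs.graphs) if e in g.edges)
        for e in gs.universe
    }
    scores: dict[Edge, float] = {}
    n_single = 0
    for e in sorted(gs.universe):
        engines = membership[e]
        if len(engines) < 2:
            n_single += 1
            continue
        b = sum(
            w for (i, j), w in gs.weights.items() if i in engines and j in engines
        )
        if b > 0:
            scores[e] = b
        else:
            logger.info("edge %s supported only by zero-weight pairs; dropped", e)
    logger.info(
        "structural scoring: %d union edges, %d single-engine discarded, %d scored",
        len(gs.universe), n_single, len(scores),
    )
    return scores
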