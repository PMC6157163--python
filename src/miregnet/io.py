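"""Domain types and readers/writers for the ensemble-graph pipeline.

The pipeline moves five kinds of objects around: class-labelled expression
matrices (miRNA or gene role), a phenotype vector, per-engine target
prediction graphs, scored candidate edges carrying a structural score ``b``
and a functional score ``d``, and the Pareto-ordered ensemble graph from
which classifiers of increasing complexity are instantiated.

TSV is the canonical interchange format.  Expression matrices are
features x samples with a header row of sample ids and the feature id in
the first column; missing values may be encoded as empty cells or ``NA``.
An optional loader for R-Data supplements is provided behind a soft
dependency on :mod:`pyreadr`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


class FeatureRole(str, Enum):
    MIRNA = "miRNA"
    GENE = "gene"


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2-scale expression values.

    Missing entries are represented as NaN and are only permitted before
    imputation.  Feature and sample identifiers must be unique.
    """

    data: pd.DataFrame
    role: FeatureRole

    def __post_init__(self) -> None:
        self.role = FeatureRole(self.role)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy_with(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, role=self.role)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        if self.role is not other.role:
            return False
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, atol=atol, rtol=0.0, equal_nan=False)
        return bool(np.all(both_nan | close))


@dataclass
class PhenotypeVector:
    """Per-sample class labels from a finite class set (|classes| >= 2)."""

    sample_ids: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample id in phenotype vector")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ParseError(f"sample {missing[0]!r} has no phenotype label")
        counts = self.class_counts
        if len(counts) < 2:
            raise ParseError("phenotype vector must contain at least two classes")
        small = [c for c, n in counts.items() if n < 2]
        if small:
            raise ParseError(f"class {small[0]!r} has fewer than two samples")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels[s] for s in self.sample_ids))

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        return counts

    def label_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return np.asarray([self.labels[s] for s in ids], dtype=object)

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeVector":
        return PhenotypeVector(
            sample_ids=list(sample_ids),
            labels={s: self.labels[s] for s in sample_ids},
        )


@dataclass(frozen=True)
class PredictionGraph:
    """Edge set reported by one target-prediction engine.

    Edges are (miRNA id, gene id) pairs with set semantics; the graph is
    bipartite by construction.
    """

    engine_name: str
    edges: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True, order=True)
class ScoredEdge:
    """A candidate miRNA->gene edge with structural score b and functional score d.

    ``b`` lies in (0, 1]; edges predicted by fewer than two engines never
    reach this type.  ``d`` is a conditional mutual information in nats and
    may be tiny-negative from quadrature.
    """

    mirna_id: str
    gene_id: str
    b: float
    d: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"structural score must be positive, got {self.b}")
        if self.d < -1e-6:
            raise ValueError(f"functional score below numerical floor: {self.d}")


@dataclass
class EnsembleGraph:
    """Pareto-ordered candidate edges plus a complexity threshold t."""

    ordered_edges: list[ScoredEdge]
    t: int = 1
    front_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.t <= max(len(self.ordered_edges), 1):
            raise ValueError(f"t={self.t} out of range for {len(self.ordered_edges)} edges")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, role: FeatureRole | str) -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    The header row holds sample ids; the first column holds feature ids.
    Empty cells and ``NA`` (case-insensitive) mark missing values; any
    other non-numeric cell is a parse error naming the row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.name is None and len(raw.columns) == 0:
        raise ParseError(f"{path}: malformed header (no sample columns)")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw.iloc[:, j]):
            token = cell.strip()
            if token.lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
    frame = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    return ExpressionMatrix(data=frame, role=FeatureRole(role))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature")


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read a two-column TSV (sample id, class label); a header is optional."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: phenotype file needs two columns")
    first = frame.iloc[0]
    if str(first.iloc[0]).lower() in {"sample", "sample_id", "id"}:
        frame = frame.iloc[1:]
    ids = [str(v) for v in frame.iloc[:, 0]]
    labels = {str(s): str(l) for s, l in zip(frame.iloc[:, 0], frame.iloc[:, 1])}
    return PhenotypeVector(sample_ids=ids, labels=labels)


def write_phenotype(y: PhenotypeVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tclass\n")
        for s in y.sample_ids:
            fh.write(f"{s}\t{y.labels[s]}\n")


# ---------------------------------------------------------------------------
# Prediction graphs
# ---------------------------------------------------------------------------

def read_edge_lists(
    paths: Iterable[str | Path],
    strip_species_prefix: bool = False,
) -> list[PredictionGraph]:
    """Read one edge-list TSV per prediction engine.

    Each file needs at least two columns (miRNA id, gene id); extra
    columns are ignored and duplicate pairs collapse to one edge.  The
    engine name is the file stem.  ``strip_species_prefix`` removes a
    leading ``hsa-`` from miRNA identifiers (off by default).
    """
    graphs: list[PredictionGraph] = []
    for path in paths:
        path = Path(path)
        name = path.stem
        edges: set[tuple[str, str]] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected >=2 columns")
                mirna, gene = parts[0].strip(), parts[1].strip()
                if lineno == 1 and mirna.lower() in {"mirna", "mirna_id", "microrna"}:
                    continue
                if strip_species_prefix and mirna.startswith("hsa-"):
                    mirna = mirna[len("hsa-"):]
                edges.add((mirna, gene))
        if not edges:
            warnings.warn(f"{path}: empty edge list for engine {name!r}", stacklevel=2)
        graphs.append(PredictionGraph(engine_name=name, edges=frozenset(edges)))
    return graphs


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna, gene in sorted(edges):
            fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# Scored-edge exports
# ---------------------------------------------------------------------------

def export_graph(edges: Sequence[ScoredEdge], path: str | Path, fmt: str = "tsv") -> None:
    """Serialize scored edges as GraphML, SIF or TSV.

    GraphML carries ``b`` and ``d`` as edge attributes and the node type
    (miRNA/gene) as a node attribute; SIF uses the relation ``regulates``;
    TSV has the columns mirna, gene, b, d.
    """
    if not edges:
        raise ValueError("cannot export an empty edge list")
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        g = nx.DiGraph()
        for e in edges:
            g.add_node(e.mirna_id, type="miRNA")
            g.add_node(e.gene_id, type="gene")
            g.add_edge(e.mirna_id, e.gene_id, b=float(e.b), d=float(e.d))
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.mirna_id} regulates {e.gene_id}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("mirna\tgene\tb\td\n")
            for e in edges:
                fh.write(f"{e.mirna_id}\t{e.gene_id}\t{e.b!r}\t{e.d!r}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected graphml/sif/tsv)")


def read_scored_edges(path: str | Path) -> list[ScoredEdge]:
    """Read back a TSV produced by :func:`export_graph` (format ``tsv``)."""
    frame = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str},
                        float_precision="round_trip")
    required = {"mirna", "gene", "b", "d"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return [
        ScoredEdge(str(r.mirna), str(r.gene), float(r.b), float(r.d))
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Optional R-Data supplement loader
# ---------------------------------------------------------------------------

def load_rdata_expression(path: str | Path, role: FeatureRole | str) -> ExpressionMatrix:
    """Load an expression matrix from an R-Data supplement file.

    Requires the optional :mod:`pyreadr` dependency; the pipeline itself
    never needs it.  The loader reports the dimensions found so callers
    can adapt to whichever matrix the supplement ships.
    """
    try:
        import pyreadr  # type: ignore
    except ImportError as exc:  # pragma: no cover - soft dependency
        raise ImportError(
            "reading R-Data supplements requires the optional 'pyreadr' package; "
            "install miregnet[rdata] or convert the file to TSV"
        ) from exc
    result = pyreadr.read_r(str(path))  # pragma: no cover - soft dependency
    name, frame = next(iter(result.items()))  # pragma: no cover
    logger.info("R-Data object %r: %d features x %d samples", name, *frame.shape)  # pragma: no cover
    return ExpressionMatrix(data=frame, role=FeatureRole(role))  # pragma: no cover
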