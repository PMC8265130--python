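"""Construction of kinase-substrate set libraries.

Two routes into a :class:`~kinrank.io.GeneSetLibrary`:

* from a typed interaction edge list (kinase-substrate or protein-protein
  interactions), keeping only kinases with at least ``min_substrates``
  distinct partners — undirected PPI partners are treated as putative
  substrates of the kinase endpoint(s);
* from a gene x sample expression matrix, where each kinase's set is the
  ``top_n`` genes most positively Pearson-correlated with it after quantile
  normalization and duplicate-gene variance filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetLibrary, _clean_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionEdge:
    """One typed interaction. ``directed=True`` means ``source`` is the acting kinase."""

    source: str
    target: str
    directed: bool
    evidence: str = "PPI"

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty symbols")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix.

    Row labels may repeat on input (multiple probes / transcript variants
    per gene symbol) and are collapsed by
    :func:`dedupe_genes_by_variance` before correlation analysis.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def read_edges(path: str | Path) -> list[InteractionEdge]:
    """Read an edge-list TSV: source, target, directed(0/1), evidence."""
    edges = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields (source, target, directed, evidence)")
            edges.append(InteractionEdge(
                source=_clean_symbol(fields[0]),
                target=_clean_symbol(fields[1]),
                directed=fields[2].strip() == "1",
                evidence=fields[3].strip(),
            ))
    return edges


def write_edges(edges: Iterable[InteractionEdge], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{int(e.directed)}\t{e.evidence}\n")
    return path


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV: first column gene symbols, header row of samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=[_clean_symbol(g) for g in df.index],
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def build_from_edges(
    edges: Sequence[InteractionEdge],
    kinase_universe: set[str],
    min_substrates: int = 5,
    source_type: str = "mixed",
    name: str = "edges",
    evidence_filter: Callable[[str], bool] | None = None,
) -> GeneSetLibrary:
    """Build a substrate-set library from an interaction edge list.

    A directed edge contributes its target to the source kinase's set only.
    An undirected edge contributes each endpoint to the other's set when
    that endpoint is in ``kinase_universe`` (so two interacting kinases get
    each other). Self-edges are ignored, and kinases with fewer than
    ``min_substrates`` distinct partners are dropped — mirroring the
    requirement that a library kinase have at least five distinct putative
    substrates.

    ``evidence_filter``, when given, is a predicate on the edge evidence
    label applied before any counting (e.g. keep only "binding" links).
    """
    if min_substrates < 1:
        raise ValueError("min_substrates must be >= 1")
    adjacency: dict[str, dict[str, None]] = {}

    def add(kinase: str, partner: str) -> None:
        adjacency.setdefault(kinase, {}).setdefault(partner, None)

    for edge in edges:
        if evidence_filter is not None and not evidence_filter(edge.evidence):
            continue
        if edge.source == edge.target:
            continue
        if edge.directed:
            if edge.source in kinase_universe:
                add(edge.source, edge.target)
        else:
            if edge.source in kinase_universe:
                add(edge.source, edge.target)
            if edge.target in kinase_universe:
                add(edge.target, edge.source)
    sets = {
        kinase: list(partners)
        for kinase, partners in adjacency.items()
        if len(partners) >= min_substrates
    }
    return GeneSetLibrary(name=name, source_type=source_type, sets=sets)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the identical value distribution.

    The target distribution is the per-rank mean across columns of the
    column-sorted values; within-column rank order is preserved, and rank
    ties within a column receive the mean of their tied positions' target
    values. Idempotent.
    """
    X = matrix.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties within a column all map to the mean of their target slots
        tied = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return ExpressionMatrix(genes=list(matrix.genes), samples=list(matrix.samples), values=out)


def dedupe_genes_by_variance(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse repeated gene labels, keeping the row with maximal variance.

    Exact variance ties among duplicates keep the first occurrence. Rows
    with unique labels pass through untouched; surviving rows keep their
    original relative order.
    """
    genes = np.asarray(matrix.genes)
    variances = matrix.values.var(axis=1, ddof=0)
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        j = best.get(g)
        if j is None or variances[i] > variances[j]:
            best[g] = i
    keep = sorted(best.values())
    return ExpressionMatrix(
        genes=[matrix.genes[i] for i in keep],
        samples=list(matrix.samples),
        values=matrix.values[keep, :],
    )


def build_coexpression(
    matrix: ExpressionMatrix,
    kinases: set[str],
    top_n: int = 300,
    name: str = "coexpression",
) -> GeneSetLibrary:
    """Build co-expression sets: top ``top_n`` positively correlated genes per kinase.

    ``matrix`` is expected to be quantile-normalized and deduplicated.
    For each kinase present among the rows, the other genes are ranked by
    Pearson correlation with the kinase's expression profile (largest
    positive r first; correlation ties broken by row order) and the top
    ``top_n`` form its set. The kinase itself is always excluded.
    Zero-variance rows cannot be correlated and are skipped — a
    zero-variance kinase is omitted with a logged warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(set(matrix.genes)) != len(matrix.genes):
        raise ValueError("matrix has duplicate gene labels; run dedupe_genes_by_variance first")
    X = matrix.values
    sd = X.std(axis=1, ddof=0)
    nonconstant = sd > 0
    centered = X - X.mean(axis=1, keepdims=True)
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    sets: dict[str, list[str]] = {}
    for kinase in sorted(kinases):
        i = gene_index.get(kinase)
        if i is None:
            continue
        if not nonconstant[i]:
            logger.warning("kinase %s has zero expression variance; omitted", kinase)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = centered @ centered[i] / (sd * sd[i] * X.shape[1])
        candidate = np.flatnonzero(nonconstant)
        candidate = candidate[candidate != i]
        order = candidate[np.argsort(-r[candidate], kind="mergesort")]
        sets[kinase] = [matrix.genes[j] for j in order[:top_n]]
    return GeneSetLibrary(name=name, source_type="coexpression", sets=sets)
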