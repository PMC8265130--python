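"""Per-library Fisher's-exact over-representation ranking of kinases.

For a query protein set and a library of k kinase-substrate sets, each
kinase is scored by the one-sided (over-representation) Fisher's exact
test on the 2x2 table of query/set membership against a fixed background
universe of 20,000 genes. Kinases are ranked 1..k by ascending p-value
with exact ties broken by a seeded RNG, scaled ranks are integer rank / k,
and Benjamini-Hochberg FDRs are attached per library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary, QuerySet

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND = 20_000


@dataclass
class EnrichmentRow:
    """One kinase's enrichment result within a single library."""

    kinase: str
    overlap_count: int
    overlap_members: list[str]
    p_value: float
    fdr: float
    integer_rank: int
    scaled_rank: float


@dataclass
class EnrichmentTable:
    """Complete ranking of one library's kinases for one query.

    ``rows`` are sorted by ``integer_rank``; the integer ranks are exactly
    the permutation 1..k. ``seed`` records the RNG seed used to permute
    exact p-value ties, making the table bit-reproducible.
    """

    library_name: str
    k: int
    rows: list[EnrichmentRow]
    seed: int

    def scaled_ranks(self) -> dict[str, float]:
        return {row.kinase: row.scaled_rank for row in self.rows}

    def integer_ranks(self) -> dict[str, int]:
        return {row.kinase: row.integer_rank for row in self.rows}


def fisher_overlap(
    query: QuerySet | Sequence[str],
    kinase_set: Sequence[str],
    background_size: int = DEFAULT_BACKGROUND,
) -> tuple[int, list[str], float]:
    """One-sided Fisher's exact test of query/set over-representation.

    With a = |query ∩ set|, the p-value is the hypergeometric upper tail
    P(X >= a) for drawing |query| genes from a universe of
    ``background_size`` containing |set| marked genes.

    Returns ``(overlap_count, overlap_members, p_value)``; overlap members
    preserve the kinase set's order.
    """
    symbols = query.symbols if isinstance(query, QuerySet) else list(query)
    query_set = set(symbols)
    members = [m for m in kinase_set if m in query_set]
    a = len(members)
    n_query = len(query_set)
    n_set = len(set(kinase_set))
    n_union = len(query_set | set(kinase_set))
    if background_size < n_union:
        raise ValueError(
            f"background_size={background_size} smaller than |query ∪ set|={n_union}"
        )
    # P(X >= a), X ~ Hypergeom(M=background, n=|set|, N=|query|)
    p = float(hypergeom.sf(a - 1, background_size, n_set, n_query))
    return a, members, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def rank_table(
    query: QuerySet | Sequence[str],
    library: GeneSetLibrary,
    background_size: int = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> EnrichmentTable:
    """Rank every kinase in a library against a query.

    All k kinases receive a row — zero-overlap kinases score p = 1 and
    land in the random-tie region at the bottom, so scaled ranks always
    cover the full grid {1/k, ..., 1} needed by integration and
    benchmarking. Rows are ordered by ascending p-value; exact p ties are
    permuted by the RNG seeded with ``seed``.
    """
    if library.k == 0:
        raise ValueError(f"library {library.name!r} is empty")
    symbols = query.symbols if isinstance(query, QuerySet) else list(query)
    if not symbols:
        logger.warning("empty query: all p-values are 1, ranking is a seeded permutation")
    kinases = library.kinases()
    results = [fisher_overlap(symbols, library.sets[kin], background_size) for kin in kinases]
    p_values = np.array([r[2] for r in results])
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(len(kinases))
    order = np.lexsort((tiebreak, p_values))
    fdrs = bh_fdr(p_values)
    k = len(kinases)
    rows = []
    for rank_minus_1, idx in enumerate(order):
        a, members, p = results[idx]
        rows.append(EnrichmentRow(
            kinase=kinases[idx],
            overlap_count=a,
            overlap_members=members,
            p_value=p,
            fdr=fdrs[idx],
            integer_rank=rank_minus_1 + 1,
            scaled_rank=(rank_minus_1 + 1) / k,
        ))
    return EnrichmentTable(library_name=library.name, k=k, rows=rows, seed=seed)


def write_enrichment_tsv(table: EnrichmentTable, path: str | Path) -> Path:
    """Write a per-library result table as TSV (one row per kinase, ranked)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("kinase\toverlap_count\toverlap_members\tp_value\tfdr\trank\tscaled_rank\n")
        for row in table.rows:
            fh.write(
                f"{row.kinase}\t{row.overlap_count}\t{';'.join(row.overlap_members)}\t"
                f"{row.p_value:.6g}\t{row.fdr:.6g}\t{row.integer_rank}\t{row.scaled_rank:.6g}\n"
            )
    return path
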