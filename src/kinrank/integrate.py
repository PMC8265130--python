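"""Cross-library rank integration: MeanRank and TopRank.

MeanRank re-ranks the union of kinases by each kinase's mean integer rank
over only the libraries that contain it; TopRank re-ranks by the best
(minimum) scaled rank across libraries. Score ties are broken first by
more contributing libraries, then by a seeded RNG, so results are
reproducible and invariant to the order of the input tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrich import EnrichmentTable


@dataclass
class IntegratedRow:
    """One kinase in a composite ranking.

    ``provenance`` lists the contributing ``(library, integer_rank,
    scaled_rank)`` triples, sorted by library name.
    """

    kinase: str
    score: float
    final_rank: int
    n_libraries: int
    provenance: list[tuple[str, int, float]]


def _gather(tables: Sequence[EnrichmentTable]) -> dict[str, list[tuple[str, int, float]]]:
    if not tables:
        raise ValueError("need at least one enrichment table")
    per_kinase: dict[str, list[tuple[str, int, float]]] = {}
    for table in tables:
        for row in table.rows:
            per_kinase.setdefault(row.kinase, []).append(
                (table.library_name, row.integer_rank, row.scaled_rank)
            )
    for triples in per_kinase.values():
        triples.sort()
    return per_kinase


def _finalize(scores: dict[str, tuple[float, list[tuple[str, int, float]]]],
              seed: int) -> list[IntegratedRow]:
    kinases = sorted(scores)  # canonical order so the seeded tie-break is stable
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(len(kinases))
    keyed = sorted(
        range(len(kinases)),
        key=lambda i: (scores[kinases[i]][0], -len(scores[kinases[i]][1]), tiebreak[i]),
    )
    rows = []
    for final_rank, i in enumerate(keyed, start=1):
        kinase = kinases[i]
        score, provenance = scores[kinase]
        rows.append(IntegratedRow(
            kinase=kinase,
            score=score,
            final_rank=final_rank,
            n_libraries=len(provenance),
            provenance=provenance,
        ))
    return rows


def mean_rank(tables: Sequence[EnrichmentTable], seed: int = 0) -> list[IntegratedRow]:
    """Composite ranking by mean integer rank across libraries containing each kinase."""
    per_kinase = _gather(tables)
    scores = {
        kinase: (float(np.mean([t[1] for t in triples])), triples)
        for kinase, triples in per_kinase.items()
    }
    return _finalize(scores, seed)


def top_rank(tables: Sequence[EnrichmentTable], seed: int = 0) -> list[IntegratedRow]:
    """Composite ranking by best (minimum) scaled rank across libraries."""
    per_kinase = _gather(tables)
    scores = {
        kinase: (min(t[2] for t in triples), triples)
        for kinase, triples in per_kinase.items()
    }
    return _finalize(scores, seed)


def write_integrated_tsv(rows: Sequence[IntegratedRow], path: str | Path) -> Path:
    """Write a composite ranking as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("kinase\tscore\tfinal_rank\tn_libraries\tprovenance\n")
        for row in sorted(rows, key=lambda r: r.final_rank):
            prov = ",".join(f"{lib}:{rank}" for lib, rank, _ in row.provenance)
            fh.write(f"{row.kinase}\t{row.score:.6g}\t{row.final_rank}\t{row.n_libraries}\t{prov}\n")
    return path
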