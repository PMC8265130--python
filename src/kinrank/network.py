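"""Kinase co-regulatory subnetwork extraction.

Among a list of top-ranked kinases, every membership of one kinase in
another's substrate set becomes an edge. Kinase-substrate (KSI) evidence
directs the edge from the acting kinase to its substrate; memberships
supported only by protein-protein interaction or mixed evidence yield a
single undirected edge per pair. When both kinds of evidence exist the
directed edge wins and absorbs the PPI evidence — direction is strictly
more informative. Reciprocal KSI evidence yields two directed edges,
since kinases genuinely phosphorylate each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import GeneSetLibrary


@dataclass
class KinaseEdge:
    """An edge of the co-regulatory subnetwork; ``a -> b`` when directed."""

    a: str
    b: str
    directed: bool
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edges are not allowed")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")
        if self.directed and not any(st == "KSI" for _, st in self.evidence):
            raise ValueError("directed edges require at least one KSI evidence entry")


def extract_subnetwork(top_kinases: Sequence[str],
                       libraries: Sequence[GeneSetLibrary]) -> list[KinaseEdge]:
    """Edges among ``top_kinases`` implied by substrate-set membership.

    For every ordered pair (K1, K2) with K2 in K1's set in some library:
    KSI-sourced membership yields a directed K1 -> K2 edge; PPI/mixed/
    co-expression-only membership contributes to one undirected edge for
    the unordered pair. Evidence records every supporting
    ``(library name, source_type)``.
    """
    if not top_kinases:
        raise ValueError("top_kinases must be non-empty")
    top = [k for k in dict.fromkeys(top_kinases)]
    top_set = set(top)
    # ordered-pair evidence split by whether it can direct an edge
    ksi_ev: dict[tuple[str, str], list[tuple[str, str]]] = {}
    other_ev: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for lib in libraries:
        for k1 in top:
            members = lib.sets.get(k1)
            if not members:
                continue
            for k2 in members:
                if k2 == k1 or k2 not in top_set:
                    continue
                bucket = ksi_ev if lib.source_type == "KSI" else other_ev
                bucket.setdefault((k1, k2), []).append((lib.name, lib.source_type))
    edges: list[KinaseEdge] = []
    for (k1, k2), evidence in sorted(ksi_ev.items()):
        # directed edge absorbs any same-direction PPI evidence
        evidence = evidence + other_ev.pop((k1, k2), [])
        edges.append(KinaseEdge(a=k1, b=k2, directed=True, evidence=sorted(set(evidence))))
    undirected_seen: set[frozenset[str]] = set()
    for (k1, k2) in sorted(other_ev):
        pair = frozenset((k1, k2))
        if pair in undirected_seen:
            continue
        # skip pairs already carrying a directed edge in either direction
        if (k1, k2) in ksi_ev or (k2, k1) in ksi_ev:
            evidence = other_ev[(k1, k2)]
            target = next(e for e in edges
                          if {e.a, e.b} == set(pair) and e.directed)
            target.evidence = sorted(set(target.evidence) | set(evidence))
            continue
        undirected_seen.add(pair)
        evidence = other_ev.get((k1, k2), []) + other_ev.get((k2, k1), [])
        a, b = sorted(pair)
        edges.append(KinaseEdge(a=a, b=b, directed=False,
                                evidence=sorted(set(evidence))))
    return edges


def write_subnetwork_tsv(edges: Sequence[KinaseEdge], path: str | Path) -> Path:
    """Edge TSV: a, b, directed(0/1), evidence as semicolon-joined library:source_type."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("a\tb\tdirected\tevidence\n")
        for e in edges:
            ev = ";".join(f"{lib}:{st}" for lib, st in e.evidence)
            fh.write(f"{e.a}\t{e.b}\t{int(e.directed)}\t{ev}\n")
    return path
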