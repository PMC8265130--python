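"""Seeded synthetic fixtures with planted signal.

Generates gene-set libraries, benchmark cases, interaction edge lists and
correlated expression matrices over an artificial ``G000001...`` symbol
namespace (so fixtures can never collide with real gene symbols or alias
maps). Every generator is bit-reproducible from its seed. These fixtures
emulate the shape of real kinase-substrate benchmarks — a query carries a
tunable fraction of a true kinase's substrates plus background noise —
but not real kinome topology or phosphosite-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import BenchmarkCase
from .build import ExpressionMatrix, InteractionEdge
from .io import GeneSetLibrary, QuerySet


def gene_universe(size: int) -> list[str]:
    """The synthetic symbol namespace: G000001 ... G<size>."""
    return [f"G{i:06d}" for i in range(1, size + 1)]


def kinase_names(n: int) -> list[str]:
    return [f"KIN{i:03d}" for i in range(1, n + 1)]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults mirror the planted-signal recovery setting used throughout
    the test suite: a 2,000-gene universe, 20 kinase sets of ~50
    substrates, 30-gene queries carrying half signal, 200 cases.
    """

    universe_size: int = 2000
    n_kinases: int = 20
    set_size_range: tuple[int, int] = (50, 50)
    query_size: int = 30
    signal_fraction: float = 0.5
    n_cases: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if lo < 5:
            raise ValueError("set sizes must be >= 5 to survive the library filter")
        if lo > hi:
            raise ValueError("set_size_range must be (min, max) with min <= max")
        if hi > self.universe_size:
            raise ValueError("set size exceeds universe size")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if round(self.signal_fraction * self.query_size) > lo:
            raise ValueError("signal portion of the query exceeds the minimum set size")


def make_library(spec: SyntheticSpec, name: str = "synthetic",
                 source_type: str = "KSI") -> GeneSetLibrary:
    """Sample ``n_kinases`` member sets uniformly without replacement."""
    rng = np.random.default_rng(spec.seed)
    universe = np.array(gene_universe(spec.universe_size))
    lo, hi = spec.set_size_range
    sets = {}
    for kinase in kinase_names(spec.n_kinases):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[kinase] = members.tolist()
    return GeneSetLibrary(name=name, source_type=source_type, sets=sets)


def make_benchmark(library: GeneSetLibrary, spec: SyntheticSpec) -> list[BenchmarkCase]:
    """Plant queries: a signal slice of a random true kinase's set plus noise.

    Each case picks its true kinase uniformly; the query holds
    ``round(signal_fraction * query_size)`` members of that kinase's set
    and fills the remainder with genes sampled outside the set (possibly
    inside other sets — real substrate sets overlap, and so should the
    noise).
    """
    if library.k == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(spec.seed + 1)
    universe = gene_universe(spec.universe_size)
    kinases = library.kinases()
    cases = []
    for _ in range(spec.n_cases):
        kinase = kinases[int(rng.integers(len(kinases)))]
        members = library.sets[kinase]
        n_signal = round(spec.signal_fraction * spec.query_size)
        n_signal = min(n_signal, len(members))
        signal = rng.choice(np.array(members), size=n_signal, replace=False).tolist()
        outside = np.array([g for g in universe if g not in set(members)])
        n_noise = spec.query_size - n_signal
        noise = rng.choice(outside, size=n_noise, replace=False).tolist()
        cases.append(BenchmarkCase(
            query=QuerySet(symbols=signal + noise),
            true_kinases={kinase},
        ))
    return cases


def make_edges(library: GeneSetLibrary, directed_fraction: float = 1.0,
               seed: int = 0) -> list[InteractionEdge]:
    """One edge per (kinase, member); a seeded coin picks directed KSI vs undirected PPI."""
    rng = np.random.default_rng(seed)
    edges = []
    for kinase, members in library.sets.items():
        for member in members:
            directed = bool(rng.random() < directed_fraction)
            edges.append(InteractionEdge(
                source=kinase, target=member,
                directed=directed,
                evidence="KSI" if directed else "PPI",
            ))
    return edges


def make_correlated_expression(
    n_genes: int,
    n_samples: int,
    modules: list[tuple[str, list[str]]],
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression with planted co-expression modules.

    Genes of a module (the kinase plus its member genes) share a latent
    standard-normal sample vector plus independent N(0, noise_sd) noise;
    background genes are pure independent noise. Module gene lists must
    be disjoint.
    """
    claimed: set[str] = set()
    for kinase, members in modules:
        block = {kinase, *members}
        if claimed & block:
            raise ValueError("module gene lists must be disjoint")
        claimed |= block
    rng = np.random.default_rng(seed)
    module_genes = [g for kinase, members in modules for g in (kinase, *members)]
    background = [g for g in gene_universe(n_genes) if g not in claimed]
    genes = module_genes + background[: max(0, n_genes - len(module_genes))]
    values = rng.normal(size=(len(genes), n_samples))
    row = 0
    for kinase, members in modules:
        latent = rng.normal(size=n_samples)
        size = 1 + len(members)
        values[row:row + size] = latent + noise_sd * rng.normal(size=(size, n_samples))
        row += size
    samples = [f"S{j:03d}" for j in range(1, n_samples + 1)]
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


def degrade_library(library: GeneSetLibrary, noise_fraction: float,
                    universe_size: int, seed: int = 0,
                    name: str | None = None) -> GeneSetLibrary:
    """Corrupt a library by replacing a fraction of each set's members.

    ``round(noise_fraction * |set|)`` members are dropped from every set
    and replaced with distinct random genes drawn outside the original
    set, emulating a lower-quality evidence source with the same size
    distribution.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = np.array(gene_universe(universe_size))
    sets = {}
    for kinase, members in library.sets.items():
        n_replace = round(noise_fraction * len(members))
        keep_idx = rng.choice(len(members), size=len(members) - n_replace, replace=False)
        kept = [members[i] for i in sorted(keep_idx)]
        outside = universe[~np.isin(universe, members)]
        replacements = rng.choice(outside, size=n_replace, replace=False).tolist()
        sets[kinase] = kept + [g for g in replacements if g not in kept]
    return GeneSetLibrary(
        name=name or f"{library.name}_noisy",
        source_type=library.source_type,
        sets=sets,
    )
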