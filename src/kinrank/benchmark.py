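"""Benchmarking framework for kinase-ranking libraries and integration methods.

A benchmark case pairs a query protein set with the "true" kinase(s) that
generated it. For each ranking source (a single library or an integration
method) the scaled ranks of the true kinases form the positive class and
the scaled ranks of all other ranked kinases the negative class. From
these pooled classes we compute:

* ROC AUC of the classifier score s = 1 - scaled_rank (perfect
  predictor -> AUC 1);
* mean PR AUC over repeated bootstrap downsamplings of the negative
  class to the positive-class size, so a random classifier scores 0.5
  regardless of library size;
* the bridge statistic D(r) - U — deviation of the true-rank ECDF from
  the uniform CDF — with an Anderson-Darling test of uniformity.

Library selection (both metrics in the top 50% for >= 2 of 3 benchmarks)
and pairwise inter-library AUECDF concordance live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.distributions.empirical_distribution import ECDF

from .enrich import DEFAULT_BACKGROUND, rank_table
from .integrate import mean_rank, top_rank
from .io import GeneSetLibrary, QuerySet, _clean_symbol

Ranker = Callable[[QuerySet], Mapping[str, float]]


@dataclass
class BenchmarkCase:
    """One labeled evaluation case: a query set and its true kinase(s)."""

    query: QuerySet
    true_kinases: set[str]

    def __post_init__(self) -> None:
        if not self.true_kinases:
            raise ValueError("true_kinases must be non-empty")


@dataclass
class ClassScores:
    """Pooled scaled ranks: positives are true kinases, negatives everything else."""

    positives: list[float]
    negatives: list[float]
    n_skipped_true: int = 0


@dataclass
class BenchmarkReport:
    """All benchmark metrics for one ranking source."""

    source: str
    roc_auc: float
    mean_pr_auc: float
    pr_curves: list[np.ndarray]
    composite_pr: np.ndarray
    ecdf_dev: np.ndarray
    ad_p_value: float
    n_skipped_true: int


@dataclass
class ConcordanceMatrix:
    """Pairwise AUECDF values keyed by ordered (query_library, prediction_library)."""

    auecdf: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ranking sources

def library_ranker(library: GeneSetLibrary,
                   background_size: int = DEFAULT_BACKGROUND,
                   seed: int = 0) -> Ranker:
    """Wrap a single library as a ranking source returning kinase -> scaled rank."""

    def rank(query: QuerySet) -> dict[str, float]:
        return rank_table(query, library, background_size, seed).scaled_ranks()

    return rank


def integration_ranker(libraries: Sequence[GeneSetLibrary],
                       method: str = "meanrank",
                       background_size: int = DEFAULT_BACKGROUND,
                       seed: int = 0) -> Ranker:
    """Wrap MeanRank/TopRank over several libraries as a ranking source.

    The composite final rank over the K-kinase union is scaled to (0, 1]
    by dividing by K, mirroring the per-library scaled-rank convention.
    """
    combine = {"meanrank": mean_rank, "toprank": top_rank}[method.lower()]

    def rank(query: QuerySet) -> dict[str, float]:
        tables = [rank_table(query, lib, background_size, seed) for lib in libraries]
        rows = combine(tables, seed=seed)
        K = len(rows)
        return {row.kinase: row.final_rank / K for row in rows}

    return rank


# ---------------------------------------------------------------------------
# class collection and threshold-free metrics

def collect_classes(cases: Sequence[BenchmarkCase], ranker: Ranker) -> ClassScores:
    """Pool positive/negative scaled ranks across cases.

    A true kinase absent from the ranker's kinase universe cannot be
    scored; it is skipped and tallied in ``n_skipped_true`` rather than
    imputed a worst rank.
    """
    if not cases:
        raise ValueError("need at least one benchmark case")
    positives: list[float] = []
    negatives: list[float] = []
    skipped = 0
    for case in cases:
        ranks = ranker(case.query)
        bad = [r for r in ranks.values() if not (0.0 < r <= 1.0)]
        if bad:
            raise ValueError(f"ranker returned scaled ranks outside (0,1]: {bad[:3]}")
        for kinase, r in ranks.items():
            if kinase in case.true_kinases:
                positives.append(r)
            else:
                negatives.append(r)
        skipped += sum(1 for t in case.true_kinases if t not in ranks)
    return ClassScores(positives=positives, negatives=negatives, n_skipped_true=skipped)


def roc_auc(scores: ClassScores) -> float:
    """ROC AUC of s = 1 - scaled_rank; ties count 1/2 (Mann-Whitney convention)."""
    if not scores.positives or not scores.negatives:
        raise ValueError("ROC AUC needs at least one positive and one negative")
    y = np.concatenate([np.ones(len(scores.positives)), np.zeros(len(scores.negatives))])
    s = 1.0 - np.concatenate([scores.positives, scores.negatives])
    return float(roc_auc_score(y, s))


def _pr_curve(pos_scores: np.ndarray, neg_scores: np.ndarray) -> np.ndarray:
    """Precision-recall staircase over all achieved thresholds.

    Points are (recall, precision) at every distinct score threshold,
    descending; the recall-0 anchor uses the precision of the top-scored
    item so a curve always starts at recall 0.
    """
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # indices of the last element of each distinct-score group
    boundaries = np.flatnonzero(np.diff(scores)) if len(scores) > 1 else np.array([], int)
    cut = np.append(boundaries, len(scores) - 1)
    tp = np.cumsum(labels)[cut]
    n_pred = cut + 1.0
    precision = tp / n_pred
    recall = tp / len(pos_scores)
    points = np.column_stack([np.concatenate([[0.0], recall]),
                              np.concatenate([[precision[0]], precision])])
    return points


def _pr_auc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def pr_auc_downsampled(scores: ClassScores, n_boot: int = 1000,
                       seed: int = 0) -> tuple[float, list[np.ndarray]]:
    """Mean PR AUC over bootstrap downsamplings of the negative class.

    Each iteration samples |positives| negatives without replacement,
    builds the PR curve on s = 1 - scaled_rank, and takes its trapezoid
    AUC; the mean over ``n_boot`` iterations and all curves are returned.
    Balancing the classes pins a random classifier's expected PR AUC at
    0.5 independent of library size.
    """
    n_pos, n_neg = len(scores.positives), len(scores.negatives)
    if n_pos < 1:
        raise ValueError("need at least one positive")
    if n_neg < n_pos:
        raise ValueError(
            f"cannot downsample {n_neg} negatives to positive-class size {n_pos}"
        )
    pos = 1.0 - np.asarray(scores.positives)
    neg = 1.0 - np.asarray(scores.negatives)
    rng = np.random.default_rng(seed)
    curves = []
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        sampled = rng.choice(neg, size=n_pos, replace=False)
        points = _pr_curve(pos, sampled)
        curves.append(points)
        aucs[b] = _pr_auc(points)
    return float(aucs.mean()), curves


def composite_pr_curve(pr_curves: Sequence[np.ndarray], grid_size: int = 100) -> np.ndarray:
    """Pointwise-mean PR curve: each curve interpolated onto a shared recall grid."""
    if not pr_curves:
        raise ValueError("need at least one PR curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    stack = np.empty((len(pr_curves), grid_size))
    for i, points in enumerate(pr_curves):
        recall, precision = points[:, 0], points[:, 1]
        # collapse duplicate recall values (vertical staircase drops) by mean
        uniq, inverse = np.unique(recall, return_inverse=True)
        mean_prec = np.bincount(inverse, weights=precision) / np.bincount(inverse)
        stack[i] = np.interp(grid, uniq, mean_prec)
    return np.column_stack([grid, stack.mean(axis=0)])


# ---------------------------------------------------------------------------
# ECDF bridge statistic and Anderson-Darling uniformity test

def ecdf_auc(ranks: Sequence[float]) -> float:
    """Exact area under the ECDF of scaled ranks over [0, 1].

    For a step ECDF of values in (0, 1] this integral equals
    ``1 - mean(ranks)``; a perfect predictor (all ranks at 1/k) approaches
    1, a uniform ranker gives ~0.5.
    """
    r = np.asarray(ranks, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one rank")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("scaled ranks must lie in (0, 1]")
    return float(1.0 - r.mean())


def ecdf_deviation(true_ranks: Sequence[float], grid_size: int = 1000) -> np.ndarray:
    """Sample the bridge statistic D(r) - U on a uniform grid over [0, 1].

    D is the ECDF of the true-kinase scaled ranks and U the uniform CDF
    (U(r) = r). Positive deviation near r = 0 means the true kinases are
    preferentially well ranked.
    """
    r = np.asarray(true_ranks, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one rank")
    grid = np.linspace(0.0, 1.0, grid_size + 1)
    dev = ECDF(r)(grid) - grid
    return np.column_stack([grid, dev])


def _ad_statistic(u: np.ndarray) -> float:
    n = len(u)
    i = np.arange(1, n + 1)
    with np.errstate(divide="ignore"):
        terms = (2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))
    return float(-n - terms.sum() / n)


def _adinf(z: float) -> float:
    # asymptotic CDF of the A^2 statistic (Marsaglia & Marsaglia 2004)
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (math.exp(-1.2337141 / z) / math.sqrt(z)) * (
            2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z)
                                                * z) * z) * z) * z)
    return math.exp(-math.exp(
        1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z)
                                        * z) * z) * z) * z))


def _ad_errfix(n: int, x: float) -> float:
    # finite-n correction to the asymptotic CDF (Marsaglia & Marsaglia 2004)
    if x > 0.8:
        return (-130.2137 + (745.2337 - (1705.091 - (1950.646 - (1116.360 - 255.7844 * x)
                                                     * x) * x) * x) * x) / n
    c = 0.01265 + 0.1757 / n
    if x < c:
        t = x / c
        t = math.sqrt(t) * (1 - t) * (49 * t - 102)
        return t * (0.0037 / n ** 2 + 0.00078 / n + 0.00006) / n
    t = (x - c) / (0.8 - c)
    t = -0.00022633 + (6.54034 - (14.6538 - (14.458 - (8.259 - 1.91864 * t) * t) * t) * t) * t
    return t * (0.04213 + 0.01365 / n) / n


def ad_uniform_test(true_ranks: Sequence[float]) -> float:
    """Anderson-Darling test of uniformity on [0, 1]; returns the p-value.

    The statistic is A^2 = -n - (1/n) sum_i (2i-1)[ln u_(i) + ln(1 - u_(n+1-i))]
    on the sorted ranks, with the finite-n corrected asymptotic p-value.
    Ranks exactly at 1 (a true kinase ranked dead last) drive A^2 to
    infinity, for which the p-value is the limiting 0.
    """
    u = np.sort(np.asarray(true_ranks, dtype=float))
    n = len(u)
    if n < 5:
        raise ValueError("Anderson-Darling test needs n >= 5")
    if np.any((u <= 0) | (u > 1)):
        raise ValueError("scaled ranks must lie in (0, 1]")
    a2 = _ad_statistic(u)
    if not math.isfinite(a2):
        return 0.0
    cdf = _adinf(a2)
    # the finite-n correction has absolute fit error ~1e-5; applying it in
    # the extreme tail would swamp the p-value itself, so skip it there
    if 1.0 - cdf < 1e-5:
        return 1.0 - cdf
    cdf = min(max(cdf + _ad_errfix(n, cdf), 0.0), 1.0)
    return 1.0 - cdf


# ---------------------------------------------------------------------------
# library selection and concordance

def select_libraries(
    metrics: Sequence[Mapping[str, tuple[float, float]]],
    top_fraction: float = 0.5,
    min_benchmarks: int = 2,
) -> set[str]:
    """Select libraries in the top fraction on BOTH metrics for enough benchmarks.

    ``metrics`` holds, per benchmark, a mapping library -> (roc_auc,
    mean_pr_auc). A library passes one benchmark iff it lies within the
    top ``ceil(top_fraction * L)`` libraries on ROC AUC and on mean PR AUC
    separately (ties resolved by better ROC AUC, then name). Selected
    libraries pass at least ``min_benchmarks`` benchmarks.
    """
    if len(metrics) < min_benchmarks:
        raise ValueError("fewer benchmarks than min_benchmarks")
    passes: dict[str, int] = {}
    for bench in metrics:
        names = sorted(bench)
        cutoff = math.ceil(top_fraction * len(names))
        by_roc = sorted(names, key=lambda n: (-bench[n][0], -bench[n][0], n))[:cutoff]
        by_pr = sorted(names, key=lambda n: (-bench[n][1], -bench[n][0], n))[:cutoff]
        for name in set(by_roc) & set(by_pr):
            passes[name] = passes.get(name, 0) + 1
    return {name for name, count in passes.items() if count >= min_benchmarks}


def auecdf(query_lib: GeneSetLibrary, pred_lib: GeneSetLibrary,
           background_size: int = DEFAULT_BACKGROUND, seed: int = 0) -> float:
    """Inter-library concordance: area under the ECDF of matched-kinase ranks.

    Every set in the query library is submitted as a query against the
    prediction library; the scaled ranks of the prediction sets whose
    kinase matches the query set's kinase are pooled and the ECDF area
    over [0, 1] returned. Self-concordance of a library with unique,
    mutually distinguishable sets is 1 - 1/k (every match lands at scaled
    rank 1/k).
    """
    shared = set(query_lib.sets) & set(pred_lib.sets)
    if not shared:
        raise ValueError(
            f"libraries {query_lib.name!r} and {pred_lib.name!r} share no kinases"
        )
    seeds = np.random.SeedSequence(seed).generate_state(len(query_lib.sets))
    matched_ranks = []
    for sub_seed, (kinase, members) in zip(seeds, query_lib.sets.items()):
        if kinase not in pred_lib.sets:
            continue
        table = rank_table(members, pred_lib, background_size, int(sub_seed))
        matched_ranks.append(table.scaled_ranks()[kinase])
    return ecdf_auc(matched_ranks)


def concordance_matrix(libraries: Sequence[GeneSetLibrary],
                       background_size: int = DEFAULT_BACKGROUND,
                       seed: int = 0) -> ConcordanceMatrix:
    """AUECDF for every ordered library pair that shares at least one kinase."""
    out = ConcordanceMatrix()
    for qlib in libraries:
        for plib in libraries:
            if qlib.name == plib.name:
                continue
            if not set(qlib.sets) & set(plib.sets):
                continue
            out.auecdf[(qlib.name, plib.name)] = auecdf(qlib, plib, background_size, seed)
    return out


# ---------------------------------------------------------------------------
# end-to-end report

def run_benchmark(cases: Sequence[BenchmarkCase], rankers: Mapping[str, Ranker],
                  n_boot: int = 1000, seed: int = 0,
                  grid_size: int = 1000) -> dict[str, BenchmarkReport]:
    """Benchmark each ranking source over the cases; returns source -> report."""
    reports = {}
    for name, ranker in rankers.items():
        scores = collect_classes(cases, ranker)
        mean_auc, curves = pr_auc_downsampled(scores, n_boot=n_boot, seed=seed)
        reports[name] = BenchmarkReport(
            source=name,
            roc_auc=roc_auc(scores),
            mean_pr_auc=mean_auc,
            pr_curves=curves,
            composite_pr=composite_pr_curve(curves),
            ecdf_dev=ecdf_deviation(scores.positives, grid_size=grid_size),
            ad_p_value=ad_uniform_test(scores.positives)
            if len(scores.positives) >= 5 else float("nan"),
            n_skipped_true=scores.n_skipped_true,
        )
    return reports


def read_benchmark_cases(path: str | Path) -> list[BenchmarkCase]:
    """Read a GMT-like benchmark file.

    Field 1: comma-separated true kinase symbols; field 2: case label;
    remaining fields: the query symbols.
    """
    cases = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            true = {_clean_symbol(t) for t in fields[0].split(",") if t.strip()}
            seen: dict[str, None] = {}
            for token in fields[2:]:
                sym = _clean_symbol(token)
                if sym:
                    seen.setdefault(sym, None)
            cases.append(BenchmarkCase(query=QuerySet(symbols=list(seen)), true_kinases=true))
    return cases


def write_benchmark_cases(cases: Sequence[BenchmarkCase], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for i, case in enumerate(cases):
            true = ",".join(sorted(case.true_kinases))
            fh.write("\t".join([true, f"case{i:04d}", *case.query.symbols]) + "\n")
    return path


def write_benchmark_report(reports: Mapping[str, BenchmarkReport], path: str | Path) -> Path:
    """One TSV row per ranking source with the scalar metrics."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\troc_auc\tmean_pr_auc\tad_p_value\tn_skipped_true\n")
        for name, rep in reports.items():
            fh.write(f"{name}\t{rep.roc_auc:.6g}\t{rep.mean_pr_auc:.6g}\t"
                     f"{rep.ad_p_value:.6g}\t{rep.n_skipped_true}\n")
    return path
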