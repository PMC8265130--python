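"""ROC/PR benchmarking, ECDF bridge statistics, library selection, concordance."""

import math

import numpy as np
import pytest

from kinrank import (
    BenchmarkCase,
    ClassScores,
    QuerySet,
    ad_uniform_test,
    auecdf,
    collect_classes,
    composite_pr_curve,
    ecdf_auc,
    ecdf_deviation,
    integration_ranker,
    library_ranker,
    pr_auc_downsampled,
    read_benchmark_cases,
    roc_auc,
    select_libraries,
    write_benchmark_cases,
)
from kinrank.benchmark import _ad_statistic, _pr_auc, _pr_curve


class TestCollectClasses:
    def test_one_case_splits_positive_and_negatives(self):
        ranker = lambda q: {f"K{i}": i / 10 for i in range(1, 11)}
        cases = [BenchmarkCase(query=QuerySet(symbols=["A"]), true_kinases={"K1"})]
        scores = collect_classes(cases, ranker)
        assert scores.positives == [0.1]
        assert sorted(scores.negatives) == pytest.approx(
            [i / 10 for i in range(2, 11)])

    def test_true_kinase_absent_is_skipped_and_counted(self):
        ranker = lambda q: {"K1": 0.5, "K2": 1.0}
        cases = [BenchmarkCase(query=QuerySet(symbols=["A"]),
                               true_kinases={"NOT_THERE"})]
        scores = collect_classes(cases, ranker)
        assert scores.positives == []
        assert scores.n_skipped_true == 1

    def test_bookkeeping_over_many_cases(self):
        """|positives| + |negatives| equals the sum of per-case universe sizes."""
        rng = np.random.default_rng(1)
        cases = []
        for i in range(50):
            true = {f"K{int(rng.integers(15))}"}
            cases.append(BenchmarkCase(query=QuerySet(symbols=[f"A{i}"]),
                                       true_kinases=true))
        ranker = lambda q: {f"K{i}": (i + 1) / 10 for i in range(10)}
        scores = collect_classes(cases, ranker)
        n_found_true = 50 - scores.n_skipped_true
        assert len(scores.positives) == n_found_true
        assert len(scores.positives) + len(scores.negatives) == 50 * 10

    def test_out_of_range_ranks_rejected(self):
        ranker = lambda q: {"K1": 1.5}
        with pytest.raises(ValueError, match="scaled ranks"):
            collect_classes([BenchmarkCase(query=QuerySet(symbols=["A"]),
                                           true_kinases={"K1"})], ranker)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = ClassScores(positives=[0.05, 0.1], negatives=[0.5, 0.7, 0.9])
        assert roc_auc(scores) == 1.0

    def test_single_tie_gives_half(self):
        assert roc_auc(ClassScores(positives=[0.3], negatives=[0.3])) == 0.5

    def test_same_distribution_is_near_half(self):
        rng = np.random.default_rng(2)
        scores = ClassScores(positives=rng.uniform(size=500).tolist(),
                             negatives=rng.uniform(size=500).tolist())
        assert roc_auc(scores) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_mann_whitney_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.choice(np.linspace(0.1, 1, 10), size=20).tolist()
        neg = rng.choice(np.linspace(0.1, 1, 10), size=30).tolist()
        wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(ClassScores(positives=pos, negatives=neg)) == \
            pytest.approx(wins / (len(pos) * len(neg)))

    def test_reversing_orientation_flips_auc(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(size=40).tolist()
        neg = rng.uniform(size=60).tolist()
        a = roc_auc(ClassScores(positives=pos, negatives=neg))
        flipped = roc_auc(ClassScores(positives=[1 - p for p in pos],
                                      negatives=[1 - n for n in neg]))
        assert flipped == pytest.approx(1 - a)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(ClassScores(positives=[], negatives=[0.5]))


class TestPrAuc:
    def test_perfect_separation_every_bootstrap(self):
        scores = ClassScores(positives=[0.01, 0.02, 0.05],
                             negatives=[0.5, 0.6, 0.7, 0.8, 0.9])
        mean_auc, curves = pr_auc_downsampled(scores, n_boot=20, seed=0)
        assert mean_auc == 1.0
        assert all(_pr_auc(c) == 1.0 for c in curves)

    def test_staircase_matches_hand_enumeration(self):
        # scores desc: 0.9(+) 0.8(-) 0.7(+) 0.4(+) 0.3(-) 0.1(-); AUC = 55/72
        points = _pr_curve(np.array([0.9, 0.7, 0.4]), np.array([0.8, 0.3, 0.1]))
        expected = [(0, 1), (1/3, 1), (1/3, 1/2), (2/3, 2/3),
                    (1, 3/4), (1, 3/5), (1, 1/2)]
        np.testing.assert_allclose(points, expected)
        assert _pr_auc(points) == pytest.approx(55 / 72)

    def test_iid_uniform_scores_average_half(self):
        rng = np.random.default_rng(5)
        scores = ClassScores(positives=rng.uniform(size=50).tolist(),
                             negatives=rng.uniform(size=500).tolist())
        mean_auc, _ = pr_auc_downsampled(scores, n_boot=200, seed=6)
        assert mean_auc == pytest.approx(0.5, abs=0.05)

    def test_single_bootstrap_deterministic(self):
        rng = np.random.default_rng(7)
        scores = ClassScores(positives=rng.uniform(size=10).tolist(),
                             negatives=rng.uniform(size=40).tolist())
        a1, _ = pr_auc_downsampled(scores, n_boot=1, seed=8)
        a2, _ = pr_auc_downsampled(scores, n_boot=1, seed=8)
        assert a1 == a2

    def test_fewer_negatives_than_positives_rejected(self):
        with pytest.raises(ValueError, match="downsample"):
            pr_auc_downsampled(ClassScores(positives=[0.1, 0.2], negatives=[0.5]))


class TestCompositePr:
    def test_identical_curves_reproduce_curve(self):
        curve = np.array([[0.0, 1.0], [0.5, 0.8], [1.0, 0.6]])
        comp = composite_pr_curve([curve, curve.copy()], grid_size=5)
        np.testing.assert_allclose(comp[:, 1], np.interp(comp[:, 0],
                                                         curve[:, 0], curve[:, 1]))

    def test_mean_of_constant_curves(self):
        c1 = np.array([[0.0, 0.4], [1.0, 0.4]])
        c2 = np.array([[0.0, 0.6], [1.0, 0.6]])
        comp = composite_pr_curve([c1, c2], grid_size=11)
        np.testing.assert_allclose(comp[:, 1], 0.5)

    def test_matches_reimplemented_interpolation_oracle(self):
        rng = np.random.default_rng(9)
        curves = []
        for _ in range(5):
            recall = np.sort(np.concatenate([[0, 1], rng.uniform(size=6)]))
            precision = rng.uniform(size=len(recall))
            curves.append(np.column_stack([recall, precision]))
        grid = np.linspace(0, 1, 50)
        oracle = np.mean(
            [np.interp(grid, c[:, 0], c[:, 1]) for c in curves], axis=0)
        comp = composite_pr_curve(curves, grid_size=50)
        np.testing.assert_allclose(comp[:, 1], oracle, atol=1e-9)


class TestEcdfDeviation:
    def test_perfect_predictor_gives_one_minus_r(self):
        k = 10
        dev = ecdf_deviation([1 / k] * 25, grid_size=100)
        grid, values = dev[:, 0], dev[:, 1]
        at_or_after = grid >= 1 / k
        np.testing.assert_allclose(values[at_or_after], 1 - grid[at_or_after])

    def test_full_grid_ranks_stay_within_one_over_n(self):
        n = 50
        ranks = [(i + 1) / n for i in range(n)]
        dev = ecdf_deviation(ranks, grid_size=500)
        assert np.abs(dev[:, 1]).max() <= 1 / n + 1e-12

    def test_uniform_ranks_obey_dkw_bound(self):
        rng = np.random.default_rng(10)
        dev = ecdf_deviation(rng.uniform(size=1000), grid_size=2000)
        assert np.abs(dev[:, 1]).max() < 0.07

    def test_trapezoid_integral_matches_exact_ecdf_area(self):
        """Bridge-statistic area equals AUECDF-style area minus 1/2."""
        rng = np.random.default_rng(11)
        ranks = rng.uniform(size=300)
        dev = ecdf_deviation(ranks, grid_size=1000)
        integral = np.trapezoid(dev[:, 1], dev[:, 0])
        assert integral == pytest.approx(ecdf_auc(ranks) - 0.5, abs=1e-3)


class TestAdUniformTest:
    def test_statistic_matches_textbook_formula(self):
        u = [0.1, 0.3, 0.5, 0.7, 0.9]
        n = len(u)
        expected = -n - sum(
            (2 * (i + 1) - 1) * (math.log(u[i]) + math.log(1 - u[n - 1 - i]))
            for i in range(n)) / n
        assert _ad_statistic(np.array(u)) == pytest.approx(expected)

    def test_point_mass_strongly_rejected(self):
        assert ad_uniform_test([0.01] * 100) < 1e-6

    def test_uniform_sample_not_rejected(self):
        rng = np.random.default_rng(12)
        assert ad_uniform_test(rng.uniform(size=200)) > 0.05

    def test_needs_five_observations(self):
        with pytest.raises(ValueError, match="n >= 5"):
            ad_uniform_test([0.1, 0.2, 0.3, 0.4])

    def test_rank_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ad_uniform_test([0.1, 0.2, 0.3, 0.4, 1.5])


def _selection_oracle(metrics, top_fraction, min_benchmarks):
    passes = {}
    for bench in metrics:
        names = sorted(bench)
        m = math.ceil(top_fraction * len(names))
        roc_sorted = sorted(names, key=lambda n: (-bench[n][0], -bench[n][0], n))
        pr_sorted = sorted(names, key=lambda n: (-bench[n][1], -bench[n][0], n))
        top = set(roc_sorted[:m]) & set(pr_sorted[:m])
        for name in top:
            passes[name] = passes.get(name, 0) + 1
    return {n for n, c in passes.items() if c >= min_benchmarks}


class TestSelectLibraries:
    def test_top_library_everywhere_selected(self):
        bench = {"L1": (0.9, 0.9), "L2": (0.6, 0.6),
                 "L3": (0.5, 0.5), "L4": (0.4, 0.4)}
        assert "L1" in select_libraries([bench] * 3)

    def test_both_metrics_required(self):
        metrics = [{"L1": (0.9, 0.1), "L2": (0.8, 0.8),
                    "L3": (0.1, 0.9), "L4": (0.5, 0.5)}] * 3
        assert "L1" not in select_libraries(metrics)

    def test_matches_brute_force_predicate_oracle(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            L = int(rng.integers(3, 9))
            metrics = [
                {f"L{i}": (float(rng.uniform()), float(rng.uniform()))
                 for i in range(L)}
                for _ in range(3)
            ]
            assert select_libraries(metrics) == _selection_oracle(metrics, 0.5, 2)

    def test_monotone_in_metrics(self):
        rng = np.random.default_rng(14)
        metrics = [
            {f"L{i}": (float(rng.uniform()), float(rng.uniform()))
             for i in range(6)}
            for _ in range(3)
        ]
        selected = select_libraries(metrics)
        for name in selected:
            boosted = [
                {n: ((v[0] + 0.2, v[1] + 0.2) if n == name else v)
                 for n, v in bench.items()}
                for bench in metrics
            ]
            assert name in select_libraries(boosted)

    def test_too_few_benchmarks_rejected(self):
        with pytest.raises(ValueError):
            select_libraries([{"L1": (0.5, 0.5)}], min_benchmarks=2)


class TestAuecdf:
    def test_ecdf_mass_at_one_gives_zero_area(self):
        assert ecdf_auc([1.0, 1.0, 1.0]) == 0.0

    def test_self_concordance_closed_form(self, random_library_factory):
        lib = random_library_factory(seed=15, n_sets=4, set_size=20,
                                     universe_size=300)
        assert auecdf(lib, lib, seed=1) == pytest.approx(1 - 1 / 4)

    def test_unrelated_libraries_near_half(self, random_library_factory):
        qlib = random_library_factory(seed=16, n_sets=50, set_size=20,
                                      universe_size=5000, name="q")
        plib = random_library_factory(seed=17, n_sets=50, set_size=20,
                                      universe_size=5000, name="p")
        assert auecdf(qlib, plib, seed=2) == pytest.approx(0.5, abs=0.1)

    def test_disjoint_kinase_names_rejected(self, random_library_factory):
        qlib = random_library_factory(seed=18, n_sets=3)
        plib = random_library_factory(seed=19, n_sets=3)
        plib.sets = {f"OTHER{i}": v for i, v in enumerate(plib.sets.values())}
        with pytest.raises(ValueError, match="share no kinases"):
            auecdf(qlib, plib)


class TestFullPipeline:
    def test_meanrank_beats_pure_noise_libraries(self, random_library_factory):
        """With one signal library and three noise libraries, integrating by
        MeanRank can never trail the noise-only libraries on ROC AUC."""
        signal_lib = random_library_factory(seed=20, n_sets=10, set_size=20,
                                            universe_size=500, name="signal")
        noise_libs = [
            random_library_factory(seed=30 + i, n_sets=10, set_size=20,
                                   universe_size=500, name=f"noise{i}")
            for i in range(3)
        ]
        rng = np.random.default_rng(40)
        cases = []
        for _ in range(30):
            kinase = f"KIN{int(rng.integers(1, 11)):03d}"
            members = signal_lib.sets[kinase]
            query = rng.choice(members, size=10, replace=False).tolist()
            cases.append(BenchmarkCase(query=QuerySet(symbols=query),
                                       true_kinases={kinase}))
        all_libs = [signal_lib] + noise_libs
        mr = roc_auc(collect_classes(
            cases, integration_ranker(all_libs, "meanrank", seed=1)))
        for noise in noise_libs:
            noise_auc = roc_auc(collect_classes(
                cases, library_ranker(noise, seed=1)))
            assert mr >= noise_auc

    def test_cases_file_round_trip(self, tmp_path):
        cases = [BenchmarkCase(query=QuerySet(symbols=["A", "B"]),
                               true_kinases={"K1", "K2"}),
                 BenchmarkCase(query=QuerySet(symbols=["C"]),
                               true_kinases={"K3"})]
        path = write_benchmark_cases(cases, tmp_path / "cases.gmt")
        back = read_benchmark_cases(path)
        assert [c.query.symbols for c in back] == [["A", "B"], ["C"]]
        assert [c.true_kinases for c in back] == [{"K1", "K2"}, {"K3"}]
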