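"""Benchmark libraries and integration methods on labeled synthetic cases.

Generates 60 cases whose queries carry half of a true kinase's substrate
set, benchmarks the clean library, two degraded copies, and MeanRank
integration, then applies the selection rule (both ROC AUC and mean PR
AUC in the top half, here trivially on one benchmark repeated).
"""

from kinrank import (SyntheticSpec, degrade_library, integration_ranker,
                     library_ranker, make_benchmark, make_library,
                     run_benchmark, select_libraries)

spec = SyntheticSpec(universe_size=2000, n_kinases=20,
                     set_size_range=(50, 50), query_size=30,
                     signal_fraction=0.5, n_cases=60, seed=31)
clean = make_library(spec, name="clean")
cases = make_benchmark(clean, spec)
noisy = [degrade_library(clean, 0.6, spec.universe_size, seed=40 + i,
                         name=f"noisy{i}") for i in range(2)]
libs = [clean] + noisy

rankers = {lib.name: library_ranker(lib, seed=2) for lib in libs}
rankers["MeanRank"] = integration_ranker(libs, "meanrank", seed=2)
reports = run_benchmark(cases, rankers, n_boot=200, seed=2)

print("source     ROC AUC  mean PR AUC  AD p-value")
for name, rep in reports.items():
    print(f"{name:<10} {rep.roc_auc:.3f}    {rep.mean_pr_auc:.3f}        "
          f"{rep.ad_p_value:.2g}")

metrics = [{n: (r.roc_auc, r.mean_pr_auc) for n, r in reports.items()
            if n != "MeanRank"}] * 3
print("\nselected libraries:", sorted(select_libraries(metrics)))
print("A tiny Anderson-Darling p-value means true-kinase scaled ranks are"
      " far from uniform, i.e. the source carries real signal.")
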