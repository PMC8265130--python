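"""Rank upstream kinases for a query protein set against one library.

Builds a small synthetic kinase-substrate library, plants a query that
carries half of kinase KIN007's substrates, and prints the top of the
enrichment table. The true kinase should surface at rank 1 with a tiny
Fisher p-value; unrelated kinases cluster near p = 1.
"""

import numpy as np

from kinrank import SyntheticSpec, make_library, rank_table

spec = SyntheticSpec(universe_size=2000, n_kinases=20,
                     set_size_range=(50, 50), seed=7)
library = make_library(spec)

rng = np.random.default_rng(1)
signal = rng.choice(library.sets["KIN007"], size=15, replace=False).tolist()
noise = [f"G{i:06d}" for i in range(1900, 1915)]
query = signal + noise

table = rank_table(query, library, background_size=20000, seed=3)
print(f"library of k={table.k} kinase sets, query of {len(query)} proteins")
print("rank  kinase   overlap  p-value    FDR        scaled")
for row in table.rows[:5]:
    print(f"{row.integer_rank:>4}  {row.kinase}  {row.overlap_count:>7}  "
          f"{row.p_value:<9.3g}  {row.fdr:<9.3g}  {row.scaled_rank:.2f}")
print("\nRank 1 is the kinase whose substrate set overlaps the query most"
      " significantly; scaled rank = rank / k feeds integration and benchmarks.")
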