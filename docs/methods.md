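# Methods

## Model and assumptions

The central object is a gene-set library: a map from kinase symbols to
sets of putative substrate symbols. Enrichment of a query protein set in
a kinase's substrate set is modelled as sampling without replacement from
a fixed background universe, so the overlap count follows a
hypergeometric distribution and the one-sided Fisher's exact p-value is
the upper tail P(X ≥ a). The background is a fixed integer (default
20 000, roughly the protein-coding gene count) rather than an explicit
gene list: the 2×2 table is built purely from set sizes. This assumes
the query and the substrate sets are drawn from a common, equally sized
universe; queries dominated by genes outside that universe (e.g.
non-coding transcripts) would make p-values anticonservative.

Per-library rankings deliberately retain zero-overlap kinases (p = 1,
placed randomly within the tie region) so that scaled ranks always cover
the full grid {1/k, …, 1}. Integration and benchmarking both rely on
this: MeanRank's mean integer rank and the negative-class scaled ranks
are only comparable across libraries when every library ranks its entire
kinase complement.

Rank integration treats each library as one voter. MeanRank averages
integer ranks over only the libraries containing the kinase — a kinase
absent from a library is excluded from that library's mean, not imputed
at rank k — which favours kinases that are consistently well ranked but
does not penalise sparse coverage. TopRank takes the minimum scaled rank
and therefore rewards a single strong library. Score ties break first
toward the kinase supported by more libraries, then by a seeded RNG.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `background_size` | 20 000 | universe size for the 2×2 table (genes) |
| `min_substrates` | 5 | minimum distinct partners for a kinase to enter an edge-built library |
| `top_n` | 300 | co-expression set size per kinase |
| `n_boot` | 1 000 | bootstrap downsamplings per PR AUC estimate |
| `top_fraction` / `min_benchmarks` | 0.5 / 2 | selection rule: both metrics in the top ⌈0.5·L⌉ for ≥ 2 benchmarks |
| `grid_size` | 1 000 | sampling grid for the bridge statistic D(r) − U |
| `seed` | required | every tie-break and bootstrap; recorded in outputs |

All seeds are explicit; there is no wall-clock fallback, because random
p-value tie-breaking would otherwise make repeated runs silently
non-reproducible.

## Benchmarking estimators and numerical choices

**Classifier orientation.** ROC/PR machinery consumes s = 1 − scaled
rank so that a perfect predictor attains AUC 1. ROC AUC uses the
Mann–Whitney convention (ties count ½).

**PR curve.** The curve is the achieved (recall, precision) staircase
over all distinct score thresholds, anchored at recall 0 with the
precision of the top-scored item, and integrated by trapezoid. With the
negative class downsampled to the positive-class size, the expected PR
AUC of an uninformative ranker is 0.5 by symmetry; the staircase
estimator carries a small positive finite-sample offset (≈ +0.01 at 50
positives, consistent with the ~1/(2n) order of the anchor bias), which
is well inside the calibration band checked by the acceptance script.
A single 50/500 dataset draw has sampling SD ≈ 0.03 in its 1 000-bootstrap
mean PR AUC, so the calibration estimate averages 25 replicate datasets
to bring its standard error to ≈ 0.006.

**Composite PR curves.** Each bootstrap curve is linearly interpolated
onto a shared recall grid; duplicate recall values (vertical staircase
segments) are collapsed by mean precision before interpolation.

**AUECDF.** The area under a step ECDF of values in (0, 1] over [0, 1]
equals 1 − mean(ranks); it is computed in that closed form rather than by
grid quadrature. The bridge statistic D(r) − U is sampled on a uniform
grid for plotting/inspection, and its trapezoid integral agrees with the
closed-form area minus ½ to O(1/grid_size) — the consistency the test
suite asserts at 10⁻³ with the default 1 000-point grid.

**Anderson–Darling uniformity test.** A² is computed from the textbook
order-statistic formula, with the Marsaglia & Marsaglia (2004)
asymptotic CDF plus finite-n correction for the p-value. The correction
polynomial has absolute fit error ~10⁻⁵, so it is skipped when the
asymptotic tail is already below 10⁻⁵ — otherwise the correction noise
would swamp extreme p-values. A scaled rank exactly at 1 (a true kinase
ranked dead last) makes A² infinite; the p-value is the limiting 0.
Calibration is verified empirically: type-I error at α = 0.05 over 1 000
uniform null datasets of n = 100 lies in [0.03, 0.08].

**Selection rule.** Top-half cutoffs use ⌈0.5·L⌉; metric ties resolve by
better ROC AUC, then lexicographic library name, making the selection
deterministic for odd L.

## Library construction choices

- Undirected PPI edges treat each endpoint as a putative substrate of
  the other when that endpoint is a kinase; directed (KSI) edges
  contribute the target to the source's set only. Self-edges are ignored.
- "Most correlated" in co-expression sets means largest **positive**
  Pearson r, not |r|: co-expression is used as a proxy for shared pathway
  membership, and anti-correlated genes are weaker evidence of shared
  regulation. Correlation ties break by row order; zero-variance rows are
  excluded (r undefined) and a zero-variance kinase is omitted with a
  warning.
- Quantile normalization maps each column onto the per-rank mean of the
  column-sorted values; within-column ties receive the mean of their
  target slots, which makes the operation idempotent.
- Duplicate gene rows keep the maximal-variance row; exact ties keep the
  first occurrence.
- Evidence-type subsetting (e.g. binding-only PPI) is a caller-supplied
  predicate on the edge's evidence label.

## Synthetic data: what it emulates and what it does not

The generators produce libraries with uniformly sampled substrate sets
over an artificial `G000001…` namespace, benchmark queries that mix a
`signal_fraction` of a true kinase's substrates with background noise,
edge lists that invert library construction, and expression matrices with
planted latent-factor co-expression modules. Defaults (universe 2 000,
20 kinases × 50 substrates, 30-protein queries at signal fraction 0.5,
200 cases) define the planted-signal recovery conditions exercised by the
test suite.

These fixtures capture overlap statistics and rank behaviour, not
biology: real substrate sets are heavy-tailed in size, heavily
overlapping in non-uniform ways, and benchmark "true kinases" come from
noisy perturbation readouts. Passing the planted-signal tests therefore
shows the machinery is correct and well calibrated, not that any
particular evidence source performs well on real phosphoproteomics data.

One subtlety of the noise model: queries at `signal_fraction = 0` draw
their genes from the universe *excluding* the true set, which slightly
depresses the true kinase's overlap relative to chance. The "null ≈ 0.5
ROC AUC" behaviour therefore holds only when sets are small relative to
the universe; at a 50/2000 set/universe ratio the exclusion bias is
visible, and the null test uses a dilute 20/20000 regime.

## Known limitations

- Phosphosite-level evidence (site-specific substrate scoring,
  up/down-regulation direction) is out of scope; sets are plain symbol
  lists.
- The background is a count, not a gene list, so queries cannot be
  restricted to a measured universe (e.g. the proteins detectable in a
  given MS run).
- No FDR is attached to integrated (MeanRank/TopRank) scores; FDRs are
  per-library only.
- The AD p-value is asymptotic (with finite-n correction); for n < 5 the
  test refuses rather than returning an unreliable value.
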