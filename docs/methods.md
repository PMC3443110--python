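# Methods

## Data model

The pipeline operates on summary-level microarray exports: per gene and per
array a non-negative linear-scale signal and a detection call in
{Present, Marginal, Absent}. Probe-level data (CEL/CHP, probe-set
condensation, instrument change calls) are outside the package's scope; the
one selection criterion that originally depended on them is re-expressed at
the summary level (see below).

## Normalization

Each array is scaled independently by `target / trimmed_mean(signals)`.
Trimming is symmetric and count-based: of k values, the `floor(k·trim)`
smallest and largest are removed, with `trim = 0.02` and `target = 150` by
default. Count-based trimming was chosen over percentile interpolation
because instrument software documentation leaves the convention ambiguous;
fixing one convention makes every downstream number deterministic. Scaling
is exactly idempotent and rank-preserving.

Log-scale statistics use floored signals, `log2(max(signal, floor))` with
`floor = 10`. The floor caps the dynamic range of decreases, guarantees
finite log intensities, and makes `log2(10) = 3.32` the smallest possible
group mean — the value that recurs as a hard minimum in small-sample
expression tables. The floor is applied only inside log-space statistics;
the stored matrix keeps unfloored scaled signals. Group "mean log2
intensity" is the arithmetic mean of per-array floored log2 signals (a
geometric mean on the linear scale), and the fold difference between groups
is `2^(mean_b − mean_a)`, so fold values below 1 denote decreases.

## Exact rank-sum testing

For groups of sizes (n_a, n_b) the test enumerates all `C(n_a+n_b, n_b)`
assignments of the observed values. The statistic U counts pairwise wins of
group B over A with ties scoring ½ (equivalently mid-rank sums). Two-tailed
extremity is the symmetric distance `|U − n_a·n_b/2|`; for tie-free data
this equals the doubled one-sided tail, and for tied data it remains well
defined. Ties are handled permutation-exactly: the null ranges over
assignments of the observed multiset itself. Distances live on a
half-integer grid, compared with a 1e-9 slack to keep floating-point noise
out of the discrete counts.

Enumeration is capped at 14 total samples (worst case 3432 assignments);
larger designs fall back to a tie-corrected normal approximation and are
flagged `exact=False`. For a shared design across thousands of genes the
assignment index set is built once and all per-assignment statistics are
computed as one vectorized gather-and-sum.

Two derived quantities document the discreteness of the support:
`min_achievable_p(m, n) = min(1, 2/C(m+n, n))` (complete separation), and
`kth_smallest_p(m, n, k)`, the cumulative two-tailed probability of the
k-th most extreme distinct level — for 4 vs 4 the second level is 4/70 =
0.0571, which is where a three-decimal cutoff of 0.057 comes from; whether
that cutoff was chosen for exactly that reason is documented but not
assumed anywhere in the code.

## The four-criterion filter

A gene is Increased or Decreased (by the sign of the group-mean difference)
only if all four criteria hold, otherwise Unchanged:

1. high-group mean over low-group mean strictly greater than
   `fold_threshold` (default 2), on floored log2 means;
2. at least `min_present_high` Present calls in the high-expression group,
   capped at the group size so 3-member groups require 3/3;
3. exact two-tailed p ≤ `max(p_max, min_achievable_p(m, n))` when
   `adaptive_min_p` is set (default), else ≤ `p_max`. With the default
   `p_max = 0.057` the adaptive rule leaves 4 vs 4 unchanged and relaxes
   3 vs 3 to its floor of 0.1 — the only threshold that design can meet;
4. at least `(m−1)·n` of the `m·n` cross-group sample pairs (m ≥ n) show a
   same-direction ratio ≥ `pairwise_fold` (default 2) on floored signals.
   This is the package's summary-level stand-in for per-pair instrument
   change calls: it preserves the rule's intent — the difference must be
   consistent across almost all pairings — using only exported signals.

No multiple-testing correction is applied; the procedure is a fixed
selection filter and is reported as such. Raising the fold threshold can
only shrink the selected set, and disabling the pairwise rule can only
enlarge it (both are tested properties).

## Concordance and overlap

Direction labels from three contrasts (knockout effect at each age, plus
the adult-vs-immature WT "developmental" contrast) are counted into a
3×3×3 integer tensor with axes ordered (Increased, Decreased, Unchanged).
Concordant increases/decreases are the (Inc,Inc)/(Dec,Dec) cells summed
over the developmental axis. The modulated-overlap percentage divides genes
non-Unchanged in either knockout contrast AND non-Unchanged developmentally
by all genes non-Unchanged in either knockout contrast; the unaffected
analogue conditions on doubly-Unchanged genes. The tensor is
layout-agnostic; the writer renders the conventional nested layout
(developmental axis nested within the second contrast's axis) with plain
integers.

Cross-study overlap uses Pearson's χ² without continuity correction on the
3×3 direction table (df = 4), with per-cell fold enrichment
`observed / (row_total · col_total / N)` for the two concordant cells.
Because published statistics of this kind can reach p ≈ 10⁻¹⁶¹, the log
survival function supplies `log10(p)` alongside p, which underflows to 0 in
double precision long before the statistic stops being meaningful.

## Keyword tallies and reporter arithmetic

GO Biological Process text is scanned by plain case-insensitive substring
match — the default tokens `immun`/`inflamm` are deliberate prefixes that
catch immune/immunity/autoimmune and inflammation/inflammatory. Up/down
counts aggregate over all supplied contrasts, so a gene may count in both
directions; each count is bounded by the number of matching genes but their
sum is not.

Reporter assays normalize firefly by Renilla per well and define
fold-activation as mean-of-ratios over mean-of-ratios (treatment over
empty-vector control), with the SEM of the treatment replicates divided by
the control mean. Whether published SEMs are over wells or independent
experiments is generally unstated; this package computes the well-level
SEM and leaves experiment-level aggregation to the caller.

## Synthetic data

The generator emulates the study design: WT and KO at two ages, 3 replicates
per group at PN11 and 4 at PN56, one array per sample. Per-gene baselines
are `N(baseline_log2_mean, baseline_log2_sd)` on the log2 scale, per-array
noise is additive `N(0, noise_sd)` on log2 (log-normal signals — matching
the fold-ratio arithmetic the pipeline uses throughout), and planted
effects add a signed `effect_log2` shift in three independent layers: KO
at PN11, KO at PN56, and a developmental layer applied to every PN56 array.
Detection calls are thresholded on the linear signal — Absent below 90% of
`present_threshold`, Marginal within ±10%, Present above (a zero threshold
makes every call Present); the instrument's probe-level call algorithm is
not emulated. All draws come from a single `numpy` Generator seeded once,
so identical configs give identical experiments.

Defaults are fixed at the modelled study's conditions: 3+3/4+4 design,
`effect_log2 = 2` (4-fold, the scale of the filter's fold criterion),
`de_fraction = 0.05`, `noise_sd = 0.3`, and `baseline_log2_mean = 7`,
`baseline_log2_sd = 2`, `present_threshold = 100`, which together put
roughly 55% of calls at Present — close to the ~58% detection rate typical
of these arrays — and centre scaled signals near the 150 target.

What the generator does **not** emulate: probe-level structure, spatial
artifacts, correlated noise between arrays, heavy-tailed or
intensity-dependent variance, and annotation realism beyond planted
immune-keyword text. Passing recovery benchmarks therefore demonstrates
correctness of the selection machinery under the stated generative model,
not performance on real arrays.

## Benchmark conditions and problem sizes

The parameter-recovery benchmark uses the 4 vs 4 contrast with
`noise_sd = 0.3`, 4-fold planted effects in 5% of 2000 genes, detection
always Present (`present_threshold = 0`) and baselines far above the floor
(`baseline_log2_mean = 8, sd = 1.5`), over 5 seeds; the filter achieves
≥ 90% sensitivity with ≤ 1% false positives (observed: 93–96% and 0%). The
few misses are planted decreases whose low baselines push the knockout
group into the floor, capping the measurable fold below 2 — a property of
the procedure, not a defect of the test. Null calibration uses the same
design with no planted effects: the p-criterion alone fires at ≤ its
discrete ceiling (0.1 for 3 vs 3) and the full filter's call rate is below
1%. Super-uniformity of null p-values and agreement with a brute-force
enumeration oracle are checked at a few thousand simulated genes and all
group sizes up to 5, keeping the whole suite in the tens of seconds.
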