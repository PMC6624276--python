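# Methods

## The information statistic

At every frame *t* the population splits into dead and alive. With
cells partitioned into *n* equal-frequency bins of an initial covariate
*y*, the statistic is

I(x_t; y) = H(p) − (1/n) Σᵢ H(pᵢ),

where p is the overall dead fraction, pᵢ the dead fraction in bin i,
and H the binary entropy in bits (0·log 0 := 0). Two implementation
points matter:

- **Unweighted bin average.** The conditional entropy averages the
  per-bin entropies with weight 1/n, not with the bin occupancies.
  For equal-size bins — the only case the equal-frequency binning
  produces when n divides N — this coincides with the standard
  count-weighted conditional entropy, and the statistic equals the
  plug-in mutual information of the joint (bin, state) table.
  `mi_oracle` computes that plug-in MI independently from the joint
  counts; a property test holds the two routes together to 1e−12 bits
  over random equal-bin configurations. With unequal bin sizes the two
  deliberately differ (the unweighted form can even go slightly
  negative); the package implements the unweighted form as the primary
  statistic and keeps the oracle as the cross-check.
- **Exact zeros.** Frames where every cell shares one state, or where
  every bin has exactly the marginal dead fraction, return 0.0 without
  evaluating per-bin terms, so the stated limiting cases hold exactly
  rather than to round-off. In the vectorized trace, residues below
  1e−12 bits (floating round-off of the bin average) are snapped to
  zero.

No small-sample bias correction (Miller–Madow or similar) is applied:
chance-level information is instead quantified empirically by the
permutation null, which is how the estimator's finite-sample bias is
meant to be read. The trace's peak is reported at the earliest frame
attaining the maximum (ties broken deterministically).

## Binning

Cells from all replicate positions are pooled, ranked by the covariate
from low to high, and split into n_bins groups whose sizes differ by at
most one; when N mod n_bins ≠ 0 the extra cells go to the lowest-index
(dimmest) bins. Ties in the covariate are broken by stable input
order. The assignment therefore depends on the covariate only through
its ranks, making the downstream statistic invariant under any strictly
increasing transform of fluorescence — important because reporter
intensities are in arbitrary units. The permutation counterpart
(`random_grouping`) keeps exactly these bin sizes but draws membership
uniformly at random from a seeded generator.

Ten bins is the default; `bin_sensitivity` recomputes the peak for any
list of bin counts, and the qualitative separation between linked and
null datasets is stable across 5–20 bins. The default is fixed rather
than optimized per dataset: at the ~500-cell scale of a pooled
experiment, deciles of ~50 cells keep per-bin dead fractions reasonably
estimated while resolving the covariate.

## Permutation null

For each of 100 (default) seeded random groupings the full information
trace is computed and its peak recorded. The observed peak is declared
significant when it exceeds the null's empirical 95th percentile; the
percentile is a configurable convention, exposed because any fixed
threshold here is a choice, not a derivation. The permutation RNG is
seeded independently of the simulation RNG so nulls are reproducible on
imported real data as well. Null peaks are strictly positive (plug-in
bias) and shrink with N; a test checks the median null peak at N = 1000
sits below the median at N = 100.

## Synthetic experiments

The generator emulates the statistical structure of single-cell
time-kill microscopy, not its biophysics:

- **Design:** 5 replicate positions × 100 cells, frames every 5 min for
  300 min. These defaults match the common time-lapse layout for this
  kind of experiment and give the pooled ~500 cells the binning
  defaults assume.
- **Initial fluorescence:** log-normal (log-mean 5.0, log-SD 0.5,
  arbitrary units). Real reporter distributions are right-skewed and
  heterogeneous; log-normal is the standard minimal model for
  single-cell expression and gives CV ≈ 0.53 at the default log-SD.
- **Death times:** death = center + link(q) + couplings + Gaussian
  noise, where q is the cell's fluorescence quantile under the
  generating distribution and link is one of
  ±strength·(q − ½) (continuous negative/positive),
  strength·1[q > 0.9] (top-decile threshold), or 0 (null). Using the
  theoretical quantile rather than the empirical rank keeps every
  cell's fate independent of the rest of the sample, so adding
  replicate positions never perturbs existing ones. Defaults
  (center 120 min, strength 120 min, noise SD 15 min) concentrate
  killing in the 1–3 h window and give the continuous link a 120-min
  programmed death-time span. The noise magnitude is a qualitative
  choice — real per-reporter noise is not separately identifiable from
  published summaries — so tests assert shape and discrimination, not
  fitted values.
- **Size and growth:** log-normal around 3 µm and 0.02 min⁻¹ (~35-min
  doubling, exponential phase). Growth rate stands in for the
  size-increase-over-first-20-min estimate used on real movies.
  Optional couplings add ±coupling·(q − ½) minutes to the death time;
  the growth coupling enters with a negative sign so that positive
  coupling makes slow growers survive longer, the direction reported
  for β-lactams.
- **Frame grid and censoring:** death times are snapped to the nearest
  frame (earliest possible death = first frame) and cells whose time
  exceeds the movie length are recorded censored, exactly as a movie
  truncates observation. Censored cells count as alive at every frame
  in all downstream statistics.

What the generator does *not* emulate: lineage structure and division,
segmentation/death-call errors, position-to-position batch effects,
non-Gaussian death-time noise, and any mechanistic pharmacodynamics.
Passing tests therefore demonstrate that the analysis recovers planted
statistical structure under realistic sampling noise — not that any
particular biological promoter behaves this way.

## Survival summaries

The killing curve is the cumulative dead fraction per frame, with
per-position curves and their pointwise population SD (ddof = 0, so a
single position yields zeros rather than NaN). The fate matrix is the
per-bin killing curve; death exactly at frame t counts as dead at t
(closed boundary, matching cumulative counts at each time point). The
bin-size-weighted mean of its rows reproduces the overall curve to
1e−12 — a conservation identity used as a standing test.

Time to 50% killing per decile is the first frame whose cumulative dead
fraction reaches the target (first crossing on the grid, no
interpolation); bins that never reach it are excluded from the spread
with a logged warning. Crossing times are smoothed *across bin index*
with a Savitzky–Golay filter before taking max − min, so one outlier
decile does not set the spread. Window 5 / order 2 over the 10 deciles
is the default — the narrowest window that still damps a single-bin
outlier while preserving a linear trend exactly; both parameters are
exposed, and window 1 / order 0 is the identity filter.

Promoter strength and noise are the mean and coefficient of variation
of initial fluorescence (population SD by default, ddof configurable).
Cross-promoter correlations of peak information against such statistics
report both Pearson and Spearman coefficients, returning NaN (rather
than raising) when an input is constant.

## Numerical and interface choices

- Entropies use `scipy.special.xlogy`, so p = 0 and p = 1 are exact.
- All randomness flows through `numpy.random.SeedSequence`; per-position
  and per-permutation substreams are spawned from one root seed, and
  repeated runs are byte-identical down to the written files (CSV reads
  use round-trip float parsing for losslessness).
- The cell table is a plain CSV (one row per cell) with censoring
  encoded as an empty `death_time_min` plus a `censored` flag; the
  frame grid is carried by the simulation config (YAML) or inferred
  (5-min interval, movie end at the last observed death, minimum
  300 min) when only the CSV is available.
- Problem sizes in the test suite (500-cell experiments, 20-seed
  replication studies, 100-permutation nulls) mirror the pooled ~500-cell
  scale of the experimental design the defaults encode.

## Known limitations

- The unweighted conditional-entropy average is faithful to the
  statistic as defined but is not a proper mutual information for
  unequal bins; use equal-frequency binning (the default) when
  interpreting values as bits of MI.
- The spread metric depends on the smoothing parameters, which are a
  convention; absolute spreads should be compared only at fixed
  window/order.
- Censoring is handled by treating censored cells as survivors for the
  whole movie, which biases late-time dead fractions downward if many
  cells outlive the movie; the information peak, typically mid-movie,
  is insensitive to this.
- Multivariate (multi-reporter) information and binless continuous-MI
  estimators are out of scope.
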