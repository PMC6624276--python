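# fateinfo

Quantify how much a single bacterial cell's state *before* antibiotic
exposure predicts *when* that cell will die.

In time-lapse killing experiments, isogenic *E. coli* populations show
striking heterogeneity: under a lethal dose of a β-lactam such as
carbenicillin, some cells lyse within an hour while others persist for
several. Much of this spread is forecast by stochastic gene expression —
a cell's reporter fluorescence at the moment of antibiotic addition
(*t* = 0) — as well as by its size and early growth rate. `fateinfo`
implements the analysis that turns such single-cell movies into a
quantitative statement of predictive power, together with a synthetic
experiment generator so the whole pipeline is testable without
microscopy data.

## The statistic

Cells are ranked by an initial covariate *y* (reporter fluorescence by
default) and split into equal-frequency bins — deciles, each holding
10% of the cells. At every movie frame *t* the binary state
*x<sub>t</sub>* (alive/dead) is compared with bin membership:

```
I(x_t; y) = H(x_t) − H(x_t | y)

H(x_t)     = −p log₂ p − (1 − p) log₂(1 − p),          p = overall dead fraction
H(x_t | y) = (1/n) Σᵢ H(dead fraction in bin i),        n = number of bins
```

All quantities are in bits. For a binary state the information is at
most 1 bit, attained only when bin membership separates the population
into fully-dead and fully-alive halves. It is exactly zero when all
cells share one state (everybody alive at *t* = 0, everybody dead after
long exposure) and when every bin kills at the same rate (expression
unrelated to fate). When cells die in exact fluorescence-rank order the
trace is a rise-and-fall arc peaking at 1.0 bit at the frame where half
the cells are dead.

The **peak** of the trace summarizes a promoter's predictive power, and
the frame where it occurs is when expression is most informative.
Significance is judged against a **permutation null**: cells are
regrouped into tenths at random (100 times by default) and the observed
peak is compared with the null's 95th percentile.

Around the statistic the package provides:

- a **synthetic-data generator** (`simulate_experiment`) producing
  replicate microscopy positions of cells with log-normal initial
  fluorescence and death times linked to expression through continuous
  negative / continuous positive / top-decile-threshold / null shapes,
  snapped to a 5-min frame grid and right-censored at movie end;
- **killing curves** (mean ± SD across replicate positions) and the
  per-decile cumulative-death **fate heatmap**;
- **killing-time spread**: per-decile time to 50% death,
  Savitzky–Golay-smoothed across deciles, max − min;
- promoter **strength/noise statistics** (mean fluorescence, CV) and
  cross-promoter correlations of peak information with them;
- a **CLI** (`fateinfo simulate / analyze / permute / report`) that
  writes TSV/CSV/JSON outputs and a reproducibility manifest.

## Worked example

```sh
fateinfo simulate --seed 1 -o demo/sim
fateinfo analyze -i demo/sim/cells.csv -c demo/sim/config.yaml -o demo/out
```

The default simulation is five positions of 100 cells, imaged every
5 min for 5 h, with a strong continuous negative expression–death link
(bright cells die later). The analyze step logs:

```
INFO fateinfo: loaded 500 cells from demo/sim/cells.csv
INFO fateinfo: peak information 0.698 bits at t=125 min (null 95th pct 0.035, significant)
```

and `demo/out/permutation.json` contains:

```json
{
  "observed_peak_bits": 0.697667426201112,
  "observed_peak_time_min": 125.0,
  "null_mean_bits": 0.02535235796123573,
  "null_percentile_bits": 0.035493617180998346,
  "exceeds_null": true,
  "n_permutations": 100,
  "n_bins": 10
}
```

Reading: at 125 min — near the half-killing point — knowing a cell's
initial-fluorescence decile removes 0.70 of the 1.0 bit of uncertainty
about whether it is dead, ~20× more than the ≈0.035 bits expected from
random grouping (finite-sample bias of the plug-in estimator). The
decile spread report (`decile_spread.json`) puts ~111 min between the
fastest- and slowest-dying deciles after smoothing, consistent with the
simulated 120-min expression-linked death-time span.

The same `analyze` command works on real data: any CSV with columns
`cell_id, position_id, initial_fluorescence, initial_size, growth_rate,
death_time_min, censored` (empty death time + `censored=1` for cells
alive at movie end).

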