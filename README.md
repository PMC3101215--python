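# adapart

Adaptive partitioning of a "time course" into consecutive blocks whose
adjacent population means (or proportions) differ significantly at a
user-chosen level α — multiple change-point detection with a built-in
two-sample significance restriction.

The core is a modified dynamic program that finds the *globally optimal*
(minimum-SSE / maximum-likelihood) partition within the α-restricted
space, by screening each candidate predecessor block with a two-sample
test (pooled t for continuous responses; proportion z / Fisher exact for
binary ones). Two classic greedy baselines — recursive combination
(bottom-up merging) and recursive partition (top-down splitting) — are
included for comparison, along with:

- a permutation F-type test of the no-change-point null,
- bootstrap time-point-wise confidence intervals,
- cross-validated selection of α (LOO or k-fold),
- a simulation harness (step / flat / multi-step / U-shape scenarios)
  with overall-MSE and pointwise MSE/bias/variance metrics,
- an exhaustive-search oracle (n ≤ 20) used to verify global optimality.

One-sided alternatives turn the method into reduced isotonic/monotonic
regression (α = 1 recovers classical isotonic regression; α = 0 yields a
single block).

## Python API

```python
import numpy as np
from adapart import TimeCourse, fit_dp, select_alpha, permutation_test, bootstrap_cis

tc = TimeCourse(
    times=[1, 2, 3, 4],
    observations=[[0, 1, 2], [1, 2, 0], [10, 11, 12], [11, 12, 10]],
)
fit = fit_dp(tc, alpha=0.05)
fit.change_points        # (2.0,)  — time value ending each left block
fit.block_estimates      # [1.0, 11.0]
fit.objective            # total SSE = 8.0

sel = select_alpha(tc, grid=[1e-4, 1e-3, 0.05])   # CV-chosen alpha
res = permutation_test(tc, alpha=0.05, B=199, seed=1)
cis = bootstrap_cis(tc, alpha=0.05, B=500, seed=1, level=0.95)
```

Binary responses: pass `mode="binary"` (observations in {0, 1}); the
objective switches to the Bernoulli negative log-likelihood and junction
tests to proportion-z / Fisher (automatic small-cell rule: Fisher when
any 2×2 cell is below six).

## Command line

Input is long-format CSV/TSV with one row per observation
(columns `time`, `response` by default):

```bash
adapart fit data.csv --alpha 0.001                      # fit at fixed alpha
adapart fit data.csv --alpha 0.001 --algorithm rc       # greedy baseline
adapart select-alpha data.csv --grid 1e-4,1e-3,0.05     # CV choice of alpha
adapart test data.csv --alpha 0.001 --permutations 199  # permutation p-value
adapart ci data.csv --alpha 0.001 --bootstrap 500       # bootstrap intervals
adapart simulate --scenario step --m 10 --reps 100      # method comparison
```

`--mode binary` switches to binary responses; `--round-time 5` rounds the
time variable to the nearest multiple of 5 (half-up) before grouping —
useful for noisy continuous predictors such as glucose measurements.
Outputs are a block table (TSV), a pointwise table (TSV) and a JSON
summary, all written to `--outdir`.

## Layout

| module | contents |
| --- | --- |
| `adapart.timecourse` | `TimeCourse`, blocks/partitions, prefix-sum block statistics, objectives |
| `adapart.twosample` | pooled t, proportion z, Fisher exact, junction feasibility |
| `adapart.dp` | the modified dynamic program, backtracking, exhaustive oracle |
| `adapart.baselines` | recursive combination / recursive partition |
| `adapart.inference` | permutation F-type test, bootstrap confidence intervals |
| `adapart.model_selection` | CV error, α-grid selection |
| `adapart.simulate` | scenario generator, MSE/bias/variance metrics, method comparison |
| `adapart.io`, `adapart.cli` | table readers/writers, `adapart` CLI |
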