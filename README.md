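# arakin

Single-molecule kinetics of promoter activation and activity in live
bacteria: a pipeline for counting individual RNA production events in
time-lapse fluorescence data and dissecting the contributions of inducer
*intake* and multi-step *transcription initiation* to the timing and
cell-to-cell diversity of gene expression.

The package targets MS2-GFP-type experiments on the arabinose-inducible
P_BAD system in *E. coli*: each tagged transcript appears as a bright
fluorescent spot, a cell's total spot intensity is a noisy non-decreasing
staircase over time, and each upward step marks the production of one RNA.
From the per-cell event times two quantities follow:

- **t0** — the waiting time from inducer introduction to the first RNA,
  reflecting inducer intake *plus* one transcription-initiation event;
- **Δt** — intervals between subsequent productions, reflecting initiation
  alone.

## What the package computes

- **Synthetic populations** (`arakin.synthetic_data`): ground-truthed cells
  with hypoexponential intake delays (default: two steps, mean 1444 s),
  renewal RNA production with hypoexponential intervals (default: three
  steps, mean 1440.6 s), Poisson(0.2) spurious pre-induction RNAs, 2 h
  traces sampled every 60 s, and optional rendered TIFF image stacks with
  cell masks.
- **Spot quantification** (`arakin.spot_quantification`): per-cell Gaussian
  smoothing + Otsu segmentation of spots inside supplied masks,
  background-corrected integrated spot intensities, total-spot-intensity
  traces, and single-RNA unit-intensity calibration from the first mode of
  the spot-intensity distribution.
- **Event detection** (`arakin.event_detection`): globally optimal monotone
  piecewise-constant least-squares fits (dynamic programming + isotonic
  pooling), segment count selected by a nested F-test at P = 0.01; one
  production event per jump; t0/Δt extraction with the pre-existing-RNA
  exclusion rule and right-censoring of the final partial interval.
- **Interval statistics** (`arakin.interval_statistics`): moments and the
  normalized variance σ²/µ² (σ²/µ² < 1 ⇒ sub-Poissonian production),
  two-sample Kolmogorov–Smirnov tests, and the windowed Pearson correlation
  analysis that removes the finite-observation artefact coupling t0 and Δt.
- **d-step models** (`arakin.step_model`): hypoexponential (phase-type)
  densities stable at equal rates, maximum-likelihood fitting with d fixed
  a priori (2 intake / 3 initiation / 5 combined), one-sample K–S
  goodness-of-fit (optionally parametric-bootstrap), and the intake-time
  estimate t_diff by moment subtraction:
  µ_diff = µ_t0 − µ_Δt, σ²_diff = σ²_t0 − σ²_Δt.
- **Transient dynamics** (`arakin.transient_dynamics`): exact stochastic
  simulation of intake phases → cycling initiation phases → RNA birth with
  first-order degradation; population mean, variance and Fano factor of RNA
  numbers over time; 95%-of-plateau equilibrium times; degradation-rate
  sweeps with common random numbers.

## Worked example

```sh
arakin simulate --n-cells 60 --seed 2 --outdir run
arakin detect --traces run/traces.tsv --unit-intensity 100 --outdir run
arakin stats --series run/series.tsv --intervals run/intervals.tsv
```

prints (output of the commands above):

```
t0	n=44	mean=2899.1 s	sd=1231.7 s	sigma2/mu2=0.18
dt	n=146	mean=1316.3 s	sd=771.2 s	sigma2/mu2=0.34
K-S t0 vs dt: D=0.631, p=1.2e-13
```

44 of 60 cells yield a usable waiting time (the rest produced no RNA in
2 h or carried a pre-induction RNA and are excluded from t0 by rule).
Both distributions are sub-Poissonian (σ²/µ² ≪ 1), and the K–S test
rejects their equality decisively — the waiting time contains the intake
delay that the inter-production intervals lack. Note that both means are
shortened relative to the generator's (2885 s and 1441 s) by the finite
2 h window, exactly as in the real measurement. Continuing,

```sh
arakin tdiff --series run/series.tsv --intervals run/intervals.tsv
#   tdiff mean_s=1582.8	sd_s=960.5	valid=True
arakin transient --intake-rates 0.001385,0.001385 --cells 10000 --seed 1
#   equilibrium_time_s: 4196 (1.17 h)
#   steady_state_mean: 0.2075
arakin transient --intake-rates "" --cells 10000 --seed 1
#   equilibrium_time_s: 1542 (0.43 h)
#   steady_state_mean: 0.2072
```

The moment subtraction recovers an intake time of order 25 minutes, and
the stochastic simulations show its population-level consequence: with the
two-step intake the mean RNA number needs well over an hour to reach 95%
of its plateau, while the same promoter with instantaneous intake settles
in under half an hour — the intake process acts as a delay long after
induction. A full run (`arakin run --config cfg.yaml --outdir out`)
chains all stages with per-stage seeds derived from one global seed and
writes every intermediate TSV plus `summary.json`.

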