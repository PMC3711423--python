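# Methods

This note documents the models, estimators and numerical choices behind
`arakin`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real microscopy data.

## The kinetic model

A cell activated by an external inducer is modelled as two sequential
stochastic processes:

1. **Intake.** The inducer crosses the membrane through a sequence of
   `d_in` memoryless (exponential) steps — by default two, representing
   binding to an uptake protein and translocation to the cytoplasm. The
   total intake time is therefore hypoexponential with rates
   λ₁…λ_{d_in}; mean Σ1/λᵢ, variance Σ1/λᵢ².
2. **Transcription initiation.** Once the promoter is inducible, RNAs
   are produced as a renewal process whose inter-event times are
   hypoexponential with `d_init` steps — by default three, representing
   closed-complex formation, open-complex formation and promoter escape.
   A sum of d comparable exponential steps has squared coefficient of
   variation near 1/d < 1: the sub-Poissonian signature that the
   measured interval statistics show (σ²/µ² ≈ 0.1–0.4).

The waiting time to the first RNA, t0, is the sum of the intake time and
one initiation interval; subsequent intervals Δt reflect initiation
alone. Elongation and fluorophore binding are treated as instantaneous
(they are an order of magnitude faster than initiation). Tagged RNAs are
effectively immortal on the 2 h observation scale, so intensity traces
are non-decreasing; RNA degradation enters only the copy-number models
(below).

## Synthetic data generator

`PopulationParams` defaults encode the reference measurement conditions:
2 h observation at one frame per minute; two-step intake with mean
1444 s (the moment-subtraction estimate under strong induction);
three-step initiation with mean 1440.6 s (the measured mean interval);
Poisson(0.2) spurious pre-induction RNAs per cell; unit intensity 100
a.u. per RNA.

Choices the measurements do not constrain, fixed once as plausible
fixtures rather than claims about the instrument:

- **Trace noise** is additive i.i.d. Gaussian on the total-intensity
  staircase, sd 10 a.u. (10% of a unit step). No published noise
  magnitude exists for these traces; 10% makes single steps clearly
  resolvable but not trivial, and the sd is a parameter so harder
  regimes are testable.
- **Rendered images** place each RNA as a pixel-integrated 2-D Gaussian
  spot (σ = 1.5 px) at a position drawn once per RNA, over a uniform
  per-cell background with pixel noise 0.7 a.u. — peak amplitude ≈ 10×
  the pixel noise, i.e. the spot SNR regime the detection examples
  assume. Photobleaching, focus drift, cell growth, division and motion
  are not simulated; masks are static rectangles.
- An **empty intake-rate list** encodes infinitely fast intake
  (activation at t = 0), avoiding a second model class.

Every draw derives from `numpy.random.SeedSequence`, spawned per cell:
the same seed reproduces populations bit-for-bit, and per-cell streams
are independent of population size ordering.

## Spot quantification

Spots are detected inside user-supplied labelled masks (cell
segmentation and tracking are upstream problems, out of scope here):

1. The frame is smoothed by *masked* (normalized) Gaussian convolution,
   σ equal to the optical spot width. Masked convolution matters: plain
   smoothing bleeds the darker inter-cell background into cell edges and
   the resulting rim, not the spots, dominates a per-cell threshold.
2. Otsu's threshold is computed from the smoothed values within each
   cell separately, because cells differ in free-fluorophore background.
   Otsu always returns a split, so a cell counts as containing spots
   only if the foreground–background contrast exceeds 4 robust (MAD)
   standard deviations of the smoothed in-cell signal; otherwise the
   split is noise and the cell contributes no spots.
3. Connected components above threshold (≥ 4 px) are spot cores. Cores
   are dilated by 2σ before integration so the Gaussian tails are
   counted — integrating the core alone loses 20–30% of the spot mass.
   Spot intensity = raw pixel sum over the aperture − aperture area ×
   cell background (median of in-cell non-spot pixels), clipped at 0.

Both the detection count and the corrected intensities are invariant to
adding a constant to the frame (Otsu's threshold and the median shift
with the data).

The single-RNA **unit intensity** is the first local maximum of a
Gaussian-KDE of pooled spot intensities; a spot's RNA count is its
intensity over the unit, rounded, minimum 1. This requires ≥ 30 spots
and a detectable mode; otherwise the caller must supply the unit.

## Event detection

Each trace is fit by a monotone piecewise-constant function chosen by
least squares. For every candidate segment count k, dynamic programming
over breakpoints yields the globally optimal (unconstrained) k-segment
partition in O(T²k); if its segment means decrease anywhere they are
pooled by weighted isotonic regression (PAVA) and equal-level neighbours
are merged — for genuinely staircase-like data this repair is rarely
triggered. k is selected forward by a nested F-test: adding a segment
costs two parameters (a level and a breakpoint), so k vs k−1 segments is

F = ((SSE_{k−1} − SSE_k)/2) / (SSE_k /(T − 2k)),  df = (2, T − 2k),

and selection stops at the first k whose test fails to reject at
α = 0.01. The df accounting and α are configurable; the forward stopping
rule (rather than global selection) matches a single-threshold term
count selection.

Each upward jump is one RNA production, timed at the first frame of the
new segment — a resolution of one frame interval (60 s) is inherent.
Rules applied when converting fits to event series:

- t0 = first event time − induction time; cells whose initial level
  exceeds half a unit intensity carried RNA before induction and are
  excluded from t0 (flagged, not discarded) while their Δt are kept.
- The partial interval from the last event to the end of the trace is
  right-censored and never emitted as a Δt.
- An optional quantized mode emits round(amplitude/unit) simultaneous
  events per jump for robustness studies; the default is strictly one
  per jump.

## Interval statistics

Moments use the n−1 denominator (at the sample sizes involved, ≥ 70,
the difference from n is below printed precision). The normalized
variance σ²/µ² is the squared coefficient of variation.

Two-sample K–S tests use exact enumeration when both samples have ≤ 10
points and the asymptotic Kolmogorov distribution with effective size
n_a n_b/(n_a+n_b) otherwise; astronomically small p-values are reported
as computed, not clamped, and no multiple-testing correction is applied
across condition pairs.

**Windowed correlation.** Because t0 and Δt are of the same order as
the 2 h window, naive per-cell correlation is biased: late-starting
cells cannot exhibit long intervals. The windowing used here — retain
only cells with t0 ≤ T − W, count only events in [t0, t0 + W], with W
scanned over the frame grid to maximize the number of (t0, Δt) pairs
(largest W on ties) — equalizes the effective observation span across
retained cells. Its justification is behavioural: on synthetic
populations where t0 and Δt are independent by construction, the
windowed Pearson test rejects at ≈ the nominal 5% rate (calibration
test over 200 replicates), i.e. the window introduces no artificial
correlation of its own.

## d-step models and the intake time

Hypoexponential densities and CDFs are evaluated through the phase-type
representation: the bidiagonal generator's matrix exponential computed
by **uniformization** — the Poisson-weighted series over powers of the
sub-stochastic jump matrix P = I + T/max(λ), truncated where the
Poisson(λ_max t) mass falls below ~1e−13. All terms are non-negative,
so the evaluation is stable when rates coincide (the Erlang limit),
which maximum-likelihood optimizers routinely visit. The textbook
distinct-rate partial-fraction formula is kept only as a cross-check; it
agrees to < 1e−10 where rates are ≥ 10% apart and cancels
catastrophically otherwise.

Fitting maximizes the likelihood over log-rates (L-BFGS-B, bounds wide
around the sample scale) from multiple starts: the moment-matched
Erlang point (all rates d/mean), a spread start, and seeded lognormal
perturbations; the best optimum is kept and rates are returned sorted
ascending (the likelihood is permutation-invariant). d is fixed a
priori — 2 (intake), 3 (initiation), 5 (combined) — not model-selected.
Goodness of fit is a one-sample K–S test against the fitted CDF; since
testing against a fitted model biases the standard p-value upward, a
parametric-bootstrap variant (resample, refit, recompute D) is provided
as the honest alternative.

The **intake time** t_diff cannot be observed directly (the first
initiation event is entangled with it), so its moments come from
subtraction: mean = µ_t0 − µ_Δt (valid regardless of dependence),
variance = σ²_t0 − σ²_Δt (valid under independence of intake and
initiation, which the near-zero measured correlations support). A
negative variance difference is reported with an in-band invalid flag,
never truncated to zero or raised as an error.

## Transient copy-number dynamics

The copy-number model couples the intake phases to a cycling initiation
chain (completing the last phase emits one RNA and re-enters the first)
with first-order RNA degradation. Because the phase chain does not
depend on the RNA count, the exact stochastic trajectory of each cell
is generated event-driven — intake delay, renewal production times, one
exponential lifetime per RNA — which is an exact realization of the
chemical master equation for this scheme, equivalent to Gillespie's
algorithm but vectorizable across cells. Cross-cell mean, variance and
Fano factor are sampled on a regular grid (10⁴ cells, 60 s grid, 6 h
horizon in the reference runs; each such run takes seconds).

Numerical/interpretive choices:

- The degradation default is k_d = 1/300 s⁻¹: a printed rate of
  "5 min⁻¹" is read as a mean RNA lifetime of 5 min, since a literal 5
  events per minute (12 s lifetime) lies outside realistic *E. coli*
  ranges. The rate is a parameter everywhere.
- **Equilibrium time** is the first (linearly interpolated) time the
  population mean reaches 95% of its plateau, the plateau being the
  mean over the final 10% of the grid. No published criterion exists;
  95% is fixed but the fraction is a parameter so conclusions can be
  checked across 0.90–0.99. With this plateau definition a crossing
  always exists for fractions < 1; the horizon-too-short error path is
  defensive.
- Degradation sweeps reuse identical structural randomness (births and
  unit-rate lifetimes scaled by 1/k_d) across k_d values — common
  random numbers, so comparisons across the sweep are variance-reduced
  and strictly paired.
- Populations are independent cells: no extrinsic noise, division or
  lineage structure, matching the model class the transient figures
  describe.

Under the reference parameters the simulations give: equilibrium in
≈ 1.2 h with the two-step intake versus ≈ 0.43 h with instantaneous
intake; steady-state mean ≈ (1/µ_Δt)/k_d ≈ 0.21; steady-state Fano
≈ 0.85 (sub-Poissonian, as forced by the 3-step initiation) versus
exactly 1 for single-step initiation; and an early-time Fano elevation
(> 1) present only with the intake stage. These are the quantities the
acceptance script and tests recompute.

## What passing tests do and do not show

The synthetic generator shares the *statistical* structure of the real
data (staircase traces, hypoexponential durations, spurious initial
RNAs, 60 s sampling) but idealizes everything optical: Gaussian spots
of fixed position and brightness, uniform backgrounds, no bleaching,
drift or division, and noise levels chosen rather than measured.
Round-trip recovery therefore validates the estimators' correctness
and calibration under the stated model, not the pipeline's robustness
to instrument artefacts. Conversely, the arithmetic reproductions
(normalized variances, moment subtraction) and the simulation bounds
are exact consequences of published population moments and hold
independently of the generator.

## Problem sizes

Default test and script sizes — 10⁴ cells for simulation summaries,
400-cell populations for end-to-end recovery, n = 500 samples for ML
recovery, 100–200 replicates for calibration rates — were chosen so
that Monte-Carlo error is comfortably below every tolerance asserted;
all are parameters, and larger runs only tighten the comparisons.
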