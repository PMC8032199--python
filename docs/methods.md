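# Methods

## Model dynamics

The simulator is a discrete-time, two-stage race between two alternatives.
Stage one holds two independent, rectified accumulators

    x_i(t) = max( x_i(t−1) + S_i + ε_i(t), 0 ),   ε_i(t) ~ N(0, σ_acc),

one per stimulus alternative, with constant mean drive S_i ≥ 0 per step
(stimulus drives are in arbitrary evidence units; only ratios to σ matter,
since the model is invariant to a joint rescaling of S, σ and T). Stage two
holds two rectified differencing units that receive excitation from the
same-preference accumulator and inhibition from the opposing one:

    δ_i(t) = max( x_i(t) − x_j(t) + ξ_i(t), 0 ),   ξ_i(t) ~ N(0, σ_diff).

Within a time step the accumulators are advanced first and the differencing
units are computed from the updated accumulator values; the differencing
units are memoryless (recomputed from the current x each step). By default
σ_diff = σ_acc — noise at both processing levels is drawn from the same
distribution — but σ_diff is a separate parameter so it can be zeroed in
tests and held fixed in the noise-manipulation design (below).

A decision is made the first time a differencing unit strictly exceeds the
bound T (δ > T). If both units cross on the same step the larger δ wins,
with exact ties broken uniformly at random. Accumulation then continues
for τ further steps and two raw confidence readouts are taken from the
winning side: the absolute decision-congruent evidence C_x = x_D(t_RT + τ)
and the balance of evidence C_δ = δ_D(t_RT + τ). Both are recorded on
every trial, so the competing "C_x model" and "C_δ model" share identical
decision and RT streams by construction.

**Time convention.** The time index starts at t = 1 on the resting state
(x = 0); the first update produces the state at t = 2, and the reported
reaction time is the state index at which δ_D first exceeds T — one more
than the number of updates. This convention reproduces the model's
published zero-drive calibration anchors (average median RT ≈ 80.6 steps
and average minimum RT ≈ 7.3 steps at σ = 0.1, T = 1, over 10 repetitions
of 10,000 trials); counting updates alone gives ≈ 79.5 and ≈ 6.2. With
zero noise and drives (s, 0), rt = 1 + min{k : k·s > T} and
C_x = (rt − 1 + τ)·s exactly.

**Censoring.** Trials that have not crossed the bound by `max_steps`
(default 10,000 state indices) are flagged censored, decided by the larger
δ at the horizon, and retained in all summaries. At the default operating
point (σ = 0.1, T = 1, S ≥ 0) censoring essentially never occurs.

**Randomness.** Every simulation call derives two independent substreams
from its seed: one for the pre-decision race, one for the post-decision
period. Decisions and RTs are therefore exactly invariant to τ under a
shared seed — the property the experiment harnesses rely on when pairing
the two readouts and the High/Low arms of a grid. Trial tables are
byte-reproducible given a seed.

## Confidence ratings

Raw confidence is mapped to an N_r-point ordinal rating (default N_r = 4)
by counting strictly exceeded thresholds, R = 1 + #{r : C > U_r}. The
thresholds are set by quantile matching: U_r is the type-7 (linearly
interpolated) empirical quantile of the confidence sample pooled across
all conditions of a simulated dataset, at cumulative probability
Σ_{i≤r} P(conf = i) of the target rating distribution. By construction the
realized rating distribution then reproduces the target to within 1/n per
category. Thresholds are refit per readout (C_x vs C_δ) and per
experiment, since they condition on the readout's own distribution.
Degenerate samples (non-invertible quantiles) are deduplicated with an
infinitesimal jitter and a warning.

## Measurement layer: d′ and meta-d′

Type-1 sensitivity is equal-variance SDT: d′ = z(HR) − z(FAR),
c = −(z(HR) + z(FAR))/2. A log-linear correction (0.5 added to every cell
of the stimulus × response × rating table) is applied uniformly before
both the d′ and meta-d′ computations — always, not only at saturated
cells, to keep the estimators continuous.

meta-d′ is estimated by maximum likelihood: an equal-variance SDT observer
with sensitivity meta-d′, type-1 criterion fixed at the observed relative
criterion (meta-c = c′·meta-d′ with c′ = c/d′; c′ is set to 0 when
|d′| < 10⁻³), and one ordered set of type-2 criteria per response side, is
fitted to the response-conditional rating counts by maximizing the
multinomial log-likelihood. Criteria are parameterized as log-gaps from
meta-c (enforcing the ordering constraint exactly), optimized with
L-BFGS-B from three starts (meta-d′ initialized at d′, at a shrunken d′,
and at 2.0; criteria initialized from the observed rating ECDF), with an
objective tolerance of 1e−9. Response-conditional meta-d′ restricts the
likelihood to one response side; a side with fewer than 5 error trials is
flagged low-reliability rather than dropped. Tables whose ratings are
concentrated on a single level are returned non-converged with meta-d′
undefined.

## Calibration

No closed forms exist for d′ or meta-d′ of the dynamic model, so control
parameters are set by simulation. σ = 0.1 and T = 1 are fixed a priori as
the reference operating point. Then:

* **S → d′**: d′ is simulated at 10 evenly spaced drive values, a
  least-squares quadratic is fitted to the d′-vs-S curve (R² > 0.99 on the
  default grid), and the quadratic is solved for the root inside the grid
  span (on the increasing branch if both roots qualify; roots within half
  a grid step outside the span are accepted and clipped). The default grid
  [0, 0.03] spans d′ ≈ 0–3.5 at the reference point; because sensitivity
  scales roughly with (1 − α)·S/σ, the grid is automatically rescaled by
  σ/(0.1·(1 − α)) when the condition has accumulation noise σ or an
  opposing-drive ratio α, keeping the spanned d′ range comparable.
* **τ → meta-d′**: meta-d′ is simulated on the integer grid
  τ ∈ {0, 10, …, 90} (thresholds refit per grid point by the quantile
  procedure), a quadratic is fitted and inverted, and the solution is
  rounded to the nearest integer. meta-d′ rises monotonically with τ,
  from ≈ 0 at τ = 0 toward d′.
* Calibration simulations default to 10,000 trials per grid point; the
  round-trip error of both calibrations shrinks with this size (checked in
  the tests at two sizes).

At τ = 0 the fitted meta-d′ is not exactly zero but slightly negative
(≈ −0.13 at d′ ≈ 2): errors are on average slower than correct responses,
and slower trials accumulate more decision-congruent evidence, so
confidence weakly anti-predicts accuracy at the moment of decision. This
is a genuine property of the dynamics, reported as computed.

## Experiment harnesses

All three harnesses follow one discipline: S is calibrated so d′ matches
its empirical target in every condition; τ is calibrated once, to the
meta-d′ target of a single representative condition, and reused
everywhere; rating thresholds are quantile-matched on confidence pooled
across all conditions of the run. Everything else — response-conditional
meta-d′, performance-matched confidence differences, RT effects — is a
prediction of the architecture, not a fitted quantity.

* **Crossover design**: stimulus "A" has fixed drive S_A (trials drive the
  accumulators as (S_A, 0)); stimulus "B" takes five levels
  S_B = scale·S_A with scales (0.4, 0.7, 1.0, 1.3, 1.6). τ is calibrated
  to the overall meta-d′ target at the middle (symmetric) level. The
  diagnostic is the pair of Spearman signs of the response-conditional
  meta-d′ trends against d′: the C_x readout yields (−, +) — the X-shaped
  dissociation — because errors of the fixed-stimulus response must beat
  an ever stronger competitor and so carry ever more decision-congruent
  evidence; the C_δ readout yields same-signed trends.
* **Positive/negative evidence design**: every trial drives both
  accumulators, (S_PE, α·S_PE) with α < 1, α_low < α_high. For each
  α_high on the grid (default α_low + 0.1 … 0.9 in steps of 0.1), S is
  recalibrated so the High arm's d′ matches the Low-arm mean d′, and the
  performance-matched confidence difference, meta-d′ difference and
  relative RT effect are read out. The best-fitting α_high minimizes the
  distance to the target confidence difference; failure to attain the
  target anywhere on the grid is flagged (`at_boundary`).
* **Noise design**: single-signal trials, with the High arm's
  accumulation noise σ swept over 0.11 … 0.20 and S recalibrated per σ.
  The σ manipulation models stimulus (sensory-evidence) variability, so
  it applies to the accumulation noise ε only; the internal differencing
  noise ξ stays at the baseline 0.1 in both arms. (Scaling ξ as well
  reverses the sign of the C_δ confidence effect and contradicts the
  qualitative pattern this design is meant to exhibit.)

The relative RT effect is η_RT = (RT_high,med − RT_low,med) /
(RT_low,easy − RT_low,difficult), computed from mean RTs and reported as
the raw ratio without re-signing; it is invariant to affine time-unit
rescaling, so step-based and millisecond-based analyses agree. Fitting
errors are signed differences (predicted − target) at each readout's
best-fitting grid point; measures without a supplied target are reported
missing, never as zero error.

High/Low arms share seeds at every grid point (paired simulation, reducing
Monte-Carlo variance of the difference statistics), and the two readouts
share the complete decision stream, so their d′ and RT values are
identical to the last bit at identical parameters.

## Synthetic fixtures

The fixture generator emulates the condition-level summaries an empirical
study would supply — per-condition d′, meta-d′, mean confidence, rating
distribution and RT summaries, plus the cross-condition effect sizes — by
simulating the model itself with known ground truth, using the C_x readout
by default (a C_δ mode exists for specificity tests). Defaults mirror the
studies' structure: Low-arm mean d′ ≈ 1.71 for the PE/NE design and
≈ 0.99 for the noise design, 4-point ratings with distribution
(0.2, 0.3, 0.3, 0.2), α_low = 0.1 with α_high = 0.3, σ_low = 0.1 with
σ_high = 0.13, and τ = 60 post-decision steps. τ = 60 places metacognitive
efficiency meta-d′/d′ at ≈ 0.7–0.8, the range typical of empirical
datasets; much lower efficiency would make the synthetic "empirical"
targets unrepresentative of the data the harnesses are meant to fit.
Perturbed fixtures add Gaussian jitter to targets (rating distributions
renormalized) to emulate finite-sample studies (~480 trials per
condition).

What fixtures do *not* emulate: raw psychophysical stimuli, lapses,
criterion drift, between-subject variability, or any deviation of real
observers from the generating model. Passing recovery tests therefore
shows the pipeline is self-consistent and identifiable at realistic
sizes — not that the model fits any particular real dataset.

## Problem sizes

Calibrations default to 10,000 trials per grid point. The test suite runs
the grid experiments at 10,000 trials per condition (5,000 per stimulus
class) with 12,000-trial calibrations, and fixtures at 8,000 trials per
condition — sizes at which the matched-d′ discipline holds to within 0.1
and all orderings are stable. The acceptance script uses the published
10 × 10,000-trial design for the baseline RT statistics and averages five
complete 10,000-trial repetitions for the τ = 0 meta-d′.

## Known limitations

* Two alternatives only; no collapsing bounds, drift variability, or
  leaky/competing accumulation.
* The meta-d′ fitter assumes equal-variance type-1 distributions and a
  fixed relative type-1 criterion; hierarchical or Bayesian variants are
  out of scope.
* The quadratic calibration is local to its grid: targets outside the
  spanned outcome range raise rather than extrapolate.
* Quantile thresholds require a pooled confidence sample from the same
  readout being rated; thresholds are not transferable across readouts.
* The fitted constants of the original studies (specific α_high/σ_high
  values) depend on empirical summaries that are not public; the harnesses
  reproduce the procedures and orderings, not those constants.
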