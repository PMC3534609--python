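# Methods

## Model

Body weight is modelled as the solution of a diffusion equation whose
boundary condition is set by net energy intake.  The continuous form,

V(t) = (E/p)·[1 − erf(x/(2√(Dt)))] + V0·erf(x/(2√(Dt))),

is a convex combination of the initial mass V0 and the steady mass E/p
(energy available divided by the energy density of fat mass, p ≈ 9400
kcal/kg for adipose tissue); `continuous_weight` evaluates it with the
standard error function erf(c) = (2/√π)∫₀ᶜ e^(−u²)du.  At x = 0 it
returns the boundary value E/p, as t → 0⁺ (x > 0) the initial mass, and
as t → ∞ the steady mass.

Freezing the spatial coordinate gives the discrete weekly recursion that
all fitting uses:

f(t) = f(t−1)·erf(β) + α·7·l(t)·[1 − erf(β)]

with f in kg, l(t) the week's mean daily net energy intake in kcal/day,
and t indexed in weeks.  The factor 7 converts the daily net intake into
a weekly energy dose; equivalently, 7·α·l is the fixed point the
trajectory relaxes towards at constant intake, at geometric rate erf(β)
per week.  Units are kg, kcal/day and weeks throughout; the model core
performs no unit conversion.  The recursion is not clamped at zero: a
sustained large deficit can drive it negative, which is logged as a
warning rather than silently altered, so that fitted objectives remain
exactly the stated ones.

Two simulation modes exist.  `chained` (the default everywhere) feeds
each prediction back as the next week's previous weight — a pure model
rollout.  `one_step_ahead` conditions each week on the observed previous
weight; it is retained as a flagged mode because the two modes answer
different questions (rollout skill versus one-week-ahead skill).  The
published trajectories are reproduced by the chained mode.

Goodness of fit is the coefficient of determination R² = 1 − SSE/SST with
SST about the observed mean; the squared Pearson correlation is exposed
as a second variant (`kind="correlation"`).  The published R² values
(0.99666 for S1–S24, 0.98499 for S1–S12, 0.94229 for the S13–S24
forecast) are reproduced by the chained mode scored with 1 − SSE/SST; the
forecast starts from the observed S12 weight (57.28 kg), the standard
forecasting convention, with the fitted S12 start available as a flag.

## Energy accounting

Total energy expenditure is REE + AEE.  REE (kcal/day) is resting oxygen
uptake (cc/min) × 1.44 × the caloric equivalent of oxygen (kcal/L); the
1.44 is stored as 1440 min/day ÷ 1000 cc/L, not as a magic float.
Caloric equivalents depend on the respiratory quotient and must be
supplied by the caller from standard indirect-calorimetry tables; none
are bundled.  The two activity terms scale linearly with body weight
relative to a 54-kg reference subject: outdoor walking costs
(w/54)·(daily miles / speed)·cost·60 kcal/day and the weekly treadmill
session (w/54)·cost·minutes/7 kcal/day.  Daily mileage is the weekly
mileage divided by 7 and quoted to hundredths of a mile (22 mi/wk →
3.14 mi/day), matching the study's own arithmetic; with full-precision
division the walking figure would be 220.29 rather than the study's
220.1 kcal/day at week S24.  Walking costs for speeds or weights other
than the tabulated ones must be supplied by the user — no interpolation
table is invented.  Net energy intake is food intake − TEE and may be
negative.

## Parameter estimation

The fitting posterior is the Box–Tiao noninformative form for a
least-squares problem, p(θ|y) ∝ SSE(θ)^(−N/2), evaluated on the log
scale; maximising it is exactly minimising SSE, and the same density
yields posterior draws for interval construction.  The posterior is
isolated behind a log-density functional, so alternatives (e.g. Gaussian
with known σ) plug in without touching the sampler.

### SCEM-UA

One run draws s points uniformly from the current box, ranks them by
log density, seeds q parallel sequences with the top q points, and deals
the ranked array into q interleaved complexes (complex k takes ranks
q(j−1)+k).  Each complex then runs L Metropolis steps: the proposal is
Gaussian, centred on the sequence's current point with covariance
c_n²·Σ, where Σ is the complex's sample covariance and c_n = 2.4/√n is
the Gaussian-optimal jump rate; when the sequence's density has drifted
more than a factor T = 10⁶ below the complex's mean density the proposal
re-centres on the complex's best member.  Accepted candidates join the
sequence and replace the complex's worst member when they improve on it,
so the complex best is non-decreasing.  Out-of-box proposals get density
−∞ and are rejected, which keeps the chain stationary for the boxed
posterior (reflection would change the stationary law).  A NaN from the
density functional is treated as −∞ and logged.

If a sequence's acceptance rate over the L steps falls below
AR_min = 0.1 its proposal covariance is halved; if it exceeds 0.6 the
scale doubles back towards 1.  The recovery direction is our addition:
with L ≈ 10-step windows, rate estimates are noisy enough that one-way
halving accumulates and freezes the chains.

After each shuffle the complexes are merged and re-ranked and the
Gelman–Rubin potential scale reduction R̂ = √[(n−1)/n + B/(nW)] is
computed per parameter on the second half of each sequence (B/n is the
variance of chain means, W the mean within-chain variance; all-constant,
all-equal chains define R̂ = 1).  The run stops when every parameter has
R̂ below 1.2, with at least 15 shuffles enforced so the check cannot fire
on trivially short chains, and at most 50 shuffles.

Defaults are s = 200, q = 10, L = m = s/q, chosen for robustness: on the
deliberately over-wide default box (α ∈ (10⁻⁶, 1], β ∈ (10⁻⁶, 10]) the
posterior mode occupies a vanishingly small corner, and smaller
populations (s = 50, q = 5) missed it outright on roughly a third of
seeds.  At s = 200 the first run located the mode to within 0.03 log
units on every seed tried, at well under a second per run for the
24-week objective.

### ISCEM refinement

ISCEM reruns SCEM-UA while shrinking the box: after the first run the
upper bound moves to the incumbent best point; each subsequent run moves
the upper bound to its best point when the best density improved, and
otherwise raises the lower bound, stopping when successive best log
densities agree to a relative ε = 10⁻⁶ or after at most 12 runs.  Two
deliberate deviations from the literal scheme:

- **Padded bound updates.**  Setting a bound exactly at the incumbent
  places it on the new boundary; whenever the incumbent sits on the wrong
  side of the true optimum, the optimum is excluded from every later box
  and the final error is locked at the first run's error (observed as
  1–2 grid cells in α on ~40% of seeds).  Bound updates are therefore
  padded outward by 5% of the current box width, keeping the incumbent
  interior while preserving monotone shrinkage; terminal error dropped
  below ~0.1 grid cells of a 500×500 reference grid on every seed tried.
- **Global best.**  The returned sample is the highest-density point seen
  across all runs, not the last run's best, since a mis-shrunk box can
  make the final run's best worse than an earlier one.

Identical seeds give bitwise-identical results end to end; one
`numpy.random.Generator` seeded from `ScemConfig.seed` drives the whole
refinement, so the outer runs differ from each other but the ensemble is
reproducible.

With noiseless (synthetic) data SSE → 0 at the truth, the log density is
unbounded there, and the ε-agreement rule cannot fire; the refinement
then ends at the outer-run cap with the constants located to ~10⁻¹⁰
relative — the `converged` flag is false but the estimate is exact for
practical purposes.

### Posterior draws and intervals

Posterior draws attached to a fit are the post-burn-in sequence samples
of the **first** SCEM-UA run, the only run whose box is the full prior:
later boxes truncate the posterior by construction and would understate
uncertainty.  Forecast intervals are the 2.5/97.5 percentile envelope of
chained rollouts from these draws, reported as centre ± half-width, with
no additive observation-noise term.  These intervals are approximate and
lean conservative — the first-run chains mix over a huge box, so their
spread somewhat exceeds the posterior's; synthetic-data coverage of the
true constants ran above the nominal 95% in our replicates.  Interval
half-widths shrink towards zero as the posterior concentrates (verified
by tempering the density in the test suite).

## Fitting windows and per-subject application

Fits are specified by closed week windows on labels 0, S1 … S24; the
week preceding the window supplies the initial condition and its absence
is an error naming the missing week.  Predictions must start in the week
immediately after the fitted window.  Subject-level baselines (week-0
weights) are not published, so per-subject application back-solves the
initial weight from the subject's first observed week by inverting one
recursion step, f(0) = (f(1) − 7αl(1)(1−e))/e with e = erf(β); an
explicit numeric baseline can be supplied instead.  Exact reproduction of
the published per-subject model rows and interval table is out of scope
(their inputs and interval construction are not published); the published
per-subject R² values are instead verified directly against the printed
trajectories, which reproduce all 32 of them to ±0.001.

## A note on the S1–S12 constants

The constants this package estimates on the S1–S24 window agree with the
published ones to ~0.2% and with a brute-force 500×500 SSE grid to a
fraction of a grid cell.  On the S1–S12 window they do not: the
least-squares optimum is α ≈ 0.00961, β ≈ 1.7027 (SSE 0.23), whereas the
published pair α = 0.0170757, β = 1.7029 has SSE 2.13 on the same
objective — about nine times the minimum — and no natural variant we
tried (one-step-ahead SSE, L1, relative SSE, maximal squared correlation,
S1-anchored start) has its optimum near the published α.  The window is
all energy deficit, the decline nearly linear, and α — which anchors the
steady state — is only weakly identified, leaving a long flat valley in
the objective.  Strikingly, the in-window optimum forecasts S13–S24
poorly (R² ≈ −0.22) while the published, non-optimal constants forecast
well (0.94229): a textbook identifiability trade-off, discussed in
`examples/03_validate_and_predict.py`.  The package reports its own
optimum for this window and reproduces the published forecast R² by
plugging in the published constants, which is how that figure is defined.

## Synthetic data

The generator runs the deterministic recursion from known constants and
adds independent Gaussian noise to the observed weekly weights only — the
latent dynamics carry no process noise, matching the residual structure
the SSE objective assumes.  Schedules: constant intake, a linear ramp, or
`minnesota_like` (piecewise-linear interpolation of the packaged group's
net-intake column — a deep initial deficit relaxing into a growing
surplus).  The week-0 record carries the exact initial weight, mirroring
fitting practice where the baseline is treated as known.  Defaults (24
weeks, study-like schedule, 0.3 kg observation noise — about the
week-to-week wiggle of the group series) define the parameter-recovery
experiments: over 50 replicates the median relative error is ~2% for α
and ~0.1% for β.  What passing these tests shows is internal consistency
— the estimator recovers the generative constants under the model's own
assumptions; they say nothing about model adequacy for data with process
noise, intake measurement error, or individual heterogeneity, none of
which the generator emulates.

## Numerical choices and limitations

- Proposal covariances carry a tiny diagonal ridge (10⁻⁸ of the box
  width, squared) so collapsed complexes keep a valid Cholesky factor.
- SSE is floored at 10⁻³⁰⁰ before taking logs.
- Bound updates that would invert an interval leave that coordinate
  unchanged (logged); ε-agreement is tested on the log-density scale
  relative to max(1, |log p|).
- Week tokens are `0` or `S<k>`; windows are closed; series CSVs use the
  dialect `week, body_weight_kg, tee_kcal_day, intake_kcal_day,
  net_intake_kcal_day`, with net derived (and logged) when absent.
  Packaged fixtures are checksummed on load.
- The recursion is weekly; daily interpolation is deliberately not
  implemented.  TEE feedback on the recursion, multi-compartment
  partitioning of weight, and basal-metabolism prediction equations are
  out of scope; the model sees expenditure only through the precomputed
  net-intake column.
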