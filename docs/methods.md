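# Methods

This note records the models, algorithms, numerical conventions and
design choices behind `naturegait`, and what the synthetic-data tests do
and do not establish about real recordings.

## The experimental design being modelled

Participants repeatedly walk a 12 m capture space toward a projected
image while performing a cognitive task (memorising the image, or rating
its visual discomfort afterwards). Each of the 105 trials shows one of
50 nature images, 50 urban images, or 5 blank controls; the nature and
urban images come in pairs matched for a liking score obtained from an
independent norming sample (scores between 2.82 and 5.61 on a 7-point
scale). The scientific question is whether environment type still
predicts gait once likeability is controlled; the package's statistical
machinery exists to answer exactly that kind of question on a
trial-by-trial basis.

## Gait kinematics

**Coordinate convention.** X lateral, Y direction of travel, Z vertical;
metres and seconds throughout. Required markers: hip, left foot, right
foot, uniformly sampled (100 Hz by default).

**Low-pass filter.** Hip and foot coordinates are filtered with a
zero-phase second-order Butterworth low-pass at 5 Hz applied forward and
backward, i.e. with squared magnitude 1/(1 + (f/f_c)^4) and zero phase.
The default implementation applies this response directly in the
frequency domain on a mirror-padded signal rather than running a
bilinear-design recursion twice: the frequency-domain form realises the
analytic forward+backward magnitude exactly at every frequency (a
sampled-time recursion designed by the bilinear transform deviates from
the analytic curve away from the cut-off — at 20 Hz on 100 Hz data it
attenuates to 0.0023 instead of the analytic 0.0039). A classical
`filtfilt` variant is available via `method="filtfilt"`. DC gain is
exactly 1, so constant signals pass untouched; trajectories shorter than
three warm-up lengths (3·f_s/f_c samples) are rejected with the minimum
stated.

**Truncation.** Samples are kept while the hip's Y position lies in
[Y_first + 0.5 m, Y_max − 2.0 m]; with a 12 m capture this leaves 9.5 m
of near-constant-speed walking. The walkway origin is taken from the
data itself (first retained hip sample), so no lab-frame calibration is
needed. A truncated trajectory carries a marker in its metadata and a
second truncation is a no-op — the window is defined relative to the
*original* capture, not to whatever segment happens to be in hand.

**Stance detection.** For each foot, a sample qualifies as stationary
when the marker's 3D displacement across a centred 0.1 s window is below
5 cm (a Y-only criterion is available by switch). Maximal runs of
qualifying samples form stationary periods; runs shorter than 0.15 s
(configurable) are discarded as swing-reversal artefacts — the window
criterion alone can briefly qualify samples at the turning point of the
swing. Samples within half a window of the trajectory ends cannot be
certified and count as moving. Each period yields one step event at the
marker position of its middle sample. The landing time is the minimum of
the signed Y acceleration (second-order central difference of the
filtered position; ties broken toward the earlier time) between the
previous period's end and the period's start — the maximal deceleration
of the incoming swing; the lifting time is the maximum Y acceleration
between the period's end and the next period's start.

**Step adjacency by position.** Step lengths, same-foot checks and the
1.3 m rule use events ordered by Y position — the physical footfall
order of a straight forward walk — not by landing time. Stances cut by
the analysis window have no observable preceding swing, so their landing
times are undefined (estimated from whatever samples remain) and can
invert with a neighbouring event; position ordering is immune to this.
This is the same reason the first and last event of each foot are
removed before parametrisation: their lifting/landing references fall
outside the truncated window. Stride times are landing-to-landing
intervals within a foot over the remaining (interior, hence reliable)
events.

**Per-trial summaries.** Step length is the Y advance from the
immediately preceding opposite-foot event; velocity is the hip's net Y
displacement over the truncated window divided by elapsed time (3D path
length by option); variability is the per-trial sample SD (ddof = 1) of
step lengths and stride times. Walking-inconsistency flags: any NaN in a
required marker (`missing_markers`; no interpolation is attempted), any
step over 1.3 m (`overlong_step`), adjacent events of the same foot
(`same_foot_repeat`), fewer than three usable events for a foot
(`too_few_steps`). Flagged trials are excluded from modelling.

## Box-counting fractal dimension

Colour images are collapsed to luminance (ITU-R BT.601 weights),
min-max normalised to [0, 1], and binarized with foreground strictly
above the image mean (an `invert` option covers the opposite
convention); a constant image has no separating threshold and is
rejected. For each box size s the raster is tiled from the top-left with
s×s boxes, partial boxes at the right/bottom edges included, and the
number of boxes containing foreground is counted. The dimension is the
OLS slope of log(count) on log(1/s); at least three sizes are required
and the fit's R² is reported. Default sizes are powers of two from 2 to
min(dim)/4; exact self-similar fixtures (Sierpinski carpet) use powers
of three. On analytic sets the estimator is exact to machine precision
(carpet: log 8/log 3; triangle: log 3/log 2; plane: 2; line: 1), which
is what the test suite pins.

## Cross-classified multilevel model

**Model.** Standardized velocity for trial t of participant j(t) viewing
image k(t):

    z_t = x_t'β + u_{j(t)} + v_{k(t)} + e_t,
    u_j ~ N(0, σ²_u), v_k ~ N(0, σ²_v), e_t ~ N(0, σ²_e).

Priors are deliberately diffuse: β ~ N(0, 10⁶) per coefficient and
inverse-Gamma(0.001, 0.001) on each variance component — the convention
of the multilevel-modelling software family this analysis style comes
from. All full conditionals are conjugate; the sampler cycles exact
draws of β (joint multivariate normal via Cholesky), u, v (vectorised
per-group normals), and the three variances (inverse-Gamma).

**Translation moves.** The likelihood identifies only the sum
intercept + mean(u) + mean(v), so the plain cycle leaves the intercept
random-walking against the random-effect means (effective sample sizes
of a few). After the u and v updates the sampler therefore draws a
location shift between the intercept and each random-effect vector from
its exact conditional (a generalized Gibbs move on the translation
group) and applies it; this is the standard remedy and raises the
intercept's effective sample size by two to three orders of magnitude
without changing the posterior.

**Determinism and exchangeability.** Rows are sorted by (participant,
image, outcome, covariates) before index arrays are built, so a fixed
seed gives bit-identical posterior summaries under any input row order.
Initialization is deterministic: OLS for β, zeros for u and v,
method-of-moments variance split.

**Summaries.** Fixed effects report the posterior mean, posterior SD
(used as the standard error), central 95% percentile interval, Wald
X²₁ = (mean/SD)² with its χ²₁ p-value; variance components report
posterior means, SDs and intervals. Convergence is monitored with a
crude initial-positive-sequence effective sample size and a Geweke z per
parameter; ESS below 200 warns but does not fail, since screening
decisions rest on well-mixed quantities.

**DIC.** The conditional-deviance convention: D(θ) = −2 log N(z | Xβ +
u + v, σ²_e) evaluated at each stored draw; pD = D̄ − D(θ̄) with θ̄ the
posterior means of (β, u, v, σ²_e); DIC = D̄ + pD. This matches the
convention of the MCMC multilevel software whose output style the
summaries mirror. DIC can be negative when σ²_e is small; only
differences are meaningful.

**Staged selection.** Model 1 is the random-intercepts null. Stage 1
enters all candidates jointly, discards terms with Wald p ≥ .05, and
refits (model 2a; equal to model 1 when nothing survives). Stage 2
augments the survivors with their pairwise interactions against every
other candidate (products of the already-coded columns, no re-centring;
unordered duplicates and rank-deficient additions are skipped), screens
and refits (model 3a). The best model is the lowest-DIC stage winner,
ties to the fewer-terms model. Because each discard decision is an
α = .05 test, the procedure carries the usual type-I exposure: with
three null candidates in play, the "true" single-predictor model is
selected in roughly 0.95³ ≈ 86% of replicates at stage 1, less after
stage 2 — the selection tests are therefore framed as seeded majorities,
not certainties.

**Design preparation.** Control trials are excluded (they have no liking
or fractal values), QC-flagged trials dropped, environment coded
nature = 0 / urban = 1 and task memory = 0 / discomfort = 1, continuous
covariates and the velocity outcome z-scored over the included rows,
and rows with missing required covariates dropped with a logged count.

One scale subtlety: the generator's latent standardized velocity has
total variance σ²_u + σ²_v + σ²_e + β²  ≈ 1.06 at the default values, so
re-z-scoring a measured velocity divides every variance component by
that factor. Significance screening and DIC ranking are invariant to
this affine rescaling, but parameter-recovery checks must compare like
with like — they fit the generator's latent column directly.

## Synthetic-data generator

The generator is the package's study stand-in; its defaults are the
study's design values, not tuning knobs.

* **Images.** Pair liking uniform on [2.82, 5.61], members jittered
  within a 0.1 pairing tolerance (0.02 by default, zero for exact
  pairing); per-image mean discomfort from a bivariate-normal
  construction with liking at r = −0.497 (location 2.85, scale 0.84,
  clipped to the 7-point scale); per-environment fractal dimensions
  N(1.65, 0.13) for nature and N(1.59, 0.14) for urban, clipped to
  [1, 2]. Controls carry no scores.
* **Trials.** One trial per participant × image; the latent outcome
  follows the cross-classified model above with configurable effects for
  liking (default 0.016), environment, task, fractal dimension and
  per-trial discomfort (defaults 0 — the study's null findings); control
  trials get a +0.05 SD speed offset (control walks were faster) and are
  dropped at design preparation. Latent z maps to physical velocity as
  1.25 + 0.12·z m/s — typical adult self-paced walking; step length is a
  per-participant ratio (N(0.56, 0.02) s/2, clipped) times velocity, and
  stride time follows from v = 2L/T exactly.
* **Trajectories.** The hip advances at the trial velocity with a small
  (5 mm) sinusoidal surge at step frequency; feet alternate stance
  (stationary, ≥ 0.3 s) and swing phases, same-foot placements 2L apart,
  swings following a minimum-jerk profile — chosen because it has a
  single acceleration maximum and minimum per swing, making
  landing/lifting definitions unambiguous on clean data. Swing occupies
  38% of the stride. Isotropic Gaussian noise of SD 1 mm (the capture
  calibration accuracy) is added to every sample. Ground-truth stance
  schedules travel in the trajectory metadata for round-trip tests.
* **Fault injection.** For QC testing only, and refused otherwise:
  `overlong_step` shifts the remainder of the walk forward so exactly
  one step measures 1.35 m; `same_foot_repeat` deletes one mid-trial
  stance of the right foot (the foot rests through a full extra stride,
  producing two adjacent left events); `missing_markers` blanks 0.3 s of
  one foot.

**What the generator does not emulate:** marker occlusion and relabelling
errors, soft-tissue artefact, curved or hesitant walking, speed drift
within a trial, skewed or heteroscedastic trial noise, and any visual
content of the stimuli (fractal dimensions are drawn, not computed from
scenes). Passing round-trip tests therefore establishes the correctness
of the algorithms under the stated model of walking, not robustness to
every artefact of real capture sessions.

## Cohort exclusions

A participant is excluded when under 80% of their trials have complete
hip+feet marker data, or (memory task only) when recognition accuracy in
the post-walk compliance check falls below 62%; the recognition task
itself is behavioural and is taken as an input column, not recomputed.
Participant-level exclusion runs first, trial-level QC second, and both
are itemised in the exclusion log; the run manifest records row counts
at every step so rows_in = rows_retained + rows_excluded is checkable.

## Problem sizes and tolerances used by the test suite

Chosen to exercise each claim at study scale while keeping the default
suite around a minute of CPU:

* Gait round-trips: 50 trials at 1 mm noise, 1% recovery tolerance;
  fault sensitivity on 5 constructed trials per fault type.
* Filter oracle: 30 s probes at 1 and 20 Hz, gains within 1% of the
  analytic values (0.9984, 0.0039).
* Fractal oracles: exact counts on the depth-4 carpet; dimensions within
  0.05 of the analytic values.
* Parameter recovery: 20 replicates of the full 44 × 100 design at the
  reported generating values, chain 2,000 after 500 burn-in (scaled down
  from the 10,000-draw default); ≥ 85% coverage of 95% credible
  intervals for the liking effect, participant variance and trial
  variance. The OLS-equivalence oracle uses group-orthogonal covariates
  (alternating demeaning across the two classifications), where the
  mixed-model and OLS estimands coincide exactly, and a 30,000-draw
  chain so Monte Carlo error sits below the 1%-of-SE bar; with
  arbitrary covariates the two estimands differ by design (partial
  pooling absorbs group-mean components), which is a property of the
  model, not a sampler defect.
* Headline selection: liking retained and environment discarded in
  ≥ 90% of 20 replicates at a clearly detectable liking effect (0.04,
  about 5.7 SEs at this design size — at the study's reported 0.016 the
  Wald power is only ≈ 0.63, so retention frequency would measure power,
  not selection correctness); discomfort-only selection in a clear
  majority of 10 replicates when per-trial discomfort (−0.054) drives
  velocity and liking only correlates with it.

## Known limitations

* The sampler covers exactly one model family: Gaussian outcome, two
  crossed random intercepts, fixed effects with optional pairwise
  products. No random slopes, non-Gaussian links, or deeper nesting.
* DIC is computed under one (conditional) focus; other deviance foci
  give different pD and are not offered.
* The stationary-period criterion detects stance only for reasonably
  steady forward walking; it is not a general-purpose gait-event
  detector for pathological or treadmill gait.
* Trajectory files are TSV only; binary capture formats must be
  exported to TSV upstream.
* Box counting operates on binarized images; grayscale (differential)
  box counting and spectral image statistics are out of scope.
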