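# Methods

## Psychometric model

All procedures share one detection model: a lapse-corrected Weibull over
stimulus intensity x,

    psi(x) = gamma + (1 - gamma - lapse) * (1 - exp(-(x / alpha)^beta)).

`alpha` is the position parameter — the intensity at which the
guess-free, lapse-free curve reaches 1 − 1/e ≈ 63% detection, the
conventional Weibull threshold. `beta` sets the slope, `gamma` the lower
asymptote, and `lapse` the rate of attention lapses that compress the
upper asymptote to 1 − lapse. For yes/no phosphene detection we fix
gamma = 0 (participants are instructed to answer "no" when unsure, so
false alarms are modelled away) and lapse = 0.04; the 2AFC validation
observer uses gamma = 0.5 and lapse = 0.02.

With lapse = 0.04 and gamma = 0, psi(alpha) = 0.96·(1 − 1/e) ≈ 0.607.
We define the reported threshold as the exact 60% crossing of the
fitted lapse-corrected curve, `threshold_at_accuracy(0.60, params)`, so
"the threshold corresponds to 60% accuracy" holds by construction. Note
the ~0.7-point ambiguity between this convention and simply reporting
alpha itself (≈ 60.7% accuracy); we chose the exact crossing and state
it here because the two differ slightly whenever beta is finite. A
post-hoc 50% threshold is computed from the same fitted (alpha, beta);
it inherits the slope estimate, which is poorly constrained by 30
trials, so the 60% readout is the one to trust.

## The Ψ staircase

The staircase holds a discrete posterior over (alpha, beta) pairs:

* alpha grid: 1..100 step 1 %MSO (the full intensity range the
  stimulator accepts);
* beta grid: 10 log-spaced values in [0.5, 20] — spanning very shallow
  to near-step psychometric functions;
* stimulus grid: integers 1..100 %MSO;
* prior: uniform over the grid (no published prior to reproduce, and a
  uniform prior makes the procedure's behaviour easy to audit);
* likelihoods precomputed once per configuration and clipped to
  (1e−12, 1 − 1e−12) so a Bayes update can never annihilate the
  posterior.

Each trial evaluates, for every candidate intensity x, the expected
posterior entropy

    E[H | x] = P(seen | x) H(posterior | seen) + P(unseen | x) H(posterior | unseen)

in natural log (the argmin is base-invariant) and delivers the argmin.
Exact ties go to the lowest intensity — a deliberate, documented rule
(lower intensities are more comfortable) that fixes the trial sequence
bit-for-bit. The run terminates after exactly 30 trials; dynamic
termination criteria are out of scope. Point estimates are the marginal
posterior means of alpha and beta (the mode is rejected: it snaps to
grid nodes), reported continuous even though delivered intensities are
integers; the threshold is clamped to the stimulus range in the
degenerate all-seen/never-seen corners.

For the 2AFC precision configuration (`PsiConfig.two_afc_validation`)
the axes are log-spaced over a 40 dB contrast range (0.01–1, 41 nodes,
~1 dB spacing; beta 1–16) and the point estimate is the posterior mean
of log alpha (geometric mean). On a log-spaced grid the geometric mean
is the natural marginal mean, and it matches the dB scale on which
staircase precision is conventionally quoted.

## MOBS

The modified binary search is specified in the literature it is cited
from rather than by published pseudocode, and circulating
implementations differ in small details; this is the two-stack variant,
"as cited, not as copied":

* boundary stacks initialised to [1] and [100] %MSO; the tested
  intensity is always the midpoint of the stack tops, rounded half-up to
  an integer;
* "seen" pushes the tested intensity as a new upper boundary, "not
  seen" as a new lower boundary;
* every response that repeats the previous one pops the *opposite*
  stack one level (never past its base element) — the retreat rule that
  lets the bracket recover from response errors;
* a reversal is a change of response category between consecutive
  trials; the first response can never be one;
* termination at six reversals; the estimate is the midpoint pending at
  termination (the ~50% point bisection converges on). Alternative
  readouts (e.g. averaging the last reversal intensities) exist in the
  wild; the pending midpoint is the choice here and is what the tests
  pin down.
* a hard cap of 100 trials guarantees termination against pathological
  responders (e.g. one who never reports a phosphene).

Half-up rounding breaks exact mirror symmetry of runs reflected about
50.5 by at most one integer step per bisection level; the test suite
checks exact symmetry on unrounded midpoints and bounds the integer
drift.

## MOCS

Seven integer levels at 5 %MSO spacing, centred on a pilot threshold
(in practice a Ψ or MOBS estimate), each presented 25 times (20–30 is
the accepted range) in a seeded random permutation. A window that would
overhang [1, 100] is shifted inside the range rather than clipped
element-wise — clipping would collapse duplicate boundary levels and
destroy the design. Fitting maximises the binomial log-likelihood over
(log alpha, log beta) with gamma and lapse fixed at the same values the
staircase uses (the asymmetric alternative — freeing the lapse — is a
known ambiguity; fixing it keeps the two procedures' thresholds
commensurable). The optimiser is Nelder–Mead from 10 starts (5 alpha
values spread over the sampled range × 2 slopes) because the likelihood
has flat shoulders when the data do not bracket the threshold; all-seen
or all-unseen data raise a non-identifiability error rather than
returning an extrapolated threshold. Parametric bootstrap (default 400
resamples) redraws binomial counts from the fitted curve at the design's
levels and counts, refits, and reports the SD of the refitted 60% and
50% thresholds; more than 20% failed refits marks the fit unstable.

## Simulated observers

An observer is a Bernoulli responder: seen with probability psi(x) from
its own (known) parameters, drawn from a per-observer seeded generator,
so identical seeds and stimulus sequences reproduce identical response
streams. Panels draw alpha uniform in [40, 80] %MSO and beta log-uniform
in [4, 16] — plausible brackets for human phosphene psychometric
functions, not values extracted from any dataset. The simulator models
stationary, independent trials only: no criterion drift, adaptation,
fatigue, or serial dependence. Passing tests therefore demonstrate the
procedures' statistical behaviour under a well-specified observer, not
robustness to the nonstationarities of real participants.

## Sessions, safety, replay

Hardware is abstracted to a three-method contract (set intensity, arm,
trigger) with an in-memory mock; the real serial protocol is an
extension point, deliberately unimplemented. A sequencer in front of the
device refuses any pulse requested before the minimum inter-pulse
interval has elapsed; refused pulses never reach the device and never
reset the interval clock. Sessions are participant-paced: the next pulse
is requested one full interval after the response, so the pulse-to-pulse
gap is interval + response latency. With the defaults (2.5 s interval,
0.4 s simulated latency) a 30-trial run averages ≈ 0.355 Hz; slow mode
(6 s) gives ≈ 0.16 Hz. Simulated sessions run on a virtual clock — no
sleeping — while producing realistic timestamps. A session log stores
the procedure, a full config snapshot, the observer spec, per-trial
records (with posterior entropy for Ψ runs) and the result block as
CSV + JSON; replay re-runs the logged config against the logged
responses and raises on any divergence of the intensity sequence or
threshold.

## Validation study

For each observer on a panel: four Ψ runs, four MOBS runs, one MOCS
session (its levels centred on the mean Ψ estimate, mirroring how a
pilot threshold guides the design in practice), all seeded from one
spawning generator. Accuracy is |mean-of-4 − truth| with truth both the
observer's analytic 60% point (available only in silico) and the MOCS
fit (the proxy a human study must use); reliability is the SD over the
four runs; cost is trial counts — wall-clock durations are excluded as
hardware-dependent. Only the direction of the effects (Ψ more accurate
and more repeatable than MOBS, fixed 30 trials vs variable) is a
reproduction target; magnitudes from human panels depend on the
observers and are not comparable.

## Numerical choices and problem sizes

* Posterior normalization is enforced to 1e−10 after every update.
* Entropy uses xlogy so empty cells contribute exactly zero.
* The bisection/brute-force oracles in the tests are independent
  reimplementations (double loops, dense grid search, float-midpoint
  traces), kept deliberately naive.
* Test and acceptance problem sizes — 200 observers for parameter
  recovery, 200 runs for the 2AFC precision study, 5 panel seeds × 6
  observers for the direction-of-effect check — were chosen as the
  smallest sizes at which the statistics of interest are stable; the
  acceptance script completes in seconds on one core.

## Known limitations

* The original Matlab grids, prior, and Excel MOBS rules are not
  published; the choices above are documented defaults, not
  reproductions.
* The lapse rate is fixed, never estimated online.
* No interactive-hardware path is tested end to end (no hardware); the
  keyboard responder exercises the same code path as simulated
  observers.
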