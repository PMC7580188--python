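# Methods

## The problem

The notched-noise method estimates the shape of the auditory filter at a
centre frequency by measuring the masker level at which a pure tone becomes
just detectable, as a function of the width and asymmetry of a spectral
notch in the masker.  Classical adaptive procedures need roughly two hours
per centre frequency, which keeps the method out of clinical use.  This
package implements and evaluates, entirely in simulation, an active-learning
variant: nine Gaussian-process (GP) classifiers — one per notch condition —
model the probability of a Yes response over the (frequency, masker-level)
plane, and each trial presents the stimulus carrying the most information
about that model.  One run yields thresholds continuously over 500–4000 Hz
for all nine notch conditions in 594 trials, from which two-slope rounded
exponential (roex) filters are fitted at every 0.1-octave node.

## Response model

A trial is a Yes/No detection of a tone at frequency f_s and level
L_s = 15 dB SL inside two noise bands of width 0.4 f_s whose inner edges sit
at offsets (delta_l | delta_u)·f_s from the tone.  The notch battery is the
standard nine-condition set (0|0) … (0.4|0.2).  The masker spectrum level
L_m is the adaptive variable, bounded below at −30 dB SPL and above by the
requirement that the overall two-band level not exceed 95 dB SPL, i.e.
L_max(f) = 95 − 10·log10(0.8 f).

The virtual listener answers Yes with probability

    p(yes | L_m) = lambda + (1 − 2 lambda) · Phi((T − L_m) / sigma)

with lapse rate lambda = 0.01, psychometric SD sigma = 3 dB, and T the
ground-truth threshold from the roex forward model (below).  Catch trials
(masker only) elicit a false alarm with probability 0.01.  For the
forced-choice comparator, the tone is heard with probability
Phi((T − L_m)/sigma) and unheard tones are guessed at 1/2; lapses are not
applied on the heard branch, matching the two-output error-channel model
used in the task-information analysis.

## GP model

Per notch condition, the latent detectability f(x) over
x = (log2(f_s/1 kHz), L_m) has

- a constant mean m, the only hyperparameter optimized during the run
  (approximate marginal likelihood, derivative-free bounded search on
  [−20, 20] latent units, restarted from scratch each trial);
- an additive kernel: squared-exponential in log-frequency with a fixed
  0.5-octave length scale and amplitude 5 latent units (≈15 dB of prior
  threshold variability across frequency), plus a homogeneous linear term
  in level, L·L′/3², so a unit latent change corresponds to 3 dB and the
  induced psychometric function has SD 3 dB;
- the lapse likelihood p(yes|f) = 0.01 + 0.98·Phi(f), flooring predictions
  at 1% and 99%.

Inference is expectation propagation.  Because the lapse likelihood is
affine in the probit, the tilted moments have closed form; sites are
updated in parallel with damping 0.8 (rescue passes at 0.4 and 0.15), and
site precisions may go negative — the lapse floor makes exact posteriors
heavier-tailed than the prior, and clamping precisions positive would
forbid the variance inflation needed to track them.  When EP finds no
stable fixed point (it provably may for this non-log-concave likelihood,
e.g. conflicting labels at near-duplicate points), Laplace's method is the
fallback; its Newton iteration starts inside |f| ≤ 3 because the likelihood
is flat at large |f| and a mode search started on the plateau cannot move.

Two properties of any Gaussian approximation here are worth knowing when
reading the tests.  First, EP's latent moments track brute-force quadrature
of the exact posterior to within a few percent, but predictive
*probabilities* in the tails can deviate by a few hundredths because the
exact posterior is skewed — the error is the Gaussian projection, not the
EP machinery.  Second, Laplace and EP disagree by up to ~0.2 in predictive
probability at the operating prior amplitude (the familiar Laplace
shrinkage); the two agree to 0.05 only at unit-scale priors.  Both effects
are asserted at honest tolerances in the suite.

A post-hoc psychometric-slope estimate is provided by rescaling the
level-to-latent divisor and maximizing the same approximate evidence; on
simulated 3-dB listeners it lands near 2.3–3 dB.

One behaviour of the ML-II mean deserves note: with the lapse floor, the
evidence often keeps increasing toward the +20 bound on sparse early data
(a large mean with a compensating slope emulates a steeper psychometric
function whose wrong-side responses are absorbed by the floor at modest
cost).  The bounded search contains this; threshold extraction is
unaffected because the 50% level is set by the zero crossing of the latent
mean, which the slope still places correctly.

## Acquisition

The informativeness of a candidate x is the mutual information between the
next binary response and the latent,

    I(x) = H_b(p̄) − E_{f ~ N(mu, sigma²)} [ H_b(0.01 + 0.98 Phi(f)) ],

with p̄ the probit-averaged predictive probability.  Candidates live on a
1-dB × 0.1-octave grid per notch; the next stimulus is the global argmax
over the nine grids with a deterministic tie-break (lowest notch index,
then frequency, then level).  The conditional-entropy expectation has no
closed form; it is evaluated by splitting off the closed-form tail
expectation (the integrand tends to H_b(0.01) in both tails, with
E[Phi(f)] = Phi(mu/sqrt(1+sigma²))) and integrating the localized remainder
by 64-node Gauss–Legendre quadrature on the window where it is
non-negligible.  This is uniformly accurate to ~2×10⁻¹⁰ bits; plain
Gauss–Hermite needs hundreds of nodes at large variance because the
remainder is much narrower than the Gaussian, and was therefore not used.

## Run protocol

Each notch condition is warmed up by a fixed rule: (a) 1 kHz from
−20 dB SPL, +20 dB after Yes / −10 dB after No (floor −30) until both
responses occur; (b) one trial at 2 kHz at the mean of the last two 1-kHz
levels; (c) the highest test frequency, starting ±10 dB from the 2-kHz
level by its response, stepping ±10 dB until both responses occur;
(d) 500 Hz analogously, starting at the 2-kHz level.  Warm-up trials count
toward the signal budget (540 total = 60 per notch, so the default run is
594 trials including 54 catch trials; the single-notch retest is 66 = 60+6).
Catch slots are placed uniformly at random within the active phase; a catch
trial presents the currently selected stimulus without the signal, and its
response does not enter any GP (configurable).  Per signal trial only the
GP that received the new datum is re-optimized, refit and rescored.

Thresholds are read off each final GP as the level where the latent
predictive mean crosses zero (p = 0.5) on the 1-dB grid, linearly
interpolated, taking the highest-level crossing if there are several.  If
the latent is still positive at the top of the level range the node is
flagged "all-above" rather than reported — the homogeneous linear kernel
pivots at L = 0 and can fabricate a spurious low-level crossing for
listeners who detect through the loudest admissible masker, so the flag is
keyed to detection persisting at the cap.

## Roex filter model and fitting

The filter weight is W(g) = (1 + p g) e^{−p g} on the normalized offset
g = |f − f_c|/f_c, with separate slopes p_l and p_u below and above the
tip.  Band integrals use the exact antiderivative −(g + 2/p)e^{−p g},
integrated over the noise bands only (the two-slope model has no tail).
The masked threshold is

    N_0 = L_s − K_db − 10 log10( f_s (I_l + I_u) )

with K_db = 10 log10 K the efficiency.  Fitting minimizes dB residuals over
(p_l, p_u, K_db) by bounded least squares from a 3×3 multi-start grid
(p ∈ {10, 20, 40} per side), bounds p ∈ (1, 200).  The (0.4|0.4) condition
is excluded, as the tail-free model mispredicts it.  Each 0.1-octave node
is fitted independently (no smoothing across frequency).  The summary
bandwidth is ERB = (2/p_l + 2/p_u)·f_c.

## Virtual listeners

Profiles hold an audiogram (piecewise-linear in log-frequency), roex slopes
p_l(f), p_u(f), efficiency K_db, and the response parameters above.  Presets:
`normal` (10 dB SPL flat, p = 30 — ERB ≈ 13% of f_c), `flat_loss`
(40 dB SPL flat) and `sloping_loss` (15 → 60 dB SPL over 0.5–4 kHz).
Hearing loss degrades both slopes linearly, 1.2% of the normal value per dB
of threshold elevation, floored at 25% — a coarse but monotone stand-in for
the loss of cochlear sharpness with outer-hair-cell damage.  K_db defaults
to 1 dB.  Ground-truth thresholds come from the same roex family that is
later fitted, which is what makes exact parameter-recovery tests possible;
an optional smooth sinusoidal threshold perturbation per notch
("model-mismatch" listener) probes robustness to listeners outside that
family.  What passing recovery tests therefore demonstrate is internal
consistency of the whole chain (sampling → GP → threshold → fit) under the
stated response model, not fidelity to any real ear: real listeners have
off-frequency listening, level-dependent filters and non-Gaussian
psychometric tails that the generator deliberately omits.

## Staircase comparator

The 2I-2AFC 2-up/1-down track raises the masker after two consecutive
correct responses and lowers it after any error: 5-dB steps until the
second reversal, 3 dB until the fourth, 1 dB thereafter; termination at the
tenth reversal; threshold = mean level of the last four reversals.  This
converges to the 70.7%-correct point, which for the composed guessing
channel ((1+p_h)/2 = 0.707 ⇒ p_h = 0.414) sits 0.65 dB above the 50%
threshold for a 3-dB-SD listener — the Monte-Carlo acceptance check.
The start level defaults to 10 dB below the listener's true threshold
(an audible start; the choice is a package default, not inferred from any
source).  A two-run-averaging wrapper mirrors the protocol used when
staircase thresholds feed filter fits.

## Task information

A Yes/No trial carries at most 1 bit, scaled by (1 − catch fraction) when
catch trials are interleaved.  An n-interval forced choice is modelled as a
binary channel whose input is "tone heard": heard → correct; unheard →
correct with probability 1/n.  Then
I(p_h) = H_b(p_h + (1−p_h)/n) − (1−p_h)·H_b(1/n), maximized in closed form
via log2((1−c)/c) = −H_b(1/n)/(1−1/n); a 1e-4 grid search provides the
independent route.  Capacities: 0.32 bits at p_h = 0.60 (n = 2), 0.47 bits
at p_h = 0.58 (n = 3) — the quantitative argument for preferring the Yes/No
task in an adaptive test.

## Convergence reporting

Filter-width convergence is summarized by the fold ratio
r′ = max(r, 1/r) of the ERB estimate at a trial checkpoint to a reference
(the run's own final estimate, or the simulated ground truth), aggregated
geometrically across frequency nodes, runs and listeners jointly.
Checkpoints default to every 10 signal trials per notch (the curve is
identical at finer strides, only denser).  Unfittable early checkpoints are
excluded and counted.

## Problem sizes and numerical choices

Default study conditions: nine notches, 60 signal trials per notch, 10%
catch trials, 500–4000 Hz at 0.1-octave resolution, 1-dB level grid.  The
test suite runs reduced batteries (single-notch and five-notch configs,
10–60 trials per notch, 10–20 seeds) chosen as the smallest sizes at which
the monitored statistics are stable; the end-to-end recovery check uses ten
full 594-trial runs.  EP: damping 0.8, tolerance 1e-4 on site-parameter
changes, 60 sweeps before rescue passes.  Kernel jitter 1e-10.  Mean
optimization tolerance 0.01 latent units.  Roex fits use scipy's bounded
trust-region least squares.  All randomness flows from one
numpy Generator seeded per run; identical config + seed reproduces logs,
surfaces and fits byte-for-byte (CSV reading uses round-trip float parsing
for the same reason).

## Known limitations

- Thresholds above the admissible level range are flagged, not estimated;
  profiles with severe loss near 4 kHz produce flagged high-frequency nodes.
- The ML-II constant mean often rests at its +20 bound (see above); the
  bound is part of the model specification and results are insensitive to
  it, but the mean value itself should not be interpreted.
- The upper slope p_u is poorly identified when the lower slope is very
  shallow; fits at the p-bounds are flagged `at_bound`.
- Simulated test–retest and staircase-vs-active-learning differences are
  reported as descriptive statistics only; they are not comparable to
  human-subject values, which include criterion shifts and learning effects
  the generator does not model.
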