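# Methods

`satkit` is a desk-scale model of an automated homecage sensory-association
training (SAT) system for freely-moving mice: a multiwhisker air-puff
stimulus is paired with a water reward on self-initiated trials, and
learning is read out as anticipatory licking in the 300 ms before scheduled
reward delivery. The package contains (i) a discrete-event simulator of the
trial controller, (ii) a parametric synthetic mouse, (iii) the
anticipatory-licking analysis pipeline, (iv) a whisker motion-energy and
whisking-bout analysis, and (v) the cohort-level statistics. This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the apparatus or analysis left the behavior
under-specified.

## Trial controller

A session is an event loop over agent-proposed nosepokes. A poke registers
at the next tick of the 100 ms sensor poll; it starts a trial only if the
lockout from the previous trial has elapsed. An accepted trial:

1. draws a trial type — stimulus+reward with probability
   `reward_probability` (default 0.8; 0.5 in reduced-contingency mode),
   otherwise blank (detection mode) or an unrewarded-direction puff
   (discrimination mode). Assignment is i.i.d. Bernoulli per trial, with no
   balancing blocks;
2. draws a random pre-stimulus delay uniform on [200, 800] ms (integer ms),
   which decouples the stimulus from the operant cue of the nosepoke;
3. schedules the actuation chain at exact millisecond times: 500 ms air
   puff, 500 ms gap, 75 ms water valve opening (15 μL at the default
   0.2 μL/ms calibration), 925 ms post-water break;
4. enforces a lockout of 2000 ms from puff onset before the next trial —
   the controller applies the maximum of the nominal lockout and, on
   rewarded trials, the actuation chain plus post-water break (equal, by
   construction, at the defaults).

**Blank-trial timeline.** Whether blank trials run the same internal
schedule is an apparatus detail the log format must decide. Here blank
trials sample a delay and define a *virtual* puff onset at init + delay, at
which a sham relay clicks (masking the solenoid's auditory cue) and nothing
is delivered. The virtual onset anchors lick alignment and keeps pacing
identical across trial types; the convention is recorded in every log
header.

**Time base and quantization.** All times are integer milliseconds.
Actuation events are exact; sensor events (nosepokes, licks) are stamped at
the first 100 ms poll *at or after* the physical event — a polled sensor
cannot report an event before it occurs. The direction of this rounding
matters: stamping at the preceding grid point would let consummatory licks
(which begin at water onset) drift backward into the anticipatory scoring
window on rewarded trials only, producing a spurious ~0.8 Hz performance
bias in non-learning agents. With forward stamping the null is mean-zero.

**Seeding.** One root seed per session spawns three independent child
streams (trial type, delay, agent), so perturbing agent parameters never
reorders the trial-type or delay sequences. Replaying a seed reproduces
the log bit-for-bit.

## Synthetic mouse

The agent is phenomenological: it reproduces the behavioral regularities
the readout is designed to detect, with no claim that its update rule is
the animal's learning mechanism.

- **Learning rule:** exponential approach. Each *detected, rewarded*
  pairing updates the association strength `a ← a + λ(1 − a)` (default
  λ = 0.01), the simplest monotone rule with an asymptote; after n pairings
  `a = 1 − (1 − λ)^n`.
- **Anticipatory rate:** on stimulus trials,
  `[r_base + a (r_asym − r_base)] · [1 − s·exp(−k/τ)]` where k counts
  trials experienced; on blank trials, `r_base`. Defaults r_base = 1 Hz,
  r_asym = 8 Hz, novelty suppression s = 0.5 with τ = 100 trials. The
  multiplicative novelty term puts the naive stimulus-trial rate *below*
  baseline, reproducing the early-training dip in which blank trials
  out-lick stimulus trials before habituation.
- **Lick emission:** an inhomogeneous Poisson process over a
  piecewise-constant profile — baseline from poke to (virtual) onset,
  anticipatory rate from onset to scheduled reward time, consummatory rate
  (8 Hz) after water — then sensor-quantized. Between trials the animal is
  away from the port and emits no port licks. An undetected puff produces
  baseline licking: the animal cannot anticipate a stimulus it did not
  perceive.
- **Trial initiation:** an inhomogeneous Poisson process (default
  20 pokes/hr, giving ≈480 initiated trials/day, matching the scale of
  observed daily trial counts) with sinusoidal diurnal modulation (default
  amplitude 0.6) peaking at 01:00, mid-dark-phase for a 07:00–19:00
  lights-on schedule; sampled by thinning.
- **Detection and dropout by stimulus intensity:** detection probability
  per puff defaults to 0.4 / 0.9 / 0.95 at the 2 / 6 / 9 psi intensity
  labels, and the per-trial hazard of permanent task dropout to
  0 / 0 / 0.007. These are configuration, not claims: the values were
  chosen once so that low intensity slows learning, medium intensity
  balances participation and learning, and high intensity drives roughly
  half of a cohort out of the task within the first day. A whiskerless
  ("barbered") agent has detection probability 0 regardless of intensity
  and therefore never departs from baseline licking.
- **Perceptual transfer:** a trained agent switched to a lower intensity
  keeps its detection probability scaled by a transfer factor (default 1.0,
  full transfer) rather than reverting to the naive value.

Dropout is sampled once per initiated trial inside the session loop; when
it fires, the loop stops consuming proposed nosepokes, so a hazard of 1
yields at most one trial.

## Lick analysis pipeline

Deterministic given a log. Licks are debounced to at most one per 100 ms
grid period (half-open periods anchored at trial onset; the sensor cannot
resolve individual licks, which can exceed 10 Hz, so measured rates are
capped at 10 Hz — three grid periods per 300 ms window). Each lick belongs
to the trial whose half-open span [init, next init) contains it, and is
re-expressed relative to the trial's (virtual) puff onset, removing
random-delay jitter. Anticipatory licks are counted in the half-open
window [700, 1000) ms after onset — exactly the 300 ms before water, which
arrives at onset + 1000 ms — and divided by 0.3 s. Note the window is
referenced to *puff onset*; this is the only reading under which "after
the random delay" and "directly before water delivery" coincide.

Trials are binned into 4-hr intervals from training onset; per bin, L_w is
the mean anticipatory rate over stimulus trials and L_b over blank trials
(unrewarded-direction trials count as blanks in discrimination mode), with
zero-lick trials included in the means; performance = L_w − L_b. A bin
with no trials of one type carries an explicit missing value, never zero —
zero is a meaningful lick rate. Per animal, the last ⌈20%⌉ of initiated
trials of the training phase (all types, time-ordered; acclimation
excluded) give the learning criterion: learned ⇔ L_w > L_b on that subset.
An animal is a non-participant if it initiated no trial in the final 4 hr
of the session.

**Finite-sample caveat.** "Learned fraction ≈ 50% under the null" is an
asymptotic property: with very short sessions (last-20% subsets of a few
dozen trials, hence only a handful of blank trials) the sign of L_w − L_b
is measurably biased by the skew of few-sample means, and a subset can
even contain no blank trials at all. Null calibration in the test suite
therefore uses 12-hr sessions (≈95 trials in the subset), where the bias
is below sampling noise; real 48-hr sessions are comfortably asymptotic.

## Whisker motion energy and bouts

Video (≈30 Hz, grayscale, cropped to the whisker field) is filtered with a
separable spatiotemporal Gabor bank — by default 4 orientations × 3
spatial frequencies (0.05, 0.1, 0.2 cyc/px) × 2 temporal frequencies (0.1,
0.25 cyc/frame), a small standard bank, fully configurable. Temporal
kernels are made zero-mean, so the bank is temporally bandpass: a static
scene contributes no energy and any frame-to-frame change contributes
positively. Per frame, squared filter magnitudes are averaged over pixels
and across the bank.

The trace is normalized by subtracting the mean of the pre-stimulus
(1.2 s) samples at or below their 20th percentile — the quiescent floor,
robust to whisking contaminating part of the baseline. The whisking
threshold is mean + 3 SD of the normalized pre-stimulus samples
(population SD). Bouts are maximal supra-threshold runs of ≥ 0.5 s, with
boundaries at sample resolution and no sub-frame interpolation; a trial
counts as whisking if a bout overlaps the 1–2 s post-onset window by at
least the minimum bout duration. Tip-displacement analysis takes tracked
(x, y) coordinates, measures Euclidean distance from the pre-stimulus rest
position, and integrates it (trapezoid) over the stimulus window; gaps in
the track are hard errors. Without a pixel-to-mm scale, outputs are in
pixels.

The synthetic video generator renders a bright quadratic-arc filament on a
dark noisy background with a prescribed tip-deflection profile, returning
ground truth for end-to-end tests. Synthetic whisking epochs superpose an
8 Hz sinusoid with smoothed incoherent jitter: a *pure* sinusoid has
coherent velocity zero-crossings twice per cycle that briefly null the
motion energy, which a real multi-whisker field does not. What passing
these tests shows is that the filter bank, normalization, threshold, and
bout logic recover known motion epochs; it does not validate performance
on real video with body motion, illumination drift, or camera noise
structure.

## Statistics

Within a condition, learning is tested with a two-sided Wilcoxon
signed-rank on per-animal (L_w, L_b) pairs from the last 20% of trials.
Zero differences are dropped before ranking (the count is always
reported); with all differences zero the result is degenerate with p = 1.
The exact null distribution is used for effective n ≤ 25 without ties,
otherwise a normal approximation with continuity correction. Cohorts of
fewer than 5 pairs are refused as underpowered. Pairing is across animals
(one pair per animal), recorded in the output metadata.

Across conditions, performance is compared with a Kruskal-Wallis omnibus
test followed by tie-corrected Dunn rank post-hoc contrasts with Šidák
adjustment, `p_adj = 1 − (1 − p)^m`. Contrasts may be restricted to pairs
against a reference condition (the typical pre-registered design) via the
`reference` argument; with no reference, all pairs are tested. A fully
degenerate dataset (every value identical) is reported as such rather than
erroring.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to keep the statistics well-powered: contingency fractions from
≥10,000 simulated trials (99% binomial CI), learner cohorts of 15 animals
× 48 hr with 10 replicate cohorts for signed-rank power, 1,000 × 12-hr
null animals, 1,000 randomized traces for the bout-rule check, and 1,000
simulated null datasets for Kruskal-Wallis type-I calibration.

## Known limitations

- The learning rule is descriptive; rate-of-learning parameters cannot be
  interpreted mechanistically, and slower learning at low intensity is not
  distinguishable from fewer detections in this parameterization.
- The controller is not real-time software; it models the logged behavior
  of the apparatus, not its electronics.
- The diurnal amplitude of trial initiation is a free parameter with no
  quantitative anchor.
- Consummatory licking that outlasts the post-water break would bleed into
  the next trial's pre-window; the trial-boundary rule (licks belong to
  the trial whose span contains them) is a convention.
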