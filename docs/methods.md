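# Methods

This note documents the generative models, the analysis conventions, the
defaults and why they were chosen, and what the synthetic recovery tests
do and do not establish.

## Task model

A session is five blocks of self-paced trials. Within a block each side of
the response panel carries a fixed reward — 1 or 3 drops of chocolate or
vanilla milk — and the two sides always carry the opposite of both
features. Transitions are unsignaled and follow the fixed scheme
number, flavor, number, flavor; a number transition flips the drop count
on both sides (flavors preserved), a flavor transition flips the flavors
(counts preserved). The first-block contingency is drawn uniformly from
the four feature combinations.

Trial timing (defaults, all integer milliseconds internally): odor onset
500 ms after trial start, odor duration 500 ms, first drop 500 ms after
well entry, 500 ms between drops. The **omission timepoint** — where a
further drop would have been expected — is one inter-drop interval after
the last delivery and is defined on correct single-drop trials. All
windows are half-open `[start, end)` so adjacent epochs (anticipation ends
+100 ms where the response epoch begins) never share a spike.

Block lengths are rounded normal draws, 43 ± 16 trials for block 1 and
65 ± 11 for blocks 2–5, clipped from below at 10 trials. Clipping (rather
than resampling) keeps the block-1 mean within ~0.1 trial of 43. Odor
identity is free-choice with probability 7/20 per trial; forced left/right
odors are balanced to within one trial over the session, and runs of more
than three identical odors are repaired by local swaps (rejection sampling
would bias the free-choice rate). The inter-trial interval is fixed at
4 s — long enough that the 2-s baseline window never overlaps the previous
trial's reward events — plus a 1-s post-consumption pause.

## Behavioral generator

No behavioral model is prescribed by the analysis; the generator is the
minimal learner that reproduces the qualitative behavioral pattern the
analysis presupposes: choices, accuracy and latency track drop number but
not flavor.

Per side the learner keeps an expected drop count V ∈ [0, 3] updated by a
delta rule V ← V + α(r − V) with α = 0.3, and a flavor belief (label +
confidence). Confidence grows toward 1 at a separate, slower rate
α_f = 0.1 while confirmed and resets to α_f when the delivered flavor
switches the belief. The slower flavor rate makes flavor novelty persist
over roughly the ten-trial windows the shift-evidence criteria test; with
a single rate of 0.3, novelty vanishes within two trials and no
ten-trial behavioral test can see it. A shared flavor → drop-count
association (delta rule, rate α) records what each flavor has recently
paid, regardless of side.

Free choices are a softmax over effective values with inverse temperature
1.5 (a converged 2-drop value difference gives ~95% choice of the 3-drop
side). Forced-choice accuracy is 0.82 + 0.04·V clipped to [0.5, 0.99];
latency is 350 − 40·V ms with 60 ms Gaussian noise (floor 80 ms). Lick
count per correct trial is Poisson with mean 6 per delivered drop. Error
trials deliver nothing and never update the learner.

**Flavor attentiveness** is a per-session Bernoulli latent with
P = 104/176 ≈ 0.59, the evident-shift fraction in the dataset the
generator emulates. Only in attentive sessions do (i) lick rate scale
with flavor novelty (multiplier 1 + 1.0·novelty, novelty = 1 − P(delivered
flavor | belief)), (ii) latency slow with flavor uncertainty (+80 ms per
unit), and (iii) the flavor → drop association boost choice values and
predicted drop counts. With attentiveness off, no behavioral measure
covaries with flavor shifts, which calibrates the classifier's null.

## Spike generator

Spike trains are inhomogeneous Poisson processes sampled by thinning
against a per-neuron rate ceiling; rates are piecewise linear on top of a
constant baseline (default 5 Hz) with peak modulation gain (default
10 Hz). Defaults were chosen so the screening test has high power at
~60 trials per block. The time-rescaling theorem test (transformed ISIs vs
unit exponential) passes for ≥95% of simulated neurons at α = .01.

* **prediction** — a triangular bump for every drop that is delivered or
  expected: rise from 200 ms before the (expected) drop, peak gain at
  +100 ms, return to baseline at +275 ms. Expected-but-omitted drops get
  the full bump (the anticipatory rise begins before the expected time);
  drops delivered unexpectedly get the same post-delivery peak/trough
  starting at delivery, so the post-drop response is identical for
  expected and surprising drops — prediction coding, not error coding.
  Expected drops are `round(V)`, boosted in attentive sessions by the
  flavor → drop association of the believed flavor (a flavor recently
  paired with three drops predicts extra drops on a 1-drop side).
* **error** — a rectangular response in the 100–300 ms window after each
  delivered drop with amplitude gain·(number surprise) + flavor-gain·
  (flavor surprise), where number surprise for drop k is
  1 − clip(V − (k−1), 0, 1) and flavor surprise is 1 − P(delivered flavor
  | belief) with P = ½ + ½·confidence on a match and ½ − ½·confidence on a
  mismatch. At a surprising omission the rate is suppressed in the same
  window by gain·P(omitted drop expected), floored at 0 Hz (rates cannot
  be negative). No pre-drop ramp.
* **flavor_selective** — baseline + gain in the post-drop window whenever
  the delivered flavor is the neuron's preferred one; no surprise
  dependence.
* **null** — constant baseline.

Neural and behavioral learning share the same per-trial state snapshot,
so "surprise" means the same thing to the simulated rat and its neurons.

## Analysis conventions

* **Screen**: paired two-sided t-test across all correct trials of the
  rate 100–500 ms after the first drop vs the last 2 s of the preceding
  inter-trial interval; responsive = p < .05 with positive mean
  difference. (Whether the original test was paired or one-tailed is not
  stated; pairing uses the within-trial structure and the positive-mean
  requirement implements "increase".)
* **Scores** are differences of same-epoch rates and are not
  baseline-subtracted (the subtraction cancels); baseline subtraction is
  applied per trial only in PSTH displays. Number-shift scores use the
  first vs last five same-side correct trials of the new block and a
  neuron's two number shifts are averaged into one datapoint; flavor-shift
  scores reference the last five same-side trials of the previous block
  and keep one datapoint per neuron × shift. The flavor-cued anticipation
  variant uses the first two trials vs the last five of the same block.
* **Population tests**: classical one-sample t against zero; Welch
  correction for all two-sample comparisons (positive t means the first
  population is larger).
* **ANOVA**: per-trial post-reward rates (3-drop trials: 100 ms after
  drop 1 to 300 ms after drop 2; 1-drop trials: 100–300 ms after the
  drop) in a three-way fixed-effects side × number × flavor model, type-2
  sums of squares. *Calibration caveat*: because the epoch length is tied
  to the number factor (700 vs 200 ms), Poisson rate variance differs
  with that factor and the number main effect rejects at roughly 8–10%
  under the null rather than 5%; heteroscedasticity-robust and
  duration-weighted variants do not repair it, and a square-root transform
  biases the null. The side and flavor effects — the flavor effect is the
  one downstream analyses consume — are calibrated at nominal α.
* **Flavor follow-up**: for neurons with a flavor main effect, per
  neuron × shift × side changes across the shift (last five previous vs
  first five new) and within the new block (first five vs last five),
  oriented by the neuron's preferred flavor when it has one (otherwise
  raw). Flavor tracking without error signaling gives a significant
  across-shift change with no within-block change.
* **Shift evidence**: a shift counts as behaviorally registered if any of
  (a) one of the first two post-shift free choices went to the 1-drop
  side, (b) lick counts differ (Welch t) between the last ten and first
  ten correct trials on either side, (c) forced-choice error rate differs
  (Fisher's exact — the well-defined form of an exact binomial comparison
  when the reference error count is zero), or (d) forced-choice latency
  differs (Welch t). "Either side" means two uncorrected tests per
  criterion; the compound false-positive rate (~20% with these criteria)
  is measured against the independence oracle 1 − Π(1 − α_i), not
  corrected.

## Determinism and I/O

Every simulation takes an integer seed; a master seed is expanded through
`numpy.random.SeedSequence` so sessions and neurons get independent
streams and identical seeds give byte-identical outputs (TSV tables
included). Sessions round-trip losslessly at millisecond resolution
through the plain-text bundle format (events.tsv, spikes.tsv,
session.json, optional ground_truth.json); the analysis layer consumes
only these files.

## Problem sizes

The recovery experiments use cohorts of 100 prediction + 60 error neurons
over 8 sessions (central dissociation), 42/36/36
prediction/error/flavor-selective neurons over 6 sessions (flavor
timepoints), 24 flavor-selective neurons over 3 sessions (follow-up), 600
null neurons and 120 inattentive sessions (calibration); the calibration
script uses 1,000 sessions and 2,000 null neurons. At these sizes every
significant effect reported by the examples has p well below 10⁻⁵, so the
pass/fail margins are wide.

## What the synthetic tests do and do not show

Passing recovery tests shows the *analysis* does what it claims: given
populations that code predictions, errors, or flavors by construction, the
screen, scores, tests and classifier separate them with the stated
direction and calibration. It does not validate the generator against
real rats: real OFC neurons mix selectivities, baselines and gains vary
across cells, firing is non-Poisson (refractoriness, bursting), learning
is not a fixed-rate delta rule, and real behavioral evidence of flavor
attention is graded rather than a per-session coin flip. The printed
t-statistics of the original recordings are not reproducible from
synthetic data and are not targets. Known limitations: the number-factor
ANOVA miscalibration above; omission suppression is capped at 0 Hz so
deep negative prediction errors compress; the free-choice balance
constraint is enforced per session, not per 250-trial window.
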