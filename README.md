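# rewardshift

Simulation and single-unit analysis of a rodent odor-discrimination task in
which the reward delivered at each response well changes — in **number of
drops** (1 ↔ 3) or in **flavor** (chocolate ↔ vanilla milk) — across
unsignaled blocks of trials. The package is built for computational
neuroscientists who want to ask, with fully verifiable synthetic ground
truth, whether peri-reward firing behaves like a **reward prediction**
(anticipatory, surprise-independent) or a **reward prediction error**
(post-delivery, surprise-scaled).

It has two halves that share one clock:

* **Generator** — a five-block task schedule, a delta-rule behavioral
  learner (softmax choices, value-dependent accuracy/latency, licking),
  and inhomogeneous-Poisson spike trains from four archetypes:
  `prediction` (ramp to each expected drop, peak ~100 ms after delivery,
  trough ~275 ms), `error` (phasic 100–300 ms post-drop response scaled by
  the positive part of the surprise, suppression at surprising omissions),
  `flavor_selective` (fixed post-drop gain for a preferred flavor), and
  `null`.
* **Analysis** — a reward-responsiveness screen, early-vs-late difference
  scores in fixed epochs with one-sample and Welch population *t*-tests, a
  side × number × flavor ANOVA with a flavor-subpopulation follow-up, a
  four-criterion behavioral classifier for whether a rat registered a
  flavor shift, PSTHs, and an end-to-end pipeline over a plain-text
  session format (TSV + JSON).

## The statistic at the core

For a neuron and a block transition, the **difference score** in epoch
*E* anchored on a reward timepoint (a drop delivery, or the omission
timepoint 500 ms after the last drop) is

    D_E = mean rate over the first n trials of the new block
        − mean rate over the last n trials of the reference block

with *n* = 5 (reference = same block for number shifts, previous block for
flavor shifts; *n* = 2 early trials for the flavor-cued anticipation
variant). The canonical epochs are the reward response (+100 to +300 ms),
anticipation (−200 to +100 ms) and screening (+100 to +500 ms) windows,
all half-open at millisecond resolution. Scores are compared against zero
across neurons by *t*-test, and between populations by Welch's *t*.

An error-coding population shows D > 0 in the response epoch after an
unexpected drop; a prediction-coding population shows D ≈ 0 there but
D > 0 in the anticipation epoch at the omitted drop. The learner state
behind both behavior and spikes is a per-side delta rule
V ← V + α(r − V) plus a flavor belief with confidence, so "surprise" is
identical for the behaving rat and its neurons.

## Worked example

`python examples/03_number_shift_dissociation.py` simulates 8 sessions
carrying 100 prediction-coding and 60 error-coding neurons (baseline 5 Hz,
gain 10 Hz) and prints:

```
prediction-error score (100-300 ms after the unexpected 2nd drop):
       error: mean +3.42 Hz, t(59)=10.94, p=8.1e-16, n=60
  prediction: mean -0.10 Hz, t(99)=-0.30, p=0.77, n=100
anticipation score (-200 to +100 ms around the omitted 2nd drop):
  prediction: mean +4.06 Hz, t(99)=20.86, p=5.1e-38, n=100
       error: mean -0.13 Hz, t(59)=-0.56, p=0.58, n=60
error > prediction on PE score:       t=7.84, p=7.8e-13
prediction > error on anticipation:   t=13.91, p=9.7e-28
```

Only the error population carries the post-drop surprise signal, and only
the prediction population carries the anticipatory signal — the double
dissociation the analysis is designed to detect, recovered from known
ground truth. The other examples cover session simulation
(`01_simulate_session.py`), the archetype rate profiles
(`02_spike_archetypes.py`), and the flavor-shift evidence classifier with
flavor prediction-error scores (`04_flavor_shift_evidence.py`).

There is also a thin CLI for running everything against the on-disk
session format:

```
rewardshift run --seed 7 --out out/demo          # simulate + analyze
rewardshift simulate --seed 7 --out out/sessions # bundles only
rewardshift analyze --seed 7 --out out/redo --load out/sessions/session00 ...
```

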