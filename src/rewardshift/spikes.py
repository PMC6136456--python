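"""Spike-train generation from parameterized rate archetypes.

Four archetypes are simulated as inhomogeneous Poisson processes:

``prediction``
    An anticipatory profile: firing rises before each expected drop of
    reward, peaks ~100 ms after delivery, and falls to a local minimum
    ~275 ms after it. Bumps are anchored on every drop that is delivered or
    expected: expected drops get the full pre-delivery ramp (including
    expected-but-omitted drops, where the rise begins before the expected
    time); unexpectedly delivered drops get the same post-delivery
    peak/trough shape starting at delivery. The post-delivery response does
    not depend on surprise.

``error``
    A phasic prediction-error profile: a rectangular rate increase
    100-300 ms after each delivered drop, scaled by the positive part of
    the surprise (number surprise plus flavor surprise), and a rate
    suppression (floored at 0 Hz) in the same window after an expected
    drop's omission. No pre-delivery ramp.

``flavor_selective``
    Baseline plus a fixed gain 100-300 ms after each delivered drop of the
    neuron's preferred flavor; no surprise dependence.

``null``
    Constant baseline.

Surprise is computed from the same learner state that drives behavior, so
neural and behavioral learning share one clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .behavior import PredictionState
from .task import Session, Trial

ARCHETYPES = ("prediction", "error", "flavor_selective", "null")


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generative parameters of one simulated neuron."""

    archetype: str
    baseline_rate: float = 5.0  # Hz
    gain: float = 10.0  # Hz, peak modulation (number / prediction)
    flavor_gain: Optional[float] = None  # Hz; defaults to ``gain``
    ramp_start_ms: int = 200  # ramp onset before an expected drop
    peak_ms: int = 100  # peak after the drop timepoint
    trough_ms: int = 275  # return to baseline after the drop timepoint
    error_window_ms: tuple[int, int] = (100, 300)
    preferred_flavor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.archetype == "flavor_selective" and self.preferred_flavor is None:
            raise ValueError("flavor_selective neurons need preferred_flavor")

    @property
    def effective_flavor_gain(self) -> float:
        return self.gain if self.flavor_gain is None else self.flavor_gain


@dataclass
class SpikeTrain:
    """One neuron's sorted spike timestamps (seconds)."""

    neuron_id: str
    timestamps: np.ndarray
    ground_truth: Optional[NeuronGroundTruth] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("spike timestamps must be sorted")


class RateModel:
    """Piecewise-linear additive rate on top of a constant baseline.

    Segments are non-overlapping, sorted, and linear in rate between their
    endpoints; the total rate is floored at 0 Hz (suppression segments can
    carry negative amplitude).
    """

    def __init__(self, baseline: float, segments: Sequence[tuple]):
        # each segment: (t_start, t_end, r_start, r_end), times in seconds
        segs = sorted(segments, key=lambda s: s[0])
        for a, b in zip(segs, segs[1:]):
            if b[0] < a[1] - 1e-12:
                raise ValueError("rate segments overlap")
        self.baseline = float(baseline)
        self.starts = np.array([s[0] for s in segs], dtype=float)
        self.ends = np.array([s[1] for s in segs], dtype=float)
        self.r0 = np.array([s[2] for s in segs], dtype=float)
        self.r1 = np.array([s[3] for s in segs], dtype=float)

    def rate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.baseline)
        if len(self.starts):
            i = np.searchsorted(self.starts, t, side="right") - 1
            ok = i >= 0
            i_safe = np.clip(i, 0, None)
            inside = ok & (t < self.ends[i_safe])
            if inside.any():
                ii = i_safe[inside]
                frac = (t[inside] - self.starts[ii]) / (
                    self.ends[ii] - self.starts[ii]
                )
                out[inside] += self.r0[ii] + (self.r1[ii] - self.r0[ii]) * frac
        return np.clip(out, 0.0, None)

    def ceiling(self) -> float:
        extra = 0.0
        if len(self.r0):
            extra = max(0.0, float(self.r0.max()), float(self.r1.max()))
        return self.baseline + extra

    def cumulative(self, t: float) -> float:
        """Integrated rate on [0, t] (for time-rescaling checks).

        Exact for segments whose clipped rate stays nonnegative; suppression
        segments are integrated with the floor applied at the endpoints'
        trapezoid, which is exact for our rectangular suppressions.
        """
        total = self.baseline * t
        for s0, s1, a, b in zip(self.starts, self.ends, self.r0, self.r1):
            lo, hi = s0, min(s1, t)
            if hi <= lo:
                continue
            frac0 = (lo - s0) / (s1 - s0)
            frac1 = (hi - s0) / (s1 - s0)
            ra = a + (b - a) * frac0
            rb = a + (b - a) * frac1
            # contribution of the extra rate, floored so baseline+extra >= 0
            ea = max(ra, -self.baseline)
            eb = max(rb, -self.baseline)
            total += 0.5 * (ea + eb) * (hi - lo)
        return total


def _number_surprise(v_num: float, k: int) -> float:
    """Surprise of delivered drop k (1-based) given expected count v."""
    p_k = float(np.clip(v_num - (k - 1), 0.0, 1.0))
    return 1.0 - p_k


def _trial_segments(
    gt: NeuronGroundTruth,
    trial: Trial,
    state: PredictionState,
    attentive: bool,
) -> list[tuple]:
    """Additive rate segments for one trial, given the pre-trial state."""
    segs: list[tuple] = []
    if gt.archetype == "null" or not trial.correct:
        return segs
    side = trial.chosen_side
    s = state.sides[side]
    idi = 0.5  # inter-drop interval in s; equals config default
    if trial.drop_times:
        idi = (
            trial.drop_times[1] - trial.drop_times[0]
            if len(trial.drop_times) > 1
            else 0.5
        )
    ramp = gt.ramp_start_ms / 1000.0
    peak = gt.peak_ms / 1000.0
    trough = gt.trough_ms / 1000.0
    w0, w1 = (x / 1000.0 for x in gt.error_window_ms)

    if gt.archetype == "prediction":
        n_pred = state.predicted_drops(side, attentive)
        n_del = len(trial.drop_times)
        first = (
            trial.drop_times[0]
            if n_del
            else None
        )
        for k in range(1, max(n_pred, n_del) + 1):
            delivered = k <= n_del
            predicted = k <= n_pred
            if delivered:
                t_k = trial.drop_times[k - 1]
            elif first is not None:
                t_k = first + (k - 1) * idi
            else:
                continue
            if predicted:
                segs.append((t_k - ramp, t_k + peak, 0.0, gt.gain))
            else:
                segs.append((t_k, t_k + peak, 0.0, gt.gain))
            segs.append((t_k + peak, t_k + trough, gt.gain, 0.0))

    elif gt.archetype == "error":
        fg = gt.effective_flavor_gain
        p_flavor = (
            state.flavor_probability(side, trial.flavor)
            if trial.flavor is not None
            else 0.5
        )
        flavor_surprise = 1.0 - p_flavor
        for k, t_k in enumerate(trial.drop_times, start=1):
            amp = gt.gain * _number_surprise(s.v_num, k) + fg * flavor_surprise
            if amp > 1e-12:
                segs.append((t_k + w0, t_k + w1, amp, amp))
        if trial.omission_time is not None:
            k_omitted = len(trial.drop_times) + 1
            p_omitted = float(
                np.clip(s.v_num - (k_omitted - 1), 0.0, 1.0)
            )
            depth = min(gt.baseline_rate, gt.gain * p_omitted)
            if depth > 1e-12:
                segs.append(
                    (
                        trial.omission_time + w0,
                        trial.omission_time + w1,
                        -depth,
                        -depth,
                    )
                )

    elif gt.archetype == "flavor_selective":
        if trial.flavor == gt.preferred_flavor:
            for t_k in trial.drop_times:
                segs.append((t_k + w0, t_k + w1, gt.gain, gt.gain))

    return segs


def session_rate_model(
    gt: NeuronGroundTruth, session: Session
) -> RateModel:
    """Compile a neuron's rate over a whole session into a RateModel."""
    segs: list[tuple] = []
    for trial in session.trials:
        if trial.pred_state is None:
            raise ValueError(
                "session trials carry no learner state; rate models can "
                "only be built for freshly simulated sessions"
            )
        segs.extend(
            _trial_segments(gt, trial, trial.pred_state, session.attentive)
        )
    return RateModel(gt.baseline_rate, segs)


def rate_profile(
    gt: NeuronGroundTruth,
    trial: Trial,
    state: PredictionState,
    t,
    attentive: bool = True,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of ``gt`` at time(s) ``t`` in a trial."""
    model = RateModel(
        gt.baseline_rate, _trial_segments(gt, trial, state, attentive)
    )
    out = model.rate(t)
    return out if np.ndim(t) else float(out[0])


def sample_spikes(
    rate_model: RateModel,
    interval: tuple[float, float],
    rng_seed,
) -> np.ndarray:
    """Sample spike times on ``interval`` by thinning.

    Homogeneous Poisson candidates at the model's rate ceiling are accepted
    with probability rate(t)/ceiling; the ceiling bounds the rate by
    construction so every acceptance ratio is <= 1.
    """
    t0, t1 = interval
    if not np.isfinite(t1 - t0) or t1 < t0:
        raise ValueError("invalid interval")
    rng = np.random.default_rng(rng_seed)
    ceiling = rate_model.ceiling()
    if not np.isfinite(ceiling):
        raise ValueError("rate ceiling must be finite")
    if ceiling <= 0:
        return np.empty(0)
    n = rng.poisson(ceiling * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    ratio = rate_model.rate(cand) / ceiling
    if np.any(ratio > 1.0 + 1e-9):
        raise ValueError("rate exceeded its ceiling during thinning")
    keep = rng.random(n) < ratio
    return cand[keep]


def simulate_population(
    session: Session,
    specs: Sequence[NeuronGroundTruth],
    rng_seed: int,
    id_prefix: str = "n",
) -> list[SpikeTrain]:
    """One spike train per ground-truth spec over the whole session."""
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(specs))
    trains = []
    for i, (gt, child) in enumerate(zip(specs, children)):
        model = session_rate_model(gt, session)
        ts = sample_spikes(model, (0.0, session.t_end), child)
        trains.append(
            SpikeTrain(
                neuron_id=f"{id_prefix}{i:04d}", timestamps=ts, ground_truth=gt
            )
        )
    return trains
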