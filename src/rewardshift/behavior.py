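"""Trial-by-trial behavior from a delta-rule value learner.

The simulated rat tracks, per response side, the expected number of reward
drops (a continuous value updated by a delta rule) and a belief about the
flavor delivered there (a label plus a confidence that grows toward 1 while
confirmed and resets when the flavor changes). Free choices are a softmax
over expected drop number; forced-choice accuracy and reaction time are
linear in the expected value of the instructed side. Because flavors are
equally palatable, choices track drop number but not flavor — number
transitions move behavior, flavor transitions do not.

Some sessions are "flavor-attentive" (a per-session Bernoulli latent): in
those, lick rate and latency carry a flavor-novelty signal and the learner's
flavor-to-drop-count association transiently biases free choices after a
flavor shift. This latent is the generator's ground truth for the
shift-evidence classifier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .task import (
    Block,
    Session,
    TaskConfig,
    Trial,
    build_block_schedule,
    drop_event_times,
    generate_odor_sequence,
)


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the behavioral generative model.

    ``flavor_attention_prob`` defaults to 104/176, the fraction of flavor
    shifts with behavioral evidence in the dataset the generator emulates.
    """

    alpha_value: float = 0.3
    alpha_flavor: float = 0.1  # slower flavor-belief learning
    softmax_temp: float = 1.5  # inverse temperature on expected drops
    base_latency_ms: float = 350.0
    latency_value_slope: float = -40.0  # ms per expected drop
    latency_sd_ms: float = 60.0
    min_latency_ms: float = 80.0
    base_accuracy: float = 0.82
    accuracy_value_slope: float = 0.04  # per expected drop
    licks_per_drop_mean: float = 6.0
    flavor_attention_prob: float = 104 / 176
    lick_flavor_gain: float = 1.0  # lick-rate multiplier per unit novelty
    latency_flavor_slope_ms: float = 80.0  # ms per unit flavor uncertainty
    lick_interval_ms: float = 120.0
    post_reward_pause_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_value <= 1.0:
            raise ValueError("alpha_value must be in [0, 1]")
        if not 0.0 <= self.flavor_attention_prob <= 1.0:
            raise ValueError("flavor_attention_prob must be in [0, 1]")


@dataclass
class SideState:
    """Learner state for one response side."""

    v_num: float = 2.0  # expected drop count, in [0, 3]
    believed_flavor: Optional[str] = None
    flavor_confidence: float = 0.0


@dataclass
class PredictionState:
    """Full learner state: per-side values/beliefs plus the flavor->drop
    association shared across sides (what each flavor has recently paid)."""

    sides: dict = field(default_factory=lambda: {
        "left": SideState(),
        "right": SideState(),
    })
    flavor_assoc: dict = field(
        default_factory=lambda: {"chocolate": 2.0, "vanilla": 2.0}
    )

    def copy(self) -> "PredictionState":
        return copy.deepcopy(self)

    def flavor_probability(self, side: str, flavor: str) -> float:
        """P(next reward on ``side`` has ``flavor``) under current belief."""
        s = self.sides[side]
        if s.believed_flavor is None:
            return 0.5
        if flavor == s.believed_flavor:
            return 0.5 + 0.5 * s.flavor_confidence
        return 0.5 - 0.5 * s.flavor_confidence

    def predicted_drops(self, side: str, attentive: bool = True) -> int:
        """Number of drops currently expected on ``side``.

        In flavor-attentive sessions the expectation is boosted by the
        flavor->drop-count association of the believed flavor: a flavor last
        paired with three drops predicts extra drops even on a side whose
        own value has converged to one.
        """
        s = self.sides[side]
        v = s.v_num
        if attentive and s.believed_flavor is not None:
            v = max(v, self.flavor_assoc.get(s.believed_flavor, v))
        return int(np.floor(v + 0.5))


def update_prediction(
    state: PredictionState,
    side: str,
    outcome: tuple[int, str],
    alpha: float,
    alpha_flavor: Optional[float] = None,
) -> PredictionState:
    """Delta-rule update after a correct trial's outcome on ``side``.

    Returns a new state; the input is not mutated. The drop-count value
    moves toward the delivered count at rate ``alpha``; flavor confidence
    grows when the delivered flavor confirms the belief and resets to the
    flavor learning rate when the belief switches. ``alpha_flavor`` defaults
    to ``alpha``; a slower flavor rate makes flavor novelty persist over
    several trials after a shift. The flavor->drop association is updated
    at ``alpha``.
    """
    if alpha_flavor is None:
        alpha_flavor = alpha
    n_drops, flavor = outcome
    new = state.copy()
    s = new.sides[side]
    s.v_num = s.v_num + alpha * (n_drops - s.v_num)
    if s.believed_flavor == flavor:
        s.flavor_confidence = s.flavor_confidence + alpha_flavor * (
            1.0 - s.flavor_confidence
        )
    else:
        s.believed_flavor = flavor
        s.flavor_confidence = alpha_flavor
    assoc = new.flavor_assoc.get(flavor, float(n_drops))
    new.flavor_assoc[flavor] = assoc + alpha * (n_drops - assoc)
    return new


def _softmax_left_prob(
    state: PredictionState, temp: float, attentive: bool
) -> float:
    def effective(side: str) -> float:
        s = state.sides[side]
        v = s.v_num
        if attentive and s.believed_flavor is not None:
            v = max(v, state.flavor_assoc.get(s.believed_flavor, v))
        return v

    dv = effective("left") - effective("right")
    return float(1.0 / (1.0 + np.exp(-temp * dv)))


def simulate_behavior(
    schedule: list[Block],
    params: BehaviorParams,
    config: TaskConfig,
    rng_seed: int,
) -> Session:
    """Simulate one complete session of behavior over ``schedule``.

    Event timestamps follow the task timing rules exactly; the learner is
    updated only on correct trials; error trials deliver no reward.
    """
    ss = np.random.SeedSequence(rng_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    odor_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
    attentive = bool(rng.random() < params.flavor_attention_prob)

    n_trials = sum(b.n_trials for b in schedule)
    odors = generate_odor_sequence(n_trials, config, odor_seed)

    state = PredictionState()
    trials: list[Trial] = []
    t_ms = config.iti_duration_ms  # pre-session ITI holds the first baseline
    trial_index = 0
    for block in schedule:
        for _ in range(block.n_trials):
            trial_index += 1
            odor = odors[trial_index - 1]
            pre_state = state.copy()

            if odor == "free":
                p_left = _softmax_left_prob(
                    state, params.softmax_temp, attentive
                )
                chosen = "left" if rng.random() < p_left else "right"
                correct = True
            else:
                instructed = "left" if odor == "forced_left" else "right"
                v = state.sides[instructed].v_num
                p_correct = float(
                    np.clip(
                        params.base_accuracy
                        + params.accuracy_value_slope * v,
                        0.5,
                        0.99,
                    )
                )
                correct = bool(rng.random() < p_correct)
                chosen = (
                    instructed
                    if correct
                    else ("right" if instructed == "left" else "left")
                )

            s_chosen = state.sides[chosen]
            latency_mean = (
                params.base_latency_ms
                + params.latency_value_slope * s_chosen.v_num
            )
            if attentive:
                uncertainty = 1.0 - s_chosen.flavor_confidence
                latency_mean += params.latency_flavor_slope_ms * uncertainty
            latency = float(
                int(
                    round(
                        max(
                            params.min_latency_ms,
                            float(
                                rng.normal(latency_mean, params.latency_sd_ms)
                            ),
                        )
                    )
                )
            )

            t_start = t_ms / 1000.0
            t_odor_on = (t_ms + config.odor_preperiod_ms) / 1000.0
            odor_off_ms = (
                t_ms + config.odor_preperiod_ms + config.odor_duration_ms
            )
            t_odor_off = odor_off_ms / 1000.0
            well_entry_ms = odor_off_ms + int(latency)
            t_well_entry = well_entry_ms / 1000.0

            if correct:
                n_drops, flavor = block.contingency[chosen]
                drop_times, omission = drop_event_times(
                    t_well_entry, n_drops, config
                )
                lick_mean = params.licks_per_drop_mean * n_drops
                if attentive:
                    novelty = 1.0 - state.flavor_probability(chosen, flavor)
                    lick_mean *= 1.0 + params.lick_flavor_gain * novelty
                n_licks = int(rng.poisson(lick_mean))
                first_drop_ms = int(round(drop_times[0] * 1000))
                lick_ms = int(round(params.lick_interval_ms))
                lick_times = [
                    (first_drop_ms + (k + 1) * lick_ms) / 1000.0
                    for k in range(n_licks)
                ]
                state = update_prediction(
                    state, chosen, (n_drops, flavor), params.alpha_value,
                    alpha_flavor=params.alpha_flavor,
                )
            else:
                n_drops, flavor = 0, None
                drop_times, omission = [], None
                lick_times = []

            trials.append(
                Trial(
                    index=trial_index,
                    block_index=block.index,
                    odor=odor,
                    chosen_side=chosen,
                    correct=correct,
                    t_trial_start=t_start,
                    t_odor_on=t_odor_on,
                    t_odor_off=t_odor_off,
                    t_well_entry=t_well_entry,
                    drop_times=drop_times,
                    omission_time=omission,
                    lick_times=lick_times,
                    latency_ms=latency,
                    n_drops=n_drops,
                    flavor=flavor,
                    pred_state=pre_state,
                )
            )

            t_last = max(
                [t_well_entry]
                + drop_times
                + lick_times
                + ([omission] if omission is not None else [])
            )
            t_ms = (
                int(round(t_last * 1000))
                + int(params.post_reward_pause_ms)
                + config.iti_duration_ms
            )

    return Session(
        config=config,
        blocks=list(schedule),
        trials=trials,
        attentive=attentive,
        seed=rng_seed,
        t_end=t_ms / 1000.0,
    )


def simulate_session(
    config: TaskConfig,
    params: BehaviorParams,
    rng_seed: int,
) -> Session:
    """Convenience wrapper: draw a block schedule and simulate behavior."""
    ss = np.random.SeedSequence(rng_seed)
    sched_seed, beh_seed = (
        int(s % (2**31)) for s in ss.generate_state(2, dtype=np.uint32)
    )
    schedule = build_block_schedule(config, sched_seed)
    return simulate_behavior(schedule, params, config, beh_seed)
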