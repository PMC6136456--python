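"""Deterministic structure of the block-design reward task.

A session is organized into blocks (default five). Within a block the two
response sides always carry opposite reward features: when one side gives one
drop of chocolate milk, the other gives three drops of vanilla, and so on.
Unsignaled transitions between blocks flip either the drop number on both
sides (flavors preserved) or the flavor on both sides (numbers preserved),
following the fixed scheme number, flavor, number, flavor after block 1.

All timing arithmetic is done on integer milliseconds internally; public
timestamps are seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FLAVORS = ("chocolate", "vanilla")
DROP_NUMBERS = (1, 3)
SIDES = ("left", "right")
ODORS = ("forced_left", "forced_right", "free")

#: The four possible (n_drops, flavor) assignments for the left side; the
#: right side always carries the opposite of both features.
CONTINGENCY_COMBOS = tuple(
    (n, f) for n in DROP_NUMBERS for f in FLAVORS
)


class ConfigurationError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the behavioral task.

    Durations are in milliseconds; block lengths in trials.
    """

    n_blocks: int = 5
    first_block_len_mean: float = 43.0
    first_block_len_sd: float = 16.0
    later_block_len_mean: float = 65.0
    later_block_len_sd: float = 11.0
    free_choice_prob: float = 7 / 20
    max_consecutive_same_odor: int = 3
    reward_delay_ms: int = 500
    inter_drop_interval_ms: int = 500
    odor_preperiod_ms: int = 500
    odor_duration_ms: int = 500
    iti_duration_ms: int = 4000
    min_block_len: int = 10

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        for name in (
            "reward_delay_ms",
            "inter_drop_interval_ms",
            "odor_preperiod_ms",
            "odor_duration_ms",
            "iti_duration_ms",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.iti_duration_ms < 2000:
            raise ConfigurationError(
                "iti_duration_ms must be >= 2000 so the 2 s baseline "
                "window fits inside the inter-trial interval"
            )
        if not 0.0 < self.free_choice_prob < 1.0:
            raise ConfigurationError("free_choice_prob must be in (0, 1)")
        if self.max_consecutive_same_odor < 1:
            raise ConfigurationError("max_consecutive_same_odor must be >= 1")
        if self.min_block_len < 1:
            raise ConfigurationError("min_block_len must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


@dataclass(frozen=True)
class Block:
    """One block of trials with a fixed reward contingency.

    ``contingency`` maps side -> (n_drops, flavor); within a block the two
    sides differ in both features.
    """

    index: int  # 1-based
    transition_type: str  # 'initial' | 'number' | 'flavor'
    contingency: dict  # side -> (n_drops, flavor)
    n_trials: int

    def __post_init__(self) -> None:
        (nl, fl) = self.contingency["left"]
        (nr, fr) = self.contingency["right"]
        if nl == nr or fl == fr:
            raise ConfigurationError(
                "sides must differ in both drop number and flavor"
            )

    def side_with_drops(self, n_drops: int) -> str:
        """The physical side carrying ``n_drops`` drops in this block."""
        for side in SIDES:
            if self.contingency[side][0] == n_drops:
                return side
        raise ValueError(f"no side with {n_drops} drops")

    def flavor_on(self, side: str) -> str:
        return self.contingency[side][1]

    def drops_on(self, side: str) -> int:
        return self.contingency[side][0]


def _opposite_flavor(flavor: str) -> str:
    return FLAVORS[1 - FLAVORS.index(flavor)]


def _opposite_drops(n: int) -> int:
    return DROP_NUMBERS[1 - DROP_NUMBERS.index(n)]


def flip_number(contingency: dict) -> dict:
    """Number transition: flip drop counts on both sides, keep flavors."""
    return {
        s: (_opposite_drops(n), f) for s, (n, f) in contingency.items()
    }


def flip_flavor(contingency: dict) -> dict:
    """Flavor transition: flip flavors on both sides, keep drop counts."""
    return {
        s: (n, _opposite_flavor(f)) for s, (n, f) in contingency.items()
    }


def _draw_block_length(
    rng: np.random.Generator, mean: float, sd: float, min_len: int
) -> int:
    return max(min_len, int(round(rng.normal(mean, sd))))


def build_block_schedule(config: TaskConfig, rng_seed: int) -> list[Block]:
    """Build the block schedule for one session.

    The block-1 contingency is drawn uniformly from the four possible
    feature combinations; later blocks follow the fixed alternating
    number/flavor flip scheme. Block lengths are rounded normal draws
    clipped from below at ``config.min_block_len``.
    """
    rng = np.random.default_rng(rng_seed)
    n_left, f_left = CONTINGENCY_COMBOS[rng.integers(len(CONTINGENCY_COMBOS))]
    contingency = {
        "left": (n_left, f_left),
        "right": (_opposite_drops(n_left), _opposite_flavor(f_left)),
    }
    blocks = []
    transition_cycle = ("number", "flavor")
    for i in range(config.n_blocks):
        if i == 0:
            ttype = "initial"
            mean, sd = config.first_block_len_mean, config.first_block_len_sd
        else:
            ttype = transition_cycle[(i - 1) % 2]
            contingency = (
                flip_number(contingency)
                if ttype == "number"
                else flip_flavor(contingency)
            )
            mean, sd = config.later_block_len_mean, config.later_block_len_sd
        blocks.append(
            Block(
                index=i + 1,
                transition_type=ttype,
                contingency=dict(contingency),
                n_trials=_draw_block_length(rng, mean, sd, config.min_block_len),
            )
        )
    return blocks


def _find_runs(seq: list[str], max_run: int) -> list[int]:
    """Indices at which a run of identical labels exceeds ``max_run``.

    Returns the index of the (max_run+1)-th element of each offending run —
    a brute-force linear scan usable as its own oracle.
    """
    bad = []
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run == max_run + 1:
            bad.append(i)
        elif run > max_run + 1:
            bad.append(i)
    return bad


def _swap_is_safe(seq: list[str], i: int, j: int, max_run: int) -> bool:
    seq[i], seq[j] = seq[j], seq[i]
    ok = True
    for k in (i, j):
        lo = max(0, k - max_run)
        hi = min(len(seq), k + max_run + 1)
        if _find_runs(seq[lo:hi], max_run):
            ok = False
            break
    seq[i], seq[j] = seq[j], seq[i]
    return ok


def generate_odor_sequence(
    n_trials: int, config: TaskConfig, rng_seed: int
) -> list[str]:
    """Pseudorandom odor sequence for one session.

    Each trial is the free-choice odor with probability
    ``config.free_choice_prob``; the remaining forced trials are split
    between left and right so that the counts differ by at most one over the
    session. Runs of more than ``max_consecutive_same_odor`` identical odors
    are repaired by local swaps (rejection sampling would bias the
    free-choice rate).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if n_trials == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    free_mask = rng.random(n_trials) < config.free_choice_prob
    n_forced = int(n_trials - free_mask.sum())
    n_left = n_forced // 2
    if n_forced % 2 == 1 and rng.random() < 0.5:
        n_left += 1
    forced = ["forced_left"] * n_left + ["forced_right"] * (n_forced - n_left)
    rng.shuffle(forced)
    seq: list[str] = []
    it = iter(forced)
    for is_free in free_mask:
        seq.append("free" if is_free else next(it))

    max_run = config.max_consecutive_same_odor

    def run_too_long_at(i: int) -> bool:
        if i < max_run:
            return False
        return all(seq[i - k] == seq[i] for k in range(1, max_run + 1))

    for _ in range(100):  # passes; violations are rare, few passes suffice
        bad = _find_runs(seq, max_run)
        if not bad:
            break
        for i in bad:
            if not run_too_long_at(i):
                continue  # already fixed by an earlier swap this pass
            j = None
            for _ in range(200):  # expected O(1) random probes
                cand = int(rng.integers(n_trials))
                if seq[cand] != seq[i] and _swap_is_safe(seq, i, cand, max_run):
                    j = cand
                    break
            if j is None:
                others = [k for k in range(n_trials) if seq[k] != seq[i]]
                if not others:
                    return seq  # degenerate single-label input
                j = others[int(rng.integers(len(others)))]
            seq[i], seq[j] = seq[j], seq[i]
    return seq


def drop_event_times(
    t_well_entry: float, n_drops: int, config: TaskConfig
) -> tuple[list[float], Optional[float]]:
    """Timestamps (s) of fluid-drop deliveries and the omission timepoint.

    Drops start ``reward_delay_ms`` after well entry and repeat every
    ``inter_drop_interval_ms``. The omission timepoint — where a further drop
    would have been expected, one inter-drop interval after the last
    delivery — is defined only for single-drop trials.
    """
    if t_well_entry < 0:
        raise ValueError("t_well_entry must be non-negative")
    if n_drops < 0:
        raise ValueError("n_drops must be >= 0")
    t_ms = int(round(t_well_entry * 1000))
    drops_ms = [
        t_ms + config.reward_delay_ms + k * config.inter_drop_interval_ms
        for k in range(n_drops)
    ]
    omission_ms = (
        drops_ms[-1] + config.inter_drop_interval_ms if n_drops == 1 else None
    )
    drops = [t / 1000.0 for t in drops_ms]
    omission = None if omission_ms is None else omission_ms / 1000.0
    return drops, omission


@dataclass
class Trial:
    """One trial of a session with its event timestamps (seconds)."""

    index: int  # 1-based, session-wide
    block_index: int
    odor: str
    chosen_side: str  # 'left' | 'right' | 'none'
    correct: bool
    t_trial_start: float
    t_odor_on: float
    t_odor_off: float
    t_well_entry: float
    drop_times: list[float]
    omission_time: Optional[float]
    lick_times: list[float]
    latency_ms: float
    n_drops: int  # delivered drops (0 on error trials)
    flavor: Optional[str]  # delivered flavor, None on error trials
    #: learner state snapshot taken before the trial outcome; used by the
    #: spike simulator, never by the analysis, and not persisted to disk
    pred_state: object = field(default=None, compare=False, repr=False)

    @property
    def lick_count(self) -> int:
        return len(self.lick_times)


@dataclass
class Session:
    """A full simulated or loaded recording session."""

    config: TaskConfig
    blocks: list[Block]
    trials: list[Trial]
    attentive: bool = True
    seed: Optional[int] = None
    t_end: float = 0.0

    def transitions(self) -> list[tuple[int, str]]:
        """(shift_id, transition_type) for each block transition.

        ``shift_id`` s marks the boundary between block s and block s+1.
        """
        return [
            (b.index - 1, b.transition_type) for b in self.blocks[1:]
        ]

    def block(self, index: int) -> Block:
        return self.blocks[index - 1]

    def correct_trials(
        self, block_index: Optional[int] = None, side: Optional[str] = None
    ) -> list[Trial]:
        out = []
        for t in self.trials:
            if not t.correct:
                continue
            if block_index is not None and t.block_index != block_index:
                continue
            if side is not None and t.chosen_side != side:
                continue
            out.append(t)
        return out
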