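"""Inferential machinery of the single-unit analysis.

The analysis asks whether a neuron's firing around each drop of reward
behaves like a reward prediction (anticipatory, surprise-independent) or a
reward prediction error (post-delivery, surprise-scaled). Its elements:

* a reward-responsiveness screen (increase 100-500 ms after the first drop
  vs. the 2-s pre-trial baseline, paired t-test across all correct trials);
* early-vs-late difference scores in fixed epochs around a drop or omission
  timepoint, compared across a population by one-sample t-test, and between
  populations by Welch's t-test;
* a side x number x flavor factorial ANOVA on post-reward firing with a
  follow-up that separates flavor tracking from flavor prediction errors;
* a four-criterion behavioral classifier deciding whether a rat registered
  a flavor shift at all.

Scores are differences of same-epoch rates and are deliberately NOT
baseline-subtracted (the subtraction cancels); baseline subtraction applies
only to PSTH displays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ephys import (
    EpochDefinition,
    anticipation_epoch,
    baseline_rate,
    reward_response_epoch,
    screening_epoch,
    trial_epoch_rate,
)
from .task import Session, Trial

logger = logging.getLogger(__name__)

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class ScoreRecord:
    """One neuron(-x-shift) early-minus-late firing-rate difference (Hz)."""

    neuron_id: str
    shift_id: Optional[int]
    epoch: EpochDefinition
    side: str  # '1-drop' | '3-drop'
    score: float
    n_early: int
    n_late: int


@dataclass
class PopulationTestResult:
    mean: float
    t: float
    df: float
    p: float
    n: int


@dataclass
class ShiftEvidence:
    """Behavioral verdict on one flavor shift: did the rat register it?"""

    shift_id: int
    criterion_a: bool  # early free choice toward the 1-drop side
    criterion_b: bool  # lick count changed (t-test, either side)
    criterion_c: bool  # forced-choice error rate changed (exact test)
    criterion_d: bool  # forced-choice latency changed (t-test, either side)
    stats: dict = field(default_factory=dict)

    @property
    def evident(self) -> bool:
        return (
            self.criterion_a
            or self.criterion_b
            or self.criterion_c
            or self.criterion_d
        )


# ---------------------------------------------------------------------------
# reward-responsiveness screen


def screen_reward_responsive(spikes, session: Session) -> tuple[bool, dict]:
    """Screen for a significant firing increase to the first reward drop.

    Paired two-sided t-test, across all correct trials, of the rate
    100-500 ms after the first drop against that trial's baseline rate;
    flagged when p < .05 with a positive mean difference.
    """
    epoch = screening_epoch()
    epoch_rates, base_rates = [], []
    for tr in session.correct_trials():
        r = trial_epoch_rate(spikes, tr, epoch)
        if r is None:
            continue
        epoch_rates.append(r)
        base_rates.append(baseline_rate(spikes, tr))
    if len(epoch_rates) < 2:
        raise InsufficientDataError("screen needs >= 2 correct trials")
    epoch_rates = np.array(epoch_rates)
    base_rates = np.array(base_rates)
    diff = epoch_rates - base_rates
    if np.allclose(diff, diff[0]):
        # zero-variance difference: identical rates trial-by-trial
        return False, {"t": 0.0, "p": 1.0, "mean_diff": float(diff.mean()),
                       "n": len(diff)}
    t, p = sps.ttest_rel(epoch_rates, base_rates)
    flag = bool(p < ALPHA and diff.mean() > 0)
    return flag, {
        "t": float(t),
        "p": float(p),
        "mean_diff": float(diff.mean()),
        "n": len(diff),
    }


# ---------------------------------------------------------------------------
# difference scores


def _resolve_side(session: Session, shift: int, side: str) -> str:
    """Map a '1-drop'/'3-drop' label (w.r.t. the post-shift block) to a
    physical side."""
    new_block = session.block(shift + 1)
    n = 1 if side == "1-drop" else 3
    return new_block.side_with_drops(n)


def _side_trials(
    session: Session, block_index: int, phys_side: str
) -> list[Trial]:
    return session.correct_trials(block_index=block_index, side=phys_side)


def prediction_error_score(
    spikes,
    session: Session,
    shift: int,
    epoch: EpochDefinition,
    side: str,
    early_n: int = 5,
    late_n: int = 5,
    reference: str = "same_block",
    neuron_id: str = "",
) -> Optional[ScoreRecord]:
    """Early-minus-late mean epoch rate around block transition ``shift``.

    Early trials are the first ``early_n`` correct trials to the given side
    in the post-shift block; late trials are the last ``late_n`` such trials
    of the same block (number shifts) or of the pre-shift block (flavor
    shifts, ``reference='previous_block'``). Returns None with a logged
    warning when either set is short.
    """
    if reference not in ("same_block", "previous_block"):
        raise ValueError("reference must be same_block or previous_block")
    phys = _resolve_side(session, shift, side)
    new_trials = _side_trials(session, shift + 1, phys)
    ref_block = shift + 1 if reference == "same_block" else shift
    ref_trials = _side_trials(session, ref_block, phys)
    early = new_trials[:early_n]
    late = ref_trials[-late_n:]
    if reference == "same_block":
        # early and late trials must not overlap within the block
        late = [t for t in late if t not in early]
    if len(early) < early_n or len(late) < late_n:
        logger.warning(
            "score excluded: shift %d side %s has %d early / %d late trials",
            shift, side, len(early), len(late),
        )
        return None

    def rates(trials):
        vals = [trial_epoch_rate(spikes, tr, epoch) for tr in trials]
        return [v for v in vals if v is not None]

    r_early, r_late = rates(early), rates(late)
    if len(r_early) < early_n or len(r_late) < late_n:
        logger.warning(
            "score excluded: shift %d side %s lacks epoch anchors", shift, side
        )
        return None
    return ScoreRecord(
        neuron_id=neuron_id,
        shift_id=shift,
        epoch=epoch,
        side=side,
        score=float(np.mean(r_early) - np.mean(r_late)),
        n_early=len(r_early),
        n_late=len(r_late),
    )


def anticipation_score(
    spikes,
    session: Session,
    shift: int,
    side: str = "1-drop",
    early_n: int = 5,
    late_n: int = 5,
    reference: str = "same_block",
    neuron_id: str = "",
) -> Optional[ScoreRecord]:
    """Early-minus-late rate in the anticipation epoch at the omission.

    The omission timepoint exists only on correct single-drop trials, so
    ``side`` defaults to the 1-drop side of the post-shift block.
    """
    return prediction_error_score(
        spikes,
        session,
        shift,
        anticipation_epoch("omission"),
        side,
        early_n=early_n,
        late_n=late_n,
        reference=reference,
        neuron_id=neuron_id,
    )


def population_score_test(
    scores: Sequence[float] | Sequence[ScoreRecord],
) -> PopulationTestResult:
    """One-sample two-sided t-test of a score distribution against zero."""
    vals = np.array(
        [s.score if isinstance(s, ScoreRecord) else float(s) for s in scores]
    )
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 scores")
    if np.allclose(vals, vals[0]):
        if vals[0] == 0.0:
            return PopulationTestResult(0.0, 0.0, vals.size - 1, 1.0, vals.size)
        raise DegenerateVarianceError("score distribution has zero variance")
    t, p = sps.ttest_1samp(vals, 0.0)
    return PopulationTestResult(
        mean=float(vals.mean()),
        t=float(t),
        df=vals.size - 1,
        p=float(p),
        n=vals.size,
    )


def compare_populations(
    scores_a: Sequence[float] | Sequence[ScoreRecord],
    scores_b: Sequence[float] | Sequence[ScoreRecord],
) -> PopulationTestResult:
    """Welch two-sample t-test; positive t means population a > b."""

    def to_arr(scores):
        return np.array(
            [s.score if isinstance(s, ScoreRecord) else float(s)
             for s in scores]
        )

    a, b = to_arr(scores_a), to_arr(scores_b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 scores per population")
    res = sps.ttest_ind(a, b, equal_var=False)
    return PopulationTestResult(
        mean=float(a.mean() - b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=a.size + b.size,
    )


# ---------------------------------------------------------------------------
# factorial analysis of post-reward firing


def _anova_epoch_rate(spikes, trial: Trial) -> Optional[float]:
    """Side-dependent post-reward rate: on 3-drop trials 100 ms after drop 1
    to 300 ms after drop 2; on 1-drop trials 100-300 ms after the drop."""
    if not trial.drop_times:
        return None
    if trial.n_drops >= 2:
        # [drop1+100, drop2+300)
        from .ephys import epoch_rate

        t0 = int(round(trial.drop_times[0] * 1000)) + 100
        t1 = int(round(trial.drop_times[1] * 1000)) + 300
        return epoch_rate(spikes, t0 / 1000.0, t1 / 1000.0)
    return trial_epoch_rate(spikes, trial, reward_response_epoch(("drop", 1)))


def firing_rate_table(spikes, session: Session) -> pd.DataFrame:
    """Per-trial post-reward rates with side/number/flavor factors."""
    rows = []
    for tr in session.correct_trials():
        r = _anova_epoch_rate(spikes, tr)
        if r is None:
            continue
        rows.append(
            {
                "trial": tr.index,
                "block": tr.block_index,
                "side": tr.chosen_side,
                "number": tr.n_drops,
                "flavor": tr.flavor,
                "rate": r,
            }
        )
    return pd.DataFrame(rows)


def anova_from_table(table: pd.DataFrame) -> dict:
    """Three-way fixed-effects ANOVA on the rate table.

    Returns {effect: (F, df_num, df_den, p)} for the three main effects and
    all interactions (type-2 sums of squares).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if table.empty:
        raise InsufficientDataError("empty rate table")
    cells = table.groupby(["side", "number", "flavor"]).size()
    if (cells < 2).any() or len(cells) < 8:
        warnings.warn(
            "factor cells missing or nearly empty; interactions unreliable",
            stacklevel=2,
        )
    model = smf.ols(
        "rate ~ C(side) * C(number) * C(flavor)", data=table
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=2)
    out = {}
    rename = {
        "C(side)": "side",
        "C(number)": "number",
        "C(flavor)": "flavor",
        "C(side):C(number)": "side:number",
        "C(side):C(flavor)": "side:flavor",
        "C(number):C(flavor)": "number:flavor",
        "C(side):C(number):C(flavor)": "side:number:flavor",
    }
    df_den = float(aov.loc["Residual", "df"])
    for key, name in rename.items():
        if key in aov.index:
            out[name] = (
                float(aov.loc[key, "F"]),
                float(aov.loc[key, "df"]),
                df_den,
                float(aov.loc[key, "PR(>F)"]),
            )
    return out


def firing_anova(spikes, session: Session) -> dict:
    """Side x number x flavor ANOVA on per-trial post-reward rates."""
    return anova_from_table(firing_rate_table(spikes, session))


@dataclass
class FollowupResult:
    """Across-shift vs within-block firing changes for a cohort."""

    shift_changes: np.ndarray  # per neuron x shift x side, preference-signed
    block_changes: np.ndarray
    shift_test: Optional[PopulationTestResult]
    block_test: Optional[PopulationTestResult]
    paired_t: Optional[float]
    paired_p: Optional[float]
    n_neurons: int


def _followup_epoch_rates(spikes, trials: Sequence[Trial]) -> list[float]:
    vals = []
    for tr in trials:
        r = _anova_epoch_rate(spikes, tr)
        if r is not None:
            vals.append(r)
    return vals


def flavor_subpop_followup(
    trains,
    session: Session,
    require_flavor_effect: bool = True,
    n_trials: int = 5,
    alpha: float = ALPHA,
) -> FollowupResult:
    """Across-shift vs within-block change for flavor-coding neurons.

    For each qualifying neuron and each flavor shift, two change magnitudes
    in the side-appropriate post-reward epoch: across the shift (last five
    same-side trials of the previous block vs first five of the new block)
    and across the new block (first five vs last five of that block). When a
    neuron has a significant flavor main effect, changes are oriented by its
    preferred flavor (positive = toward the response to the preferred
    flavor); otherwise raw. Flavor tracking without error signaling yields a
    significant across-shift change but no within-block change.
    """
    flavor_shifts = [s for s, ttype in session.transitions()
                     if ttype == "flavor"]
    d_shift, d_block = [], []
    n_used = 0
    for train in trains:
        aov = firing_anova(train, session)
        has_effect = "flavor" in aov and aov["flavor"][3] < alpha
        if require_flavor_effect and not has_effect:
            continue
        n_used += 1
        if has_effect:
            table = firing_rate_table(train, session)
            means = table.groupby("flavor")["rate"].mean()
            preferred = means.idxmax()
        else:
            preferred = None
        for shift in flavor_shifts:
            new_block = session.block(shift + 1)
            new_flavors = {
                side: new_block.flavor_on(side) for side in ("left", "right")
            }
            for side_label in ("1-drop", "3-drop"):
                phys = _resolve_side(session, shift, side_label)
                prev = _side_trials(session, shift, phys)
                new = _side_trials(session, shift + 1, phys)
                if len(prev) < n_trials or len(new) < 2 * n_trials:
                    continue
                r_prev = _followup_epoch_rates(train, prev[-n_trials:])
                r_early = _followup_epoch_rates(train, new[:n_trials])
                r_late = _followup_epoch_rates(train, new[-n_trials:])
                if not (r_prev and r_early and r_late):
                    continue
                sign = 1.0
                if preferred is not None:
                    sign = 1.0 if new_flavors[phys] == preferred else -1.0
                d_shift.append(
                    sign * (np.mean(r_early) - np.mean(r_prev))
                )
                d_block.append(
                    sign * (np.mean(r_early) - np.mean(r_late))
                )
    d_shift = np.array(d_shift)
    d_block = np.array(d_block)
    if d_shift.size == 0:
        warnings.warn("no qualifying neurons for flavor follow-up",
                      stacklevel=2)
        return FollowupResult(d_shift, d_block, None, None, None, None, 0)
    shift_test = population_score_test(d_shift) if d_shift.size >= 2 else None
    block_test = population_score_test(d_block) if d_block.size >= 2 else None
    paired_t = paired_p = None
    if d_shift.size >= 2:
        t, p = sps.ttest_rel(d_shift, d_block)
        paired_t, paired_p = float(t), float(p)
    return FollowupResult(
        d_shift, d_block, shift_test, block_test, paired_t, paired_p, n_used
    )


# ---------------------------------------------------------------------------
# behavioral evidence that a flavor shift was registered


def _two_sample_t(pre, post) -> float:
    """Welch t-test p-value; 1.0 when degenerate."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if pre.size < 2 or post.size < 2:
        return 1.0
    if np.allclose(pre, pre[0]) and np.allclose(post, post[0]):
        return 1.0 if pre[0] == post[0] else 0.0
    res = sps.ttest_ind(pre, post, equal_var=False)
    return float(res.pvalue)


def shift_evidence(
    session: Session, shift: int, n_window: int = 10
) -> ShiftEvidence:
    """Four-criterion behavioral test that a flavor shift was registered.

    (a) one of the first two free choices after the shift went to the 1-drop
    side; (b) lick counts differ between the last ten and first ten correct
    trials on either side (Welch t-test, p < .05); (c) forced-choice error
    rate differs between the last ten and first ten forced trials on either
    side (exact test, p < .05); (d) forced-choice latency differs likewise
    (Welch t-test, p < .05). "Either side" means two uncorrected tests per
    criterion. Windows shorter than ten trials leave that criterion false.
    """
    ttype = dict(session.transitions()).get(shift)
    if ttype != "flavor":
        raise ValueError(f"shift {shift} is not a flavor transition")
    shift_start_trial = sum(b.n_trials for b in session.blocks[:shift]) + 1
    one_drop_phys = _resolve_side(session, shift, "1-drop")
    stats_out: dict = {}

    # (a) first two free choices after the shift
    free_after = [
        t for t in session.trials
        if t.index >= shift_start_trial and t.odor == "free" and t.correct
    ][:2]
    crit_a = any(t.chosen_side == one_drop_phys for t in free_after)
    stats_out["a_choices"] = [t.chosen_side for t in free_after]

    crit_b = crit_c = crit_d = False
    for phys in ("left", "right"):
        pre_correct = [
            t for t in session.trials
            if t.correct and t.chosen_side == phys
            and t.index < shift_start_trial
        ][-n_window:]
        post_correct = [
            t for t in session.trials
            if t.correct and t.chosen_side == phys
            and t.index >= shift_start_trial
        ][:n_window]
        # (b) licks on correct trials to this side
        if len(pre_correct) >= n_window and len(post_correct) >= n_window:
            p = _two_sample_t(
                [t.lick_count for t in pre_correct],
                [t.lick_count for t in post_correct],
            )
            stats_out[f"b_p_{phys}"] = p
            crit_b = crit_b or p < ALPHA
        else:
            logger.warning(
                "shift %d: <%d correct trials on %s; lick criterion undefined",
                shift, n_window, phys,
            )

        # (c)/(d) forced-choice trials instructed to this side
        odor = f"forced_{phys}"
        pre_forced = [
            t for t in session.trials
            if t.odor == odor and t.index < shift_start_trial
        ][-n_window:]
        post_forced = [
            t for t in session.trials
            if t.odor == odor and t.index >= shift_start_trial
        ][:n_window]
        if len(pre_forced) >= n_window and len(post_forced) >= n_window:
            e_pre = sum(not t.correct for t in pre_forced)
            e_post = sum(not t.correct for t in post_forced)
            table = [
                [e_pre, len(pre_forced) - e_pre],
                [e_post, len(post_forced) - e_post],
            ]
            _, p_c = sps.fisher_exact(table)
            stats_out[f"c_p_{phys}"] = float(p_c)
            crit_c = crit_c or p_c < ALPHA
            p_d = _two_sample_t(
                [t.latency_ms for t in pre_forced],
                [t.latency_ms for t in post_forced],
            )
            stats_out[f"d_p_{phys}"] = p_d
            crit_d = crit_d or p_d < ALPHA
        else:
            logger.warning(
                "shift %d: <%d forced trials on %s; criteria c/d undefined",
                shift, n_window, phys,
            )

    return ShiftEvidence(
        shift_id=shift,
        criterion_a=bool(crit_a),
        criterion_b=bool(crit_b),
        criterion_c=bool(crit_c),
        criterion_d=bool(crit_d),
        stats=stats_out,
    )


# ---------------------------------------------------------------------------
# behavioral choice rates around transitions


def choice_rate_around_transition(
    session: Session, shift: int, n_window: int = 25
) -> tuple[Optional[float], Optional[float], bool]:
    """Free-choice rate toward the post-shift 3-drop side before vs after.

    Windows are the last/first ``n_window`` correct trials around the shift
    (free and forced interleaved); the rate is the fraction of free choices
    in the window toward the side carrying three drops in the new block.
    Returns (last_rate, first_rate, complete); rates are None when a window
    has no free choices.
    """
    shift_start_trial = sum(b.n_trials for b in session.blocks[:shift]) + 1
    three_phys = _resolve_side(session, shift, "3-drop")
    correct = session.correct_trials()
    pre = [t for t in correct if t.index < shift_start_trial][-n_window:]
    post = [t for t in correct if t.index >= shift_start_trial][:n_window]
    complete = len(pre) == n_window and len(post) == n_window
    if not complete:
        logger.warning("shift %d: incomplete 25-trial windows", shift)

    def rate(window):
        free = [t for t in window if t.odor == "free"]
        if not free:
            return None
        return sum(t.chosen_side == three_phys for t in free) / len(free)

    return rate(pre), rate(post), complete
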