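"""End-to-end cohort simulation and analysis.

``run_pipeline`` chains simulate (or load) -> reward-responsiveness screen
-> number- and flavor-shift difference scores -> behavioral shift-evidence
split -> factorial ANOVA with the flavor-subpopulation follow-up ->
population tests, writing tab-separated result tables (and optional PSTH
figures) plus a run log. All analysis stages consume the on-disk session
format, never simulator internals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .behavior import BehaviorParams, simulate_behavior
from .ephys import anticipation_epoch, reward_response_epoch
from .io import SessionBundle, read_session, write_session
from .spikes import NeuronGroundTruth, SpikeTrain, simulate_population
from .task import Session, TaskConfig, build_block_schedule

logger = logging.getLogger(__name__)

#: The three reward timepoints examined after a flavor shift:
#: (side label, drop index).
FLAVOR_TIMEPOINTS = (("3-drop", 1), ("3-drop", 2), ("1-drop", 1))


@dataclass(frozen=True)
class CohortConfig:
    """What to simulate: sessions, neurons per session, neuron parameters."""

    n_sessions: int = 8
    neurons_per_session: dict = field(
        default_factory=lambda: {
            "prediction": 8,
            "error": 5,
            "flavor_selective": 4,
            "null": 3,
        }
    )
    baseline_rate: float = 5.0
    gain: float = 10.0
    flavor_gain: Optional[float] = None

    def specs(self) -> list[NeuronGroundTruth]:
        out = []
        flavors = ("chocolate", "vanilla")
        i = 0
        for archetype, n in self.neurons_per_session.items():
            for k in range(n):
                out.append(
                    NeuronGroundTruth(
                        archetype=archetype,
                        baseline_rate=self.baseline_rate,
                        gain=self.gain,
                        flavor_gain=self.flavor_gain,
                        preferred_flavor=(
                            flavors[(i + k) % 2]
                            if archetype == "flavor_selective"
                            else None
                        ),
                    )
                )
            i += 1
        return out


def load_config(path) -> tuple[TaskConfig, BehaviorParams, CohortConfig]:
    """Read a YAML/JSON config with sections task, behavior, cohort."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    task = TaskConfig(**raw.get("task", {}))
    behavior = BehaviorParams(**raw.get("behavior", {}))
    cohort = CohortConfig(**raw.get("cohort", {}))
    return task, behavior, cohort


def simulate_cohort(
    task: TaskConfig,
    behavior: BehaviorParams,
    cohort: CohortConfig,
    seed: int,
) -> list[tuple[Session, list[SpikeTrain]]]:
    """Simulate ``cohort.n_sessions`` sessions, each with its population."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(cohort.n_sessions)):
        s1, s2, s3 = (
            int(x % (2**31)) for x in child.generate_state(3, dtype=np.uint32)
        )
        schedule = build_block_schedule(task, s1)
        session = simulate_behavior(schedule, behavior, task, s2)
        population = simulate_population(
            session, cohort.specs(), s3, id_prefix=f"s{i}_n"
        )
        out.append((session, population))
    return out


# ---------------------------------------------------------------------------
# cohort-level score extraction


def number_shift_pe_score(
    train: SpikeTrain, session: Session
) -> Optional[float]:
    """Prediction-error score after the unexpected second drop.

    At each number shift the second drop is newly delivered on the 3-drop
    side; the score compares the first five vs last five correct same-side
    trials of the new block in the 100-300 ms post-drop epoch. A neuron's
    two number shifts are averaged into one datapoint.
    """
    vals = []
    for shift, ttype in session.transitions():
        if ttype != "number":
            continue
        rec = st.prediction_error_score(
            train,
            session,
            shift,
            reward_response_epoch(("drop", 2)),
            side="3-drop",
            reference="same_block",
            neuron_id=train.neuron_id,
        )
        if rec is not None:
            vals.append(rec.score)
    return float(np.mean(vals)) if vals else None


def number_shift_anticipation_score(
    train: SpikeTrain, session: Session
) -> Optional[float]:
    """Anticipation score at the omitted second drop on the new 1-drop side,
    averaged over a neuron's number shifts."""
    vals = []
    for shift, ttype in session.transitions():
        if ttype != "number":
            continue
        rec = st.anticipation_score(
            train, session, shift, side="1-drop", neuron_id=train.neuron_id
        )
        if rec is not None:
            vals.append(rec.score)
    return float(np.mean(vals)) if vals else None


def flavor_shift_pe_scores(
    train: SpikeTrain,
    session: Session,
    shifts: Optional[Sequence[int]] = None,
) -> dict[tuple, list[float]]:
    """Per-shift prediction-error scores at the three flavor timepoints.

    Flavor-shift scores reference the last five same-side trials of the
    PREVIOUS block (the flavor changes at the boundary, so the new block has
    no expected-flavor trials). One datapoint per neuron x shift.
    """
    if shifts is None:
        shifts = [s for s, t in session.transitions() if t == "flavor"]
    out: dict[tuple, list[float]] = {tp: [] for tp in FLAVOR_TIMEPOINTS}
    for shift in shifts:
        for side, k in FLAVOR_TIMEPOINTS:
            rec = st.prediction_error_score(
                train,
                session,
                shift,
                reward_response_epoch(("drop", k)),
                side=side,
                reference="previous_block",
                neuron_id=train.neuron_id,
            )
            if rec is not None:
                out[(side, k)].append(rec.score)
    return out


def flavor_shift_anticipation_scores(
    train: SpikeTrain,
    session: Session,
    shifts: Optional[Sequence[int]] = None,
    early_n: int = 2,
) -> list[float]:
    """First-two-trial anticipation score at the expected-but-absent second
    drop on the 1-drop side after a flavor shift (vs last five of that
    block)."""
    if shifts is None:
        shifts = [s for s, t in session.transitions() if t == "flavor"]
    vals = []
    for shift in shifts:
        rec = st.anticipation_score(
            train,
            session,
            shift,
            side="1-drop",
            early_n=early_n,
            late_n=5,
            reference="same_block",
            neuron_id=train.neuron_id,
        )
        if rec is not None:
            vals.append(rec.score)
    return vals


def cohort_scores_by_archetype(
    cohort: Sequence[tuple[Session, list[SpikeTrain]]],
    score_fn,
) -> dict[str, list[float]]:
    """Apply a per-neuron score function across a cohort, grouped by
    ground-truth archetype (unlabeled neurons grouped under 'unknown')."""
    out: dict[str, list[float]] = {}
    for session, population in cohort:
        for train in population:
            v = score_fn(train, session)
            if v is None:
                continue
            key = (
                train.ground_truth.archetype
                if train.ground_truth is not None
                else "unknown"
            )
            vals = v if isinstance(v, list) else [v]
            out.setdefault(key, []).extend(vals)
    return out


# ---------------------------------------------------------------------------
# full pipeline


def _config_hash(*objs) -> str:
    payload = json.dumps(
        [dataclasses.asdict(o) for o in objs], sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def run_pipeline(
    out_dir,
    seed: int,
    config_path=None,
    load: Optional[Sequence] = None,
    figures: bool = False,
) -> dict:
    """Run the full simulate -> analyze -> report pipeline.

    ``load`` may give existing bundle directories to analyze instead of
    simulating. Returns a dict of output paths and headline results; writes
    scores.tsv, population_tests.tsv, shift_evidence.tsv, anova_effects.tsv
    and run.log under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rewardshift")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(out, seed, config_path, load, figures)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(out, seed, config_path, load, figures) -> dict:
    if config_path is not None:
        task, behavior, cohort_cfg = load_config(config_path)
    else:
        task, behavior, cohort_cfg = (
            TaskConfig(), BehaviorParams(), CohortConfig()
        )
    logger.info(
        "run seed=%d config_hash=%s", seed,
        _config_hash(task, behavior, cohort_cfg),
    )

    stage = "simulate/load"
    try:
        if load:
            bundles = [SessionBundle.in_dir(d) for d in load]
        else:
            cohort = simulate_cohort(task, behavior, cohort_cfg, seed)
            bundles = []
            for i, (session, population) in enumerate(cohort):
                bdir = out / "sessions" / f"session{i:02d}"
                bundles.append(
                    write_session(session, population, bdir, f"s{i}")
                )
        data = [read_session(b) for b in bundles]
        logger.info("loaded %d sessions", len(data))

        stage = "screen"
        screened = []
        n_total = 0
        for session, population in data:
            for train in population:
                n_total += 1
                flag, _ = st.screen_reward_responsive(train, session)
                if flag:
                    screened.append((session, train))
        logger.info(
            "screening: n_total=%d n_responsive=%d", n_total, len(screened)
        )

        stage = "scores"
        score_rows = []
        num_pe, num_ant = [], []
        flavor_pe = {tp: [] for tp in FLAVOR_TIMEPOINTS}
        for session, train in screened:
            v = number_shift_pe_score(train, session)
            if v is not None:
                num_pe.append(v)
                score_rows.append(
                    (train.neuron_id, "number_pe", "", "3-drop", v)
                )
            v = number_shift_anticipation_score(train, session)
            if v is not None:
                num_ant.append(v)
                score_rows.append(
                    (train.neuron_id, "number_anticipation", "", "1-drop", v)
                )

        stage = "shift evidence"
        evidence_rows = []
        evident_shifts: dict[int, list[int]] = {}
        for si, (session, population) in enumerate(data):
            evident_shifts[si] = []
            for shift, ttype in session.transitions():
                if ttype != "flavor":
                    continue
                ev = st.shift_evidence(session, shift)
                evidence_rows.append(
                    {
                        "session": si,
                        "shift_id": shift,
                        "criterion_a": int(ev.criterion_a),
                        "criterion_b": int(ev.criterion_b),
                        "criterion_c": int(ev.criterion_c),
                        "criterion_d": int(ev.criterion_d),
                        "evident": int(ev.evident),
                    }
                )
                if ev.evident:
                    evident_shifts[si].append(shift)
        n_evident = sum(len(v) for v in evident_shifts.values())
        logger.info(
            "shift evidence: %d flavor shifts, %d evident",
            len(evidence_rows), n_evident,
        )

        for si, (session, population) in enumerate(data):
            shifts = evident_shifts[si]
            if not shifts:
                continue
            for train in population:
                if not any(t is train for s, t in screened if s is session):
                    continue
                per_tp = flavor_shift_pe_scores(train, session, shifts)
                for tp, vals in per_tp.items():
                    flavor_pe[tp].extend(vals)
                    for v in vals:
                        score_rows.append(
                            (train.neuron_id, "flavor_pe",
                             f"drop{tp[1]}", tp[0], v)
                        )

        stage = "population tests"
        test_rows = []

        def add_test(name, scores):
            if len(scores) < 2:
                logger.warning("population test %s skipped (n=%d)",
                               name, len(scores))
                return None
            r = st.population_score_test(scores)
            test_rows.append(
                {"test": name, "mean": r.mean, "t": r.t, "df": r.df,
                 "p": r.p, "n": r.n}
            )
            return r

        add_test("number_pe", num_pe)
        add_test("number_anticipation", num_ant)
        for (side, k), vals in flavor_pe.items():
            add_test(f"flavor_pe_{side}_drop{k}", vals)

        stage = "anova"
        anova_rows = []
        followups = []
        for si, (session, population) in enumerate(data):
            sess_trains = [t for s, t in screened if s is session]
            for train in sess_trains:
                try:
                    aov = st.firing_anova(train, session)
                except st.InsufficientDataError:
                    continue
                for effect, (F, dfn, dfd, p) in aov.items():
                    anova_rows.append(
                        {"session": si, "neuron_id": train.neuron_id,
                         "effect": effect, "F": F, "df_num": dfn,
                         "df_den": dfd, "p": p}
                    )
            if sess_trains:
                followups.append(
                    st.flavor_subpop_followup(sess_trains, session)
                )
        logger.info("anova: %d neuron-effect rows", len(anova_rows))

        stage = "write tables"
        scores_df = pd.DataFrame(
            score_rows,
            columns=["neuron_id", "score_type", "timepoint", "side", "score"],
        ).sort_values(["score_type", "neuron_id", "timepoint"]).reset_index(
            drop=True
        )
        scores_df["score"] = scores_df["score"].map(_fmt)
        scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
        pd.DataFrame(test_rows).map(_fmt).to_csv(
            out / "population_tests.tsv", sep="\t", index=False
        )
        pd.DataFrame(evidence_rows).to_csv(
            out / "shift_evidence.tsv", sep="\t", index=False
        )
        pd.DataFrame(anova_rows).map(_fmt).to_csv(
            out / "anova_effects.tsv", sep="\t", index=False
        )

        if figures:
            stage = "figures"
            _write_figures(out, data, screened)
    except Exception as e:  # re-raise naming the failed stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    return {
        "out_dir": str(out),
        "n_neurons": n_total,
        "n_responsive": len(screened),
        "n_flavor_shifts": len(evidence_rows),
        "n_evident_shifts": n_evident,
        "tests": {r["test"]: r for r in test_rows},
    }


def _write_figures(out, data, screened) -> None:
    """Population PSTH panels around number shifts (early vs late trials)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .ephys import baseline_rate, build_psth, population_psth

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, side, title in (
        (axes[0], "3-drop", "1 drop -> 3 drops"),
        (axes[1], "1-drop", "3 drops -> 1 drop"),
    ):
        early_psths, late_psths = [], []
        for session, train in screened:
            for shift, ttype in session.transitions():
                if ttype != "number":
                    continue
                from .stats import _resolve_side, _side_trials

                phys = _resolve_side(session, shift, side)
                trials = _side_trials(session, shift + 1, phys)
                if len(trials) < 10:
                    continue
                for group, psths in (
                    (trials[:5], early_psths), (trials[-5:], late_psths)
                ):
                    anchors = [t.drop_times[0] for t in group if t.drop_times]
                    if not anchors:
                        continue
                    baselines = [
                        baseline_rate(train, t) for t in group if t.drop_times
                    ]
                    psths.append(
                        build_psth(
                            train, anchors, window_ms=(-500, 2000),
                            baselines=baselines,
                        )
                    )
        for psths, color, label in (
            (early_psths, "tab:red", "first 5"),
            (late_psths, "tab:blue", "last 5"),
        ):
            if not psths:
                continue
            pop = population_psth(psths)
            x = pop.bin_centers_ms
            ax.plot(x, pop.mean, color=color, label=label)
            ax.fill_between(
                x, pop.mean - pop.sem, pop.mean + pop.sem,
                color=color, alpha=0.3,
            )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(title)
        ax.set_xlabel("time from first drop (ms)")
    axes[0].set_ylabel("baseline-subtracted rate (Hz)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "psth_number_shifts.png", dpi=120)
    plt.close(fig)
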