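"""Plain-text session format: events and spikes tables plus JSON sidecars.

A session bundle on disk is a directory of

* ``events.tsv`` — one row per behavioral event (tab-separated, UTF-8,
  header row, no quoting) with columns session_id, trial, block,
  transition_type, odor, chosen_side, correct, event_type, event_index,
  timestamp_ms, n_drops, flavor;
* ``spikes.tsv`` — columns neuron_id, timestamp_ms, sorted within neuron;
* ``session.json`` — task config snapshot, block contingencies, master
  seed, attentiveness flag, session end time;
* ``ground_truth.json`` (optional) — per-neuron generative parameters.

Timestamps are serialized as integer milliseconds; the round trip through
this format is lossless at that resolution. The analysis layer consumes
only these files, never simulator internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .spikes import NeuronGroundTruth, SpikeTrain
from .task import Block, Session, TaskConfig, Trial

EVENT_COLUMNS = [
    "session_id",
    "trial",
    "block",
    "transition_type",
    "odor",
    "chosen_side",
    "correct",
    "event_type",
    "event_index",
    "timestamp_ms",
    "n_drops",
    "flavor",
]

SPIKE_COLUMNS = ["neuron_id", "timestamp_ms"]


class SessionFormatError(ValueError):
    """Raised on malformed session files; names the offending file."""


@dataclass
class SessionBundle:
    events_path: Path
    spikes_path: Path
    meta_path: Path
    ground_truth_path: Optional[Path] = None

    @classmethod
    def in_dir(cls, directory, with_ground_truth: bool = True):
        d = Path(directory)
        gt = d / "ground_truth.json"
        return cls(
            events_path=d / "events.tsv",
            spikes_path=d / "spikes.tsv",
            meta_path=d / "session.json",
            ground_truth_path=gt if (with_ground_truth or gt.exists()) else None,
        )


def _ms(t: Optional[float]) -> Optional[int]:
    return None if t is None else int(round(t * 1000))


def write_session(
    session: Session,
    population: list[SpikeTrain],
    directory,
    session_id: str = "s0",
) -> SessionBundle:
    """Write a session and its spike trains as a bundle under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle = SessionBundle.in_dir(d)

    rows = []
    block_types = {b.index: b.transition_type for b in session.blocks}
    for tr in session.trials:
        base = {
            "session_id": session_id,
            "trial": tr.index,
            "block": tr.block_index,
            "transition_type": block_types[tr.block_index],
            "odor": tr.odor,
            "chosen_side": tr.chosen_side,
            "correct": int(tr.correct),
            "n_drops": tr.n_drops,
            "flavor": tr.flavor if tr.flavor is not None else "",
        }

        def add(event_type, index, t):
            rows.append(
                {**base, "event_type": event_type, "event_index": index,
                 "timestamp_ms": _ms(t)}
            )

        add("trial_start", 0, tr.t_trial_start)
        add("odor_on", 0, tr.t_odor_on)
        add("odor_off", 0, tr.t_odor_off)
        add("well_entry", 0, tr.t_well_entry)
        for k, t in enumerate(tr.drop_times):
            add("drop", k, t)
        if tr.omission_time is not None:
            add("omission", 0, tr.omission_time)
        for k, t in enumerate(tr.lick_times):
            add("lick", k, t)
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events.to_csv(bundle.events_path, sep="\t", index=False)

    spike_rows = []
    for train in population:
        ts_ms = np.round(train.timestamps * 1000).astype(np.int64)
        spike_rows.append(
            pd.DataFrame(
                {"neuron_id": train.neuron_id, "timestamp_ms": ts_ms}
            )
        )
    spikes = (
        pd.concat(spike_rows, ignore_index=True)
        if spike_rows
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    spikes.to_csv(bundle.spikes_path, sep="\t", index=False)

    meta = {
        "session_id": session_id,
        "config": session.config.to_dict(),
        "seed": session.seed,
        "attentive": session.attentive,
        "t_end_ms": _ms(session.t_end),
        "blocks": [
            {
                "index": b.index,
                "transition_type": b.transition_type,
                "n_trials": b.n_trials,
                "contingency": {
                    s: list(c) for s, c in b.contingency.items()
                },
            }
            for b in session.blocks
        ],
    }
    bundle.meta_path.write_text(json.dumps(meta, indent=1))

    if population and any(t.ground_truth is not None for t in population):
        gt = {
            t.neuron_id: dataclasses.asdict(t.ground_truth)
            for t in population
            if t.ground_truth is not None
        }
        bundle.ground_truth_path.write_text(json.dumps(gt, indent=1))
    else:
        bundle.ground_truth_path = None
    return bundle


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")


def read_session(bundle: SessionBundle) -> tuple[Session, list[SpikeTrain]]:
    """Read a session bundle back into in-memory objects.

    Learner-state snapshots are not persisted, so a re-read session can be
    analyzed but not used to simulate new spike trains.
    """
    if isinstance(bundle, (str, Path)):
        bundle = SessionBundle.in_dir(bundle)
    try:
        meta = json.loads(Path(bundle.meta_path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise SessionFormatError(f"{bundle.meta_path}: {e}") from e
    config = TaskConfig.from_dict(meta["config"])
    blocks = [
        Block(
            index=b["index"],
            transition_type=b["transition_type"],
            contingency={s: tuple(c) for s, c in b["contingency"].items()},
            n_trials=b["n_trials"],
        )
        for b in meta["blocks"]
    ]

    try:
        events = pd.read_csv(bundle.events_path, sep="\t")
    except (OSError, pd.errors.ParserError) as e:
        raise SessionFormatError(f"{bundle.events_path}: {e}") from e
    _require_columns(events, EVENT_COLUMNS, bundle.events_path)

    n_blocks = len(blocks)
    bad_blocks = set(events["block"].unique()) - set(range(1, n_blocks + 1))
    if bad_blocks:
        raise SessionFormatError(
            f"{bundle.events_path}: events reference unknown block(s) "
            f"{sorted(bad_blocks)}"
        )
    trials = []
    for trial_idx, g in events.groupby("trial", sort=True):
        block_index = int(g["block"].iloc[0])
        by_type = {
            etype: sub.sort_values("event_index")
            for etype, sub in g.groupby("event_type")
        }

        def one(etype, required=True):
            if etype not in by_type:
                if required:
                    raise SessionFormatError(
                        f"{bundle.events_path}: trial {trial_idx} lacks "
                        f"{etype} event"
                    )
                return None
            return float(by_type[etype]["timestamp_ms"].iloc[0]) / 1000.0

        t_start = one("trial_start")
        t_odor_on = one("odor_on")
        t_odor_off = one("odor_off")
        t_well = one("well_entry")
        drops = (
            [float(x) / 1000.0 for x in by_type["drop"]["timestamp_ms"]]
            if "drop" in by_type
            else []
        )
        licks = (
            [float(x) / 1000.0 for x in by_type["lick"]["timestamp_ms"]]
            if "lick" in by_type
            else []
        )
        omission = one("omission", required=False)
        flavor = g["flavor"].iloc[0]
        flavor = None if (pd.isna(flavor) or flavor == "") else str(flavor)
        trials.append(
            Trial(
                index=int(trial_idx),
                block_index=block_index,
                odor=str(g["odor"].iloc[0]),
                chosen_side=str(g["chosen_side"].iloc[0]),
                correct=bool(int(g["correct"].iloc[0])),
                t_trial_start=t_start,
                t_odor_on=t_odor_on,
                t_odor_off=t_odor_off,
                t_well_entry=t_well,
                drop_times=drops,
                omission_time=omission,
                lick_times=licks,
                latency_ms=round((t_well - t_odor_off) * 1000, 1),
                n_drops=len(drops),
                flavor=flavor,
            )
        )
    session = Session(
        config=config,
        blocks=blocks,
        trials=trials,
        attentive=bool(meta.get("attentive", True)),
        seed=meta.get("seed"),
        t_end=float(meta["t_end_ms"]) / 1000.0,
    )

    try:
        spikes = pd.read_csv(bundle.spikes_path, sep="\t")
    except (OSError, pd.errors.ParserError) as e:
        raise SessionFormatError(f"{bundle.spikes_path}: {e}") from e
    _require_columns(spikes, SPIKE_COLUMNS, bundle.spikes_path)

    gt_map = {}
    if bundle.ground_truth_path and Path(bundle.ground_truth_path).exists():
        raw = json.loads(Path(bundle.ground_truth_path).read_text())
        for nid, d in raw.items():
            d = dict(d)
            if d.get("error_window_ms") is not None:
                d["error_window_ms"] = tuple(d["error_window_ms"])
            gt_map[nid] = NeuronGroundTruth(**d)

    population = []
    for nid, g in spikes.groupby("neuron_id", sort=True):
        ts = g["timestamp_ms"].to_numpy()
        if np.any(np.diff(ts) < 0):
            row = int(np.flatnonzero(np.diff(ts) < 0)[0])
            raise SessionFormatError(
                f"{bundle.spikes_path}: spikes for neuron {nid} out of "
                f"order near row {row}"
            )
        population.append(
            SpikeTrain(
                neuron_id=str(nid),
                timestamps=ts.astype(float) / 1000.0,
                ground_truth=gt_map.get(str(nid)),
            )
        )
    return session, population
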