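"""Event-aligned firing-rate extraction.

All windows are half-open ``[start, end)`` so adjacent epochs (the
anticipation epoch ends +100 ms where the reward-response epoch begins)
never double-count a spike. Epoch offsets are integer milliseconds relative
to an anchor event: a specific drop delivery, the first drop, or the
omission timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .spikes import SpikeTrain
from .task import Session, Trial


@dataclass(frozen=True)
class EpochDefinition:
    """A window relative to an anchor event, in signed milliseconds.

    ``anchor`` is ``("drop", k)`` (k is 1-based), ``"first_drop"``, or
    ``"omission"``.
    """

    anchor: Union[str, tuple]
    start_offset_ms: int
    end_offset_ms: int

    def __post_init__(self) -> None:
        if self.end_offset_ms <= self.start_offset_ms:
            raise ValueError("epoch end must follow its start")

    def anchor_time(self, trial: Trial) -> Optional[float]:
        """The anchor timestamp in ``trial``, or None if absent."""
        if self.anchor == "omission":
            return trial.omission_time
        if self.anchor == "first_drop":
            return trial.drop_times[0] if trial.drop_times else None
        kind, k = self.anchor
        if kind != "drop":
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if len(trial.drop_times) >= k:
            return trial.drop_times[k - 1]
        return None

    def window(self, trial: Trial) -> Optional[tuple[float, float]]:
        t = self.anchor_time(trial)
        if t is None:
            return None
        t_ms = int(round(t * 1000))
        return (
            (t_ms + self.start_offset_ms) / 1000.0,
            (t_ms + self.end_offset_ms) / 1000.0,
        )


def reward_response_epoch(anchor) -> EpochDefinition:
    """100-300 ms after the given reward timepoint."""
    return EpochDefinition(anchor, 100, 300)


def anticipation_epoch(anchor) -> EpochDefinition:
    """200 ms before to 100 ms after the given reward timepoint."""
    return EpochDefinition(anchor, -200, 100)


def screening_epoch() -> EpochDefinition:
    """100-500 ms after the first drop (reward-responsiveness screen)."""
    return EpochDefinition("first_drop", 100, 500)


BASELINE_WINDOW_MS = 2000  # last 2 s of the preceding inter-trial interval


def _timestamps(spikes) -> np.ndarray:
    if isinstance(spikes, SpikeTrain):
        return spikes.timestamps
    return np.asarray(spikes, dtype=float)


def epoch_rate(spikes, t0: float, t1: float) -> float:
    """Firing rate (Hz) on the half-open window [t0, t1)."""
    if t1 <= t0:
        raise ValueError("epoch end must follow its start")
    ts = _timestamps(spikes)
    n = np.searchsorted(ts, t1, side="left") - np.searchsorted(
        ts, t0, side="left"
    )
    return float(n) / (t1 - t0)


def baseline_rate(spikes, trial: Trial) -> float:
    """Rate over the last 2 s of the inter-trial interval before ``trial``."""
    t1 = trial.t_trial_start
    return epoch_rate(spikes, t1 - BASELINE_WINDOW_MS / 1000.0, t1)


def trial_epoch_rate(
    spikes, trial: Trial, epoch: EpochDefinition
) -> Optional[float]:
    """Rate in ``epoch`` of ``trial``; None if the anchor is absent."""
    win = epoch.window(trial)
    if win is None:
        return None
    return epoch_rate(spikes, *win)


@dataclass
class PSTH:
    """Binned, trial-averaged firing aligned to an event.

    ``rates`` is trials x bins, baseline-subtracted per trial when
    baselines are given. ``mean``/``sem`` are across trials.
    """

    bin_edges_ms: np.ndarray
    rates: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def build_psth(
    spikes,
    anchors: Sequence[float],
    window_ms: tuple[int, int] = (-500, 1500),
    bin_width_ms: int = 20,
    baselines: Optional[Sequence[float]] = None,
) -> PSTH:
    """Per-trial binned rates around ``anchors``, minus per-trial baselines.

    The window span must be an exact multiple of the bin width.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("anchors must be non-empty")
    span = window_ms[1] - window_ms[0]
    if span <= 0 or span % bin_width_ms != 0:
        raise ValueError("window span must be a positive multiple of bin width")
    n_bins = span // bin_width_ms
    edges_ms = window_ms[0] + bin_width_ms * np.arange(n_bins + 1)
    ts = _timestamps(spikes)
    if baselines is None:
        baselines = np.zeros(anchors.size)
    baselines = np.asarray(baselines, dtype=float)
    rates = np.empty((anchors.size, n_bins))
    for i, (a, b) in enumerate(zip(anchors, baselines)):
        a_ms = int(round(a * 1000))
        edges_s = (a_ms + edges_ms) / 1000.0
        counts = np.diff(np.searchsorted(ts, edges_s, side="left"))
        rates[i] = counts / (bin_width_ms / 1000.0) - b
    mean = rates.mean(axis=0)
    sem = (
        rates.std(axis=0, ddof=1) / np.sqrt(anchors.size)
        if anchors.size > 1
        else np.zeros(n_bins)
    )
    return PSTH(bin_edges_ms=edges_ms, rates=rates, mean=mean, sem=sem)


def population_psth(psths: Sequence[PSTH]) -> PSTH:
    """Average per-neuron PSTH means, with SEM across neurons per bin."""
    if not psths:
        raise ValueError("no PSTHs to average")
    edges = psths[0].bin_edges_ms
    means = np.vstack([p.mean for p in psths])
    mean = means.mean(axis=0)
    sem = (
        means.std(axis=0, ddof=1) / np.sqrt(len(psths))
        if len(psths) > 1
        else np.zeros(mean.shape)
    )
    return PSTH(bin_edges_ms=edges, rates=means, mean=mean, sem=sem)


def trial_anchors(
    session: Session,
    trials: Sequence[Trial],
    anchor,
) -> tuple[list[float], list[Trial]]:
    """Anchor timestamps (and the trials that have them) for PSTH building."""
    epoch = EpochDefinition(anchor, 0, 1)
    out_t, out_tr = [], []
    for tr in trials:
        t = epoch.anchor_time(tr)
        if t is not None:
            out_t.append(t)
            out_tr.append(tr)
    return out_t, out_tr
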