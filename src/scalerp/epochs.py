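"""Conventional ERP machinery: epoching, baselining, rejection, averaging.

Also provides variable-duration (cue -> response) interval epochs used by the
scaling-index and PCA analyses; those are stored ragged, one array per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ContinuousRecording, resize_box, round_half_up, trial_intervals

__all__ = [
    "EpochSet",
    "ErpAverage",
    "epoch",
    "reject_epochs",
    "average",
    "epoch_intervals",
    "stretch_and_average",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """trials x channels x time epochs with per-trial metadata.

    Rejected trials keep their metadata (``kept=False``) but are excluded from
    every average.
    """

    data: np.ndarray
    times_ms: np.ndarray
    window: tuple[float, float]
    baseline: tuple[float, float] | None
    trial_meta: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return self.trial_meta["kept"].to_numpy(dtype=bool)


@dataclass
class ErpAverage:
    mean: np.ndarray  # channels x time
    n_trials: int
    condition: str


def epoch(
    recording: ContinuousRecording,
    events: pd.DataFrame,
    window: tuple[float, float],
    baseline_mode: str = "pre_event",
    event_type: str | None = None,
    around_window_ms: tuple[float, float] = (-20.0, 20.0),
) -> EpochSet:
    """Slice per-event epochs over ``window=(pre_ms, post_ms)`` and baseline them.

    baseline_mode:
      * ``pre_event``    subtract the mean over [pre_ms, 0)
      * ``around_event`` subtract the mean over ``around_window_ms``
      * ``none``         raw slices

    Epochs truncated by the recording edge are dropped (logged).
    """
    pre_ms, post_ms = window
    if not post_ms > pre_ms:
        raise ValueError("window post must exceed pre")
    if baseline_mode not in ("pre_event", "around_event", "none"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    fs = recording.fs
    ev = events if event_type is None else events[events["type"] == event_type]
    if len(ev) == 0:
        logger.warning("no events of type %r; empty epoch set", event_type)
    n_time = int(round((post_ms - pre_ms) * fs / 1000.0))
    pre_samp = int(round_half_up(pre_ms * fs / 1000.0))
    times_ms = pre_ms + np.arange(n_time) * 1000.0 / fs

    slices, meta = [], []
    for row in ev.itertuples():
        start = int(row.sample) + pre_samp
        stop = start + n_time
        if start < 0 or stop > recording.n_samples:
            logger.info("dropping truncated epoch at sample %d", row.sample)
            continue
        slices.append(recording.data[:, start:stop])
        meta.append(
            {
                "trial_id": getattr(row, "trial_id", None),
                "condition": getattr(row, "condition", ""),
                "response_time_s": getattr(row, "response_time_s", np.nan),
                "kept": True,
            }
        )
    data = (
        np.stack(slices) if slices
        else np.empty((0, recording.n_channels, n_time))
    )
    baseline = None
    if baseline_mode == "pre_event":
        baseline = (pre_ms, 0.0)
    elif baseline_mode == "around_event":
        baseline = around_window_ms
    if baseline is not None and data.size:
        sel = (times_ms >= baseline[0]) & (times_ms < baseline[1])
        if not sel.any():
            raise ValueError("baseline window contains no samples")
        data = data - data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        times_ms=times_ms,
        window=window,
        baseline=baseline,
        trial_meta=pd.DataFrame(meta) if meta else pd.DataFrame(
            columns=["trial_id", "condition", "response_time_s", "kept"]
        ),
    )


def reject_epochs(epochs: EpochSet, step_uv: float = 50.0, range_uv: float = 150.0) -> EpochSet:
    """Mark a trial ``kept=False`` if on any channel a consecutive-sample step
    exceeds ``step_uv`` or the epoch peak-to-peak exceeds ``range_uv``."""
    if step_uv <= 0 or range_uv <= 0:
        raise ValueError("thresholds must be positive")
    meta = epochs.trial_meta.copy()
    if epochs.data.size:
        steps = np.abs(np.diff(epochs.data, axis=2)).max(axis=(1, 2))
        ranges = (epochs.data.max(axis=2) - epochs.data.min(axis=2)).max(axis=1)
        bad = (steps > step_uv) | (ranges > range_uv)
        meta["kept"] = meta["kept"].to_numpy(dtype=bool) & ~bad
    return EpochSet(
        data=epochs.data,
        times_ms=epochs.times_ms,
        window=epochs.window,
        baseline=epochs.baseline,
        trial_meta=meta,
    )


def average(epochs: EpochSet, by: str = "condition") -> list[ErpAverage]:
    """Arithmetic mean over kept trials per condition; empty conditions are
    omitted with a warning."""
    out: list[ErpAverage] = []
    meta = epochs.trial_meta
    for cond, grp in meta.groupby(by, sort=True):
        idx = grp.index[grp["kept"].astype(bool)].to_numpy()
        if idx.size == 0:
            logger.warning("condition %r has no kept trials; omitted", cond)
            continue
        out.append(
            ErpAverage(
                mean=epochs.data[idx].mean(axis=0),
                n_trials=int(idx.size),
                condition=str(cond),
            )
        )
    return out


def epoch_intervals(
    recording: ContinuousRecording,
    events: pd.DataFrame,
    start_event: str = "cue",
    end_event: str = "response",
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Ragged per-trial interval slices (channels x D_i) from start to end event."""
    trials = trial_intervals(events, start_event, end_event)
    slices, keep = [], []
    for t in trials.itertuples():
        if t.start_sample < 0 or t.end_sample > recording.n_samples:
            keep.append(False)
            slices.append(np.empty((recording.n_channels, 0)))
            continue
        keep.append(True)
        slices.append(recording.data[:, t.start_sample : t.end_sample])
    meta = trials.copy()
    meta["kept"] = keep
    return slices, meta


def stretch_and_average(
    slices: list[np.ndarray],
    meta: pd.DataFrame,
    common_length: int,
    by: str = "condition",
) -> dict[str, np.ndarray]:
    """Stretch each trial to ``common_length`` (box kernel) then average per
    condition (stretch first, then average)."""
    if common_length < 1:
        raise ValueError("common_length must be >= 1")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for sl, row in zip(slices, meta.itertuples()):
        if not row.kept or sl.shape[1] < 1:
            continue
        W = resize_box(sl.shape[1], common_length)
        stretched = sl @ W.T  # channels x common_length
        cond = str(getattr(row, by))
        if cond not in sums:
            sums[cond] = np.zeros_like(stretched)
            counts[cond] = 0
        sums[cond] += stretched
        counts[cond] += 1
    return {c: sums[c] / counts[c] for c in sums}
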