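"""Convolutional design matrices with fixed-lag and scaled-time regressor blocks.

The design matrix has one row per EEG sample and one column per estimated
waveform point.  Fixed-time blocks hold unit stick functions at millisecond
lags relative to an event; the scaled-time block holds a single basis whose
temporal support is stretched or compressed (box-kernel resampling) to span
each trial's variable interval, so its columns are indexed by elapsed
fraction rather than wall-clock time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ContinuousRecording",
    "FixedWindowSpec",
    "ScaledSpec",
    "DesignBlock",
    "DesignMatrix",
    "SampleMask",
    "round_half_up",
    "resize_box",
    "build_fixed_block",
    "build_scaled_block",
    "flag_artifact_samples",
    "exclude_response_trials",
    "assemble_and_mask",
    "build_design",
    "validate_events",
    "trial_intervals",
]

#: upper bound on total predictor count; beyond this the normal equations
#: become impractically large for a desk-scale fit
MAX_PREDICTORS = 20_000


def round_half_up(x) -> np.ndarray:
    """Round to the nearest integer with .5 going up (toward +inf)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class ContinuousRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FixedWindowSpec:
    """Fixed-lag window ``[pre_ms, post_ms)`` relative to events of one type."""

    component: str
    pre_ms: float
    post_ms: float

    def __post_init__(self):
        if not self.post_ms > self.pre_ms:
            raise ValueError("post_ms must exceed pre_ms")

    def n_columns(self, fs: float) -> int:
        return int(round((self.post_ms - self.pre_ms) * fs / 1000.0))


@dataclass(frozen=True)
class ScaledSpec:
    """Scaled-time basis: ``n_points`` columns spanning start_event -> end_event."""

    n_points: int
    start_event: str = "cue"
    end_event: str = "response"

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass
class DesignBlock:
    X: sp.csr_matrix
    columns: pd.DataFrame  # component, lag_ms, elapsed_fraction
    edge: np.ndarray | None = None  # bool per sample: row of a truncated window


@dataclass
class DesignMatrix:
    """Assembled design: sparse ``X`` plus per-column metadata and row mapping."""

    X: sp.csr_matrix
    columns: pd.DataFrame
    row_index: np.ndarray  # surviving original sample indices
    fs: float | None = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def component_columns(self, component: str) -> np.ndarray:
        return np.flatnonzero((self.columns["component"] == component).to_numpy())

    def fixed_columns(self) -> np.ndarray:
        return np.flatnonzero((self.columns["component"] != "scaled").to_numpy())

    def scaled_columns(self) -> np.ndarray:
        return self.component_columns("scaled")

    def block_boundaries(self) -> list[int]:
        comps = self.columns["component"].to_numpy()
        return [0] + [i for i in range(1, len(comps)) if comps[i] != comps[i - 1]]

    def restrict(self, cols: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X[:, cols].tocsr(),
            columns=self.columns.iloc[cols].reset_index(drop=True),
            row_index=self.row_index,
            fs=self.fs,
        )


@dataclass
class SampleMask:
    """Per-sample keep flags with a reason label for every excluded sample."""

    keep: np.ndarray
    reasons: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.reasons is None:
            self.reasons = np.full(self.keep.shape, "", dtype="<U16")
        if self.reasons.shape != self.keep.shape:
            raise ValueError("reasons must align with keep")

    @classmethod
    def all_true(cls, n_samples: int) -> "SampleMask":
        return cls(np.ones(n_samples, dtype=bool))

    def exclude(self, idx, reason: str) -> None:
        idx = np.asarray(idx)
        newly = idx[self.keep[idx]] if idx.size else idx
        self.keep[idx] = False
        self.reasons[newly] = reason

    def combine(self, other: "SampleMask") -> "SampleMask":
        if other.keep.shape != self.keep.shape:
            raise ValueError("mask length mismatch")
        keep = self.keep & other.keep
        reasons = np.where(self.reasons != "", self.reasons, other.reasons)
        reasons = np.where(keep, "", reasons)
        return SampleMask(keep, reasons)

    @property
    def n_excluded(self) -> int:
        return int((~self.keep).sum())


# ---------------------------------------------------------------------------
# event-table validation
# ---------------------------------------------------------------------------

REQUIRED_EVENT_COLUMNS = ("type", "sample", "trial_id")


def validate_events(
    events: pd.DataFrame,
    n_samples: int | None = None,
    start_event: str = "cue",
    end_event: str = "response",
) -> pd.DataFrame:
    """Check event-table invariants (pairing, ordering, bounds); return sorted copy."""
    for col in REQUIRED_EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event table missing required column {col!r}")
    ev = events.sort_values("sample", kind="stable").reset_index(drop=True)
    if n_samples is not None:
        out = (ev["sample"] < 0) | (ev["sample"] >= n_samples)
        if out.any():
            raise ValueError(
                f"{int(out.sum())} event samples outside recording bounds [0, {n_samples})"
            )
    bad: list = []
    for trial_id, grp in ev.groupby("trial_id"):
        starts = grp[grp["type"] == start_event]
        ends = grp[grp["type"] == end_event]
        if len(starts) != 1 or len(ends) != 1:
            bad.append(trial_id)
        elif not ends["sample"].iloc[0] > starts["sample"].iloc[0]:
            bad.append(trial_id)
    if bad:
        raise ValueError(
            f"trials with missing/duplicated/unordered {start_event}/{end_event} "
            f"events: {sorted(bad)}"
        )
    return ev


def trial_intervals(
    events: pd.DataFrame, start_event: str = "cue", end_event: str = "response"
) -> pd.DataFrame:
    """One row per trial: trial_id, start_sample, end_sample, condition, response_time_s."""
    rows = []
    for trial_id, grp in events.groupby("trial_id"):
        start = grp.loc[grp["type"] == start_event, "sample"]
        end = grp.loc[grp["type"] == end_event, "sample"]
        if len(start) != 1 or len(end) != 1:
            raise ValueError(f"trial {trial_id!r} lacks a {start_event}/{end_event} pair")
        rows.append(
            {
                "trial_id": trial_id,
                "start_sample": int(start.iloc[0]),
                "end_sample": int(end.iloc[0]),
                "condition": grp["condition"].iloc[0] if "condition" in grp else "",
                "response_time_s": (
                    grp["response_time_s"].dropna().iloc[0]
                    if "response_time_s" in grp and grp["response_time_s"].notna().any()
                    else np.nan
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values("start_sample").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# block builders
# ---------------------------------------------------------------------------


def build_fixed_block(
    events: pd.DataFrame,
    window: FixedWindowSpec,
    n_samples: int,
    fs: float,
) -> DesignBlock:
    """Stick-function block: column j is 1 at ``event_sample + pre + j`` per event.

    Events whose window exceeds the recording keep their in-range entries;
    the affected rows are flagged ``edge`` in the returned block.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    ev = events
    if "type" in ev.columns and (ev["type"] == window.component).any():
        ev = ev[ev["type"] == window.component]
    samples = ev["sample"].to_numpy(dtype=int)
    n_cols = window.n_columns(fs)
    pre_samp = int(round_half_up(window.pre_ms * fs / 1000.0))
    lags_ms = window.pre_ms + np.arange(n_cols) * 1000.0 / fs

    rows = samples[:, None] + pre_samp + np.arange(n_cols)[None, :]
    cols = np.broadcast_to(np.arange(n_cols)[None, :], rows.shape)
    valid = (rows >= 0) & (rows < n_samples)

    edge = np.zeros(n_samples, dtype=bool)
    truncated = ~valid.all(axis=1)
    if truncated.any():
        for i in np.flatnonzero(truncated):
            edge[rows[i][valid[i]]] = True

    X = sp.coo_matrix(
        (np.ones(int(valid.sum())), (rows[valid], cols[valid])),
        shape=(n_samples, n_cols),
    ).tocsr()
    columns = pd.DataFrame(
        {
            "component": window.component,
            "lag_ms": lags_ms,
            "elapsed_fraction": np.nan,
        }
    )
    return DesignBlock(X=X, columns=columns, edge=edge)


def resize_box(basis_len: int, target_len: int) -> np.ndarray:
    """Area-averaging (box-kernel) resampling matrix, ``target_len x basis_len``.

    Entry (d, j) is the fractional overlap of target bin d with basis bin j on
    the unit interval, scaled so every row sums to exactly 1.  Applying it to a
    basis-length vector yields its piecewise-constant stretch/compression.
    """
    if basis_len < 1 or target_len < 1:
        raise ValueError("basis_len and target_len must be >= 1")
    d = np.arange(target_len, dtype=float)
    j = np.arange(basis_len, dtype=float)
    lo = np.maximum(d[:, None] / target_len, j[None, :] / basis_len)
    hi = np.minimum((d[:, None] + 1) / target_len, (j[None, :] + 1) / basis_len)
    W = np.clip(hi - lo, 0.0, None) * target_len
    # kill round-off dust so sparsity is exact
    W[W < 1e-15] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def build_scaled_block(
    events: pd.DataFrame,
    spec: ScaledSpec,
    n_samples: int,
) -> DesignBlock:
    """Shared scaled-time basis: rows [start, start+D) of each trial receive
    ``resize_box(spec.n_points, D)``; columns are elapsed-fraction indexed."""
    trials = trial_intervals(events, spec.start_event, spec.end_event)
    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    data_acc: list[np.ndarray] = []
    for t in trials.itertuples():
        D = t.end_sample - t.start_sample
        if D < 2:
            raise ValueError(
                f"trial {t.trial_id!r}: interval of {D} samples is too short (< 2)"
            )
        if t.start_sample < 0 or t.end_sample > n_samples:
            raise ValueError(f"trial {t.trial_id!r}: interval outside recording")
        W = resize_box(spec.n_points, D)
        r, c = np.nonzero(W)
        rows_acc.append(r + t.start_sample)
        cols_acc.append(c)
        data_acc.append(W[r, c])
    if rows_acc:
        X = sp.coo_matrix(
            (np.concatenate(data_acc), (np.concatenate(rows_acc), np.concatenate(cols_acc))),
            shape=(n_samples, spec.n_points),
        ).tocsr()
    else:
        X = sp.csr_matrix((n_samples, spec.n_points))
    columns = pd.DataFrame(
        {
            "component": "scaled",
            "lag_ms": np.nan,
            "elapsed_fraction": (np.arange(spec.n_points) + 0.5) / spec.n_points,
        }
    )
    return DesignBlock(X=X, columns=columns)


# ---------------------------------------------------------------------------
# sample exclusion
# ---------------------------------------------------------------------------


def flag_artifact_samples(
    recording: ContinuousRecording,
    threshold_uv: float = 150.0,
    window_ms: float = 2000.0,
    step_ms: float = 1000.0,
) -> SampleMask:
    """Moving-window peak-to-peak artifact detector on the continuous signal.

    Any window whose peak-to-peak amplitude exceeds ``threshold_uv`` on any
    channel flags all of its samples; one shared mask across channels.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    if not (window_ms >= step_ms > 0):
        raise ValueError("require window_ms >= step_ms > 0")
    n = recording.n_samples
    win = max(1, int(round(window_ms * recording.fs / 1000.0)))
    step = max(1, int(round(step_ms * recording.fs / 1000.0)))
    mask = SampleMask.all_true(n)
    flagged = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        stop = min(start + win, n)
        seg = recording.data[:, start:stop]
        ptp = seg.max(axis=1) - seg.min(axis=1)
        if (ptp > threshold_uv).any():
            flagged[start:stop] = True
        if stop == n:
            break
        start += step
    mask.exclude(np.flatnonzero(flagged), "artifact")
    return mask


def exclude_response_trials(
    events: pd.DataFrame,
    min_rt_s: float,
    max_rt_s: float,
    n_samples: int,
    start_event: str = "cue",
    end_event: str = "response",
) -> tuple[SampleMask, pd.DataFrame]:
    """Mask interval samples of trials with out-of-bounds response times and
    drop those trials' events from the table."""
    if not min_rt_s < max_rt_s:
        raise ValueError("min_rt_s must be < max_rt_s")
    mask = SampleMask.all_true(n_samples)
    if "response_time_s" not in events.columns:
        return mask, events
    trials = trial_intervals(events, start_event, end_event)
    rt = trials["response_time_s"].to_numpy(dtype=float)
    bad = np.isfinite(rt) & ((rt < min_rt_s) | (rt > max_rt_s))
    bad_ids = set(trials.loc[bad, "trial_id"])
    for t in trials[bad].itertuples():
        mask.exclude(np.arange(t.start_sample, t.end_sample), "bad_rt")
    filtered = events[~events["trial_id"].isin(bad_ids)].reset_index(drop=True)
    return mask, filtered


def assemble_and_mask(
    blocks: Sequence[DesignBlock],
    recording: ContinuousRecording,
    mask: SampleMask | None = None,
) -> tuple[DesignMatrix, np.ndarray]:
    """Concatenate blocks column-wise, drop masked rows from X and Y alike."""
    n = recording.n_samples
    for b in blocks:
        if b.X.shape[0] != n:
            raise ValueError("block row count differs from recording length")
    if mask is None:
        mask = SampleMask.all_true(n)
    total_cols = sum(b.X.shape[1] for b in blocks)
    if total_cols > MAX_PREDICTORS:
        raise ValueError(
            f"{total_cols} predictors exceeds cap {MAX_PREDICTORS}; "
            "use fewer scaled points or shorter fixed windows"
        )
    X = sp.hstack([b.X for b in blocks], format="csr")
    columns = pd.concat([b.columns for b in blocks], ignore_index=True)
    row_index = np.flatnonzero(mask.keep)
    Xm = X[row_index]
    Y = recording.data[:, row_index]
    dm = DesignMatrix(X=Xm, columns=columns, row_index=row_index, fs=recording.fs)
    assert dm.X.shape[0] == Y.shape[1]
    return dm, Y


def build_design(
    recording: ContinuousRecording,
    events: pd.DataFrame,
    fixed_windows: Sequence[FixedWindowSpec],
    scaled_spec: ScaledSpec | None = None,
    mask: SampleMask | None = None,
) -> tuple[DesignMatrix, np.ndarray]:
    """Convenience: validate events, build all blocks, assemble, mask."""
    end_event = scaled_spec.end_event if scaled_spec is not None else "response"
    start_event = scaled_spec.start_event if scaled_spec is not None else "cue"
    ev = validate_events(events, recording.n_samples, start_event, end_event)
    blocks = [
        build_fixed_block(ev, w, recording.n_samples, recording.fs)
        for w in fixed_windows
    ]
    if scaled_spec is not None:
        blocks.append(build_scaled_block(ev, scaled_spec, recording.n_samples))
    return assemble_and_mask(blocks, recording, mask)
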