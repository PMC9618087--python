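"""File formats, run configuration, and provenance logging.

Native interchange = a ``.npy`` matrix (channels x samples, microvolts) next
to a ``.json`` sidecar carrying the sampling rate, channel labels, and units.
Events travel as BIDS-style TSV (onset in seconds).  BrainVision / EDF /
EEGLAB readers are thin adapters delegated to ``mne`` when it is installed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ContinuousRecording, round_half_up, validate_events
from .solver import DEFAULT_LAMBDA_GRID

__all__ = [
    "RunConfig",
    "RunLog",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "write_dataset",
]

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def _native_paths(path: str | Path) -> tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix in (".npy", ".json"):
        stem = stem.with_suffix("")
    return stem.with_suffix(".npy"), stem.with_suffix(".json")


def write_recording(path: str | Path, recording: ContinuousRecording) -> None:
    """Native container: ``<stem>.npy`` + ``<stem>.json`` sidecar (units uV)."""
    mat, sidecar = _native_paths(path)
    np.save(mat, recording.data)
    sidecar.write_text(
        json.dumps(
            {
                "fs": recording.fs,
                "channel_labels": list(recording.channel_labels),
                "units": "uV",
            },
            indent=2,
        )
    )


def read_recording(path: str | Path, format: str = "native") -> ContinuousRecording:
    """Read continuous EEG; non-native formats are delegated to ``mne``."""
    if format == "native":
        mat, sidecar = _native_paths(path)
        if not mat.exists() or not sidecar.exists():
            raise FileNotFoundError(f"native recording needs {mat} and {sidecar}")
        meta = json.loads(sidecar.read_text())
        units = meta.get("units", "uV")
        if units not in ("uV", "microvolt", "microvolts"):
            raise ValueError(
                f"sidecar units are {units!r}; convert to uV explicitly "
                "(no silent rescaling)"
            )
        return ContinuousRecording(
            data=np.load(mat),
            fs=float(meta["fs"]),
            channel_labels=list(meta["channel_labels"]),
        )
    if format in ("brainvision", "edf", "eeglab_set"):
        try:
            import mne  # delegated reader; optional dependency
        except ImportError as err:
            raise ImportError(
                f"reading {format} files requires the optional 'mne' package"
            ) from err
        readers = {
            "brainvision": mne.io.read_raw_brainvision,
            "edf": mne.io.read_raw_edf,
            "eeglab_set": mne.io.read_raw_eeglab,
        }
        raw = readers[format](str(path), preload=True, verbose="error")
        return ContinuousRecording(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def read_events(path: str | Path, fs: float) -> pd.DataFrame:
    """BIDS-events-style TSV -> validated event table.

    Requires columns ``onset`` (seconds) and ``trial_type``; optional
    ``trial_id``, ``response_time``.  Onsets convert to 0-based samples by
    round-half-up.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"events TSV missing required column {col!r}")
    out = pd.DataFrame(
        {
            "event_id": np.arange(len(df)),
            "type": df["trial_type"],
            "sample": round_half_up(df["onset"].to_numpy(dtype=float) * fs),
            "trial_id": df["trial_id"] if "trial_id" in df else np.arange(len(df)),
            "condition": df["condition"] if "condition" in df else "",
            "response_time_s": (
                df["response_time"].astype(float)
                if "response_time" in df
                else np.nan
            ),
        }
    )
    return validate_events(out)


def write_events(path: str | Path, events: pd.DataFrame, fs: float) -> None:
    out = pd.DataFrame(
        {
            "onset": events["sample"].to_numpy(dtype=float) / fs,
            "duration": 0.0,
            "trial_type": events["type"],
            "trial_id": events["trial_id"],
            "condition": events.get("condition", ""),
            "response_time": events.get("response_time_s", np.nan),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and provenance
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through JSON."""

    fs: float = 200.0
    cue_window_ms: tuple[float, float] = (-200.0, 800.0)
    response_window_ms: tuple[float, float] = (-800.0, 200.0)
    scaled_n_points: int = 330
    start_event: str = "cue"
    end_event: str = "response"
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 10
    cv_scheme: str = "contiguous"
    target_channel: str | int = 0
    artifact_threshold_uv: float = 150.0
    artifact_window_ms: float = 2000.0
    artifact_step_ms: float = 1000.0
    rt_bounds_s: tuple[float, float] = (0.2, 5.0)
    electrodes: tuple[str, ...] = ()
    neighbor_graph_path: str | None = None
    n_permutations: int = 1000
    alpha_cell: float = 0.05
    alpha_cluster: float = 0.05
    n_rt_bins: int = 3
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        obj = cls(**raw)
        # JSON turns tuples into lists; normalize back
        for f in dataclasses.fields(cls):
            v = getattr(obj, f.name)
            if isinstance(v, list):
                setattr(obj, f.name, tuple(v))
        return obj

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


class RunLog:
    """Timestamped stage messages; every stochastic stage must log its seed."""

    def __init__(self, seed: int | None = None):
        self.messages: list[str] = []
        self.seed = seed
        self.log(f"scalerp version {__version__}")
        if seed is not None:
            self.log(f"seed {seed}")

    def log(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.messages.append(f"{stamp} {message}")

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.messages) + "\n")


def write_dataset(out_dir: str | Path, dataset) -> None:
    """GroundTruthDataset -> native recording + events TSV + config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_recording(out / "recording", dataset.recording)
    write_events(out / "events.tsv", dataset.events, dataset.recording.fs)
    (out / "simulation_config.json").write_text(
        json.dumps(dataset.config.to_dict(), indent=2)
    )
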