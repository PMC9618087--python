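"""Synthetic continuous EEG with known fixed-time and scaled-time components.

Each trial inserts a cue-locked transient, a response-locked transient, and a
single template that is stretched or compressed (box-kernel resampling) to
span the variable cue->response interval.  The generator returns the exact
per-component contributions so closed-loop recovery tests have ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import ContinuousRecording, resize_box, round_half_up

__all__ = [
    "ComponentShape",
    "SimulationConfig",
    "GroundTruthDataset",
    "default_shapes",
    "simulate_dataset",
]

CONDITION_NAMES = ("short", "medium", "long")


@dataclass
class ComponentShape:
    """A named waveform: fixed shapes carry a (pre_ms, post_ms) span, the
    scaled shape a unit-interval template."""

    name: str
    waveform: np.ndarray
    span: tuple[float, float] | None = None  # (pre_ms, post_ms); None => scaled

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError(f"component {self.name!r}: non-finite waveform")

    @property
    def n_points(self) -> int:
        return self.waveform.size


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Single raised-cosine bump supported on [center - width/2, center + width/2]."""
    x = (t - center) / width
    out = np.zeros_like(t)
    inside = np.abs(x) < 0.5
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside]))
    return out


def default_shapes(fs: float, n_scaled: int) -> dict[str, ComponentShape]:
    """Three smooth, visually distinct shapes (sums of raised cosines).

    * cue: biphasic transient on (-200, 800) ms
    * response: ramp-plus-peak on (-800, 200) ms
    * scaled: slow negative half-cycle template of ``n_scaled`` points

    All shapes are zero-mean over their support and bounded by 20 uV.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_scaled < 2:
        raise ValueError("n_scaled must be >= 2")

    n_fixed = int(round(1.0 * fs))  # 1,000 ms window
    t_cue = (-200.0 + np.arange(n_fixed) * 1000.0 / fs) / 1000.0  # seconds
    cue = (
        8.0 * _raised_cosine(t_cue, 0.12, 0.18)
        - 10.0 * _raised_cosine(t_cue, 0.32, 0.30)
        + 4.0 * _raised_cosine(t_cue, 0.55, 0.35)
    )

    t_resp = (-800.0 + np.arange(n_fixed) * 1000.0 / fs) / 1000.0
    ramp = np.clip((t_resp + 0.6) / 0.6, 0.0, 1.0) ** 2
    resp = -6.0 * ramp * _raised_cosine(t_resp, -0.05, 1.1) + 9.0 * _raised_cosine(
        t_resp, 0.05, 0.22
    )

    u = (np.arange(n_scaled) + 0.5) / n_scaled
    scaled = -7.0 * np.sin(np.pi * u) ** 1.5

    shapes = {
        "cue": ComponentShape("cue", cue - cue.mean(), (-200.0, 800.0)),
        "response": ComponentShape("response", resp - resp.mean(), (-800.0, 200.0)),
        "scaled": ComponentShape("scaled", scaled - scaled.mean(), None),
    }
    for s in shapes.values():
        assert np.max(np.abs(s.waveform)) <= 20.0
    return shapes


@dataclass
class SimulationConfig:
    fs: float = 200.0
    interval_durations: tuple[float, ...] = (0.8, 1.65, 2.5)
    trials_per_condition: int = 50
    inter_trial_gap: tuple[float, float] = (0.8, 1.6)
    noise_model: str = "ar1"  # "white" | "ar1"
    noise_amplitude: float | str = 1.0  # RMS in uV, or "signal_rms"
    ar_coef: float = 0.95
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for d in self.interval_durations):
            raise ValueError("interval durations must be positive")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if isinstance(self.noise_amplitude, str):
            if self.noise_amplitude != "signal_rms":
                raise ValueError("noise_amplitude must be a float or 'signal_rms'")
        elif self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError("noise_model must be 'white' or 'ar1'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthDataset:
    recording: ContinuousRecording
    events: pd.DataFrame
    truth_components: dict[str, ComponentShape]
    truth_series: dict[str, np.ndarray]  # single-channel contribution per component
    topographies: dict[str, np.ndarray]  # per-channel mixing weight per component
    noise: np.ndarray
    config: SimulationConfig

    def truth_contribution(self, name: str) -> np.ndarray:
        """Per-channel continuous contribution (channels x samples) of one component."""
        return np.outer(self.topographies[name], self.truth_series[name])

    def total_signal(self) -> np.ndarray:
        return sum(self.truth_contribution(k) for k in self.truth_series)


def _truncated_normal(rng: np.random.Generator, sd: float, n_max: int = 1000) -> float:
    """Gaussian draw truncated at +/- 3 SD (redraw)."""
    if sd == 0:
        return 0.0
    for _ in range(n_max):
        x = rng.normal(0.0, sd)
        if abs(x) <= 3.0 * sd:
            return x
    return 0.0


def _make_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, config: SimulationConfig,
    amplitude: float,
) -> np.ndarray:
    if amplitude == 0:
        return np.zeros((n_channels, n_samples))
    w = rng.standard_normal((n_channels, n_samples))
    if config.noise_model == "ar1":
        w = lfilter([1.0], [1.0, -config.ar_coef], w, axis=1)
    rms = np.sqrt(np.mean(w**2, axis=1, keepdims=True))
    return w / rms * amplitude


def simulate_dataset(
    config: SimulationConfig,
    shapes: dict[str, ComponentShape] | None = None,
    n_channels: int = 1,
) -> GroundTruthDataset:
    """Generate a seeded continuous recording plus its exact decomposition.

    Channel 0 carries every component at unit weight (the "target" channel);
    the remaining channels get per-component mixing weights drawn once from
    U(0.4, 1.2), recorded in ``topographies``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    if shapes is None:
        shapes = default_shapes(fs, 330)
    for name in ("cue", "response", "scaled"):
        if name not in shapes:
            raise ValueError(f"shapes must include {name!r}")
    cue, resp, scaled = shapes["cue"], shapes["response"], shapes["scaled"]

    n_cond = len(config.interval_durations)
    cond_names = (
        list(CONDITION_NAMES)
        if n_cond == 3
        else [f"cond{i}" for i in range(n_cond)]
    )

    # randomized trial order over conditions
    cond_idx = np.repeat(np.arange(n_cond), config.trials_per_condition)
    rng.shuffle(cond_idx)

    cue_pre = int(round_half_up(-cue.span[0] * fs / 1000.0))  # samples before cue
    cue_post = int(round_half_up(cue.span[1] * fs / 1000.0))
    resp_pre = int(round_half_up(-resp.span[0] * fs / 1000.0))
    resp_post = int(round_half_up(resp.span[1] * fs / 1000.0))
    margin = max(cue_pre, resp_pre) + 2

    # place trials sequentially; gaps guarantee no cross-trial overlap
    cue_samples, resp_samples, durations_s = [], [], []
    cursor = margin
    for ci in cond_idx:
        dur = config.interval_durations[ci] + _truncated_normal(rng, config.jitter_sd)
        D = int(round(dur * fs))
        if D < 2:
            raise ValueError(
                f"interval of {D} samples too short; increase duration or fs"
            )
        gap = rng.uniform(*config.inter_trial_gap)
        cue_s = cursor + cue_pre
        cue_samples.append(cue_s)
        resp_samples.append(cue_s + D)
        durations_s.append(D / fs)
        cursor = cue_s + D + resp_post + int(round(gap * fs)) + cue_pre

    n_samples = resp_samples[-1] + resp_post + int(round(1.0 * fs))

    series = {k: np.zeros(n_samples) for k in ("cue", "response", "scaled")}
    for cue_s, resp_s in zip(cue_samples, resp_samples):
        series["cue"][cue_s - cue_pre : cue_s + cue_post] += cue.waveform
        series["response"][resp_s - resp_pre : resp_s + resp_post] += resp.waveform
        D = resp_s - cue_s
        W = resize_box(scaled.n_points, D)
        series["scaled"][cue_s:resp_s] += W @ scaled.waveform

    topographies = {}
    for name in ("cue", "response", "scaled"):
        w = np.empty(n_channels)
        w[0] = 1.0
        if n_channels > 1:
            w[1:] = rng.uniform(0.4, 1.2, size=n_channels - 1)
        topographies[name] = w

    signal = sum(np.outer(topographies[k], series[k]) for k in series)

    amp = config.noise_amplitude
    if amp == "signal_rms":
        amp = float(np.sqrt(np.mean(signal**2)))
    noise = _make_noise(rng, n_channels, n_samples, config, float(amp))

    recording = ContinuousRecording(
        data=signal + noise,
        fs=fs,
        channel_labels=[f"CH{i}" for i in range(n_channels)],
    )

    rows = []
    for t, (cue_s, resp_s, ci) in enumerate(zip(cue_samples, resp_samples, cond_idx)):
        rt = (resp_s - cue_s) / fs
        rows.append(
            dict(event_id=2 * t, type="cue", sample=cue_s, trial_id=t,
                 condition=cond_names[ci], response_time_s=rt)
        )
        rows.append(
            dict(event_id=2 * t + 1, type="response", sample=resp_s, trial_id=t,
                 condition=cond_names[ci], response_time_s=rt)
        )
    events = pd.DataFrame(rows)

    return GroundTruthDataset(
        recording=recording,
        events=events,
        truth_components=shapes,
        truth_series=series,
        topographies=topographies,
        noise=noise,
        config=config,
    )
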