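"""Synthetic cochlear-implant recording sessions.

A MED-EL-style implant can record auditory-nerve activity in short telemetry
windows: 1.7 ms of sampling at 1.2 MHz (2048 points) followed by a 13.68 ms
reset, i.e. about 65 windows per second.  During a silent 1 s cue-target
interval of a crossmodal attention task this yields, after window averaging,
a 65-sample / 65 Hz time series per trial.

This module simulates complete sessions of that experiment: the 6-block x
85-trial design with 43 auditory and 42 visual cues per block, 8 + 8
independently drawn oddball trials, the per-window Gaussian recording offset,
the USB start jitter, a decaying filter-artifact prefix on every window, and
a latent 1 s process consisting of broadband noise plus a theta-band (5-8 Hz)
oscillation whose amplitude is raised on attend-auditory trials.  The latent
per-trial theta amplitudes are retained as ground truth so downstream
estimators can be validated against the generating process.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from ._rng import STAGE_BEHAVIOR, STAGE_EEG, STAGE_SESSION, child_rng

__all__ = [
    "SessionConfig",
    "EffectSpec",
    "RawTrial",
    "Session",
    "EEGCompanion",
    "generate_session",
    "simulate_behavior",
    "generate_eeg_companion",
    "metadata_frame",
    "save_session",
    "load_session",
    "config_from_mapping",
]

AUDITORY = "auditory"
VISUAL = "visual"


@dataclass(frozen=True)
class SessionConfig:
    """Experimental-design and recording-hardware parameters.

    Defaults reproduce the published design: six 85-trial blocks with a
    43/42 auditory/visual cue split, 8 visual and 8 auditory oddballs drawn
    independently per block, 1.7 ms recording windows of 2048 samples
    followed by a 13.68 ms reset (65 windows over the 1 s interval), a
    per-window Gaussian offset of SD 0.4 mV and up to 27 ms of trial-start
    jitter.  ``latent_rate`` is a simulation fidelity knob: the rate (Hz) at
    which the latent 1 s process is synthesised before being sampled into
    windows.
    """

    n_blocks: int = 6
    trials_per_block: int = 85
    n_auditory_cues_per_block: int = 43
    n_visual_cues_per_block: int = 42
    n_visual_oddballs_per_block: int = 8
    n_auditory_oddballs_per_block: int = 8
    window_duration: float = 1.7  # ms
    reset_duration: float = 13.68  # ms
    samples_per_window: int = 2048
    n_windows_per_trial: int = 65
    offset_sd: float = 0.4  # mV
    start_jitter_max: float = 27.0  # ms
    artifact_prefix_len: int = 100
    artifact_amplitude: float = 5.0  # mV, peak of the decaying prefix artifact
    behavior_accuracy: float = 0.96
    latent_rate: float = 1040.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_blocks,
            self.trials_per_block,
            self.n_auditory_cues_per_block,
            self.n_visual_cues_per_block,
            self.samples_per_window,
            self.n_windows_per_trial,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if self.n_auditory_cues_per_block + self.n_visual_cues_per_block != self.trials_per_block:
            raise ValueError(
                f"cue counts {self.n_auditory_cues_per_block}+{self.n_visual_cues_per_block} "
                f"do not sum to trials_per_block={self.trials_per_block}"
            )
        if self.n_visual_oddballs_per_block > self.trials_per_block:
            raise ValueError("more visual oddballs than trials per block")
        if self.n_auditory_oddballs_per_block > self.trials_per_block:
            raise ValueError("more auditory oddballs than trials per block")
        if self.artifact_prefix_len >= self.samples_per_window:
            raise ValueError("artifact prefix must be shorter than the window")
        if not 0.0 <= self.behavior_accuracy <= 1.0:
            raise ValueError("behavior_accuracy must lie in [0, 1]")
        if self.trial_duration_ms < 999.0:
            raise ValueError("windows do not cover the 1 s cue-target interval")

    @property
    def window_period_ms(self) -> float:
        """Window start-to-start period: recording plus reset (ms)."""
        return self.window_duration + self.reset_duration

    @property
    def trial_duration_ms(self) -> float:
        return self.n_windows_per_trial * self.window_period_ms

    @property
    def sampling_rate(self) -> int:
        """Effective rate of the reconstructed series (Hz)."""
        return round(1000.0 / self.window_period_ms)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class EffectSpec:
    """Latent-signal parameters of the simulated attention effect.

    ``attend_auditory_gain`` multiplies the theta-band amplitude on
    attend-auditory trials; 1.0 is the null.  ``per_subject_gain_sd`` is the
    SD of a per-subject lognormal jitter on that gain (log scale).  The theta
    component is amplitude-modulated narrow-band noise, not a sinusoid, so
    simulated spectra are peakless like real low-SNR implant recordings.
    """

    theta_band: tuple[float, float] = (5.0, 8.0)
    base_theta_amplitude: float = 0.5  # mV (RMS of the narrow-band component)
    attend_auditory_gain: float = 1.2
    broadband_noise_sd: float = 0.5  # mV at the latent rate
    per_subject_gain_sd: float = 0.1  # lognormal sigma on the gain

    def __post_init__(self) -> None:
        lo, hi = self.theta_band
        if not 0 < lo < hi:
            raise ValueError("theta_band must be an increasing positive interval")
        if self.base_theta_amplitude < 0 or self.broadband_noise_sd < 0:
            raise ValueError("amplitudes and noise SDs must be non-negative")
        if self.attend_auditory_gain < 0 or self.per_subject_gain_sd < 0:
            raise ValueError("gains and gain SDs must be non-negative")


@dataclass
class RawTrial:
    """One trial's windowed recording plus its design metadata."""

    subject_id: str
    block: int
    trial_index: int
    cue: str  # "auditory" | "visual"
    is_auditory_oddball: bool
    is_visual_oddball: bool
    response_correct: bool
    start_jitter: float  # ms
    windows: np.ndarray  # (n_windows_per_trial, samples_per_window), mV


@dataclass
class Session:
    """A complete simulated session for one subject."""

    config: SessionConfig
    effect: EffectSpec
    subject_id: str
    trials: list[RawTrial]
    ground_truth: dict[int, float] = field(default_factory=dict)
    subject_gain: float = 1.0

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class EEGCompanion:
    """Simultaneously recorded multichannel series for one session.

    ``series`` has shape (n_trials, n_channels, n_samples) and is aligned
    with the reconstructed 65-sample CI series.  ``mixing[c]`` is the leakage
    coefficient of the shared latent source into channel ``c``; with an
    all-zero mixing no channel shares an instantaneous source with the CI
    signal.
    """

    n_channels: int
    series: np.ndarray
    mixing: np.ndarray
    source: np.ndarray  # (n_trials, n_samples) latent source


def _window_sample_times(config: SessionConfig) -> np.ndarray:
    """Trial-relative times (ms) of every sample, shape (windows, samples)."""
    fs_window = config.samples_per_window / config.window_duration  # samples/ms
    w_start = np.arange(config.n_windows_per_trial) * config.window_period_ms
    s_off = np.arange(config.samples_per_window) / fs_window
    return w_start[:, None] + s_off[None, :]


def _artifact(config: SessionConfig) -> np.ndarray:
    """Deterministic decaying filter artifact added to each window's prefix."""
    n = config.artifact_prefix_len
    tau = max(n / 5.0, 1.0)
    return config.artifact_amplitude * np.exp(-np.arange(n) / tau)


def _theta_sos(effect: EffectSpec, latent_rate: float):
    lo, hi = effect.theta_band
    return signal.butter(4, [lo, hi], btype="bandpass", fs=latent_rate, output="sos")


def _block_design(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cue and oddball assignment for one block (exact per-block counts)."""
    cues = np.array(
        [AUDITORY] * config.n_auditory_cues_per_block + [VISUAL] * config.n_visual_cues_per_block
    )
    rng.shuffle(cues)
    vis_odd = np.zeros(config.trials_per_block, dtype=bool)
    vis_odd[rng.choice(config.trials_per_block, config.n_visual_oddballs_per_block, replace=False)] = True
    # auditory oddballs are drawn independently; joint oddballs are possible
    aud_odd = np.zeros(config.trials_per_block, dtype=bool)
    aud_odd[rng.choice(config.trials_per_block, config.n_auditory_oddballs_per_block, replace=False)] = True
    return pd.DataFrame({"cue": cues, "is_visual_oddball": vis_odd, "is_auditory_oddball": aud_odd})


def generate_session(
    config: SessionConfig,
    effect: EffectSpec,
    subject_id: str = "S01",
    subject_key: int = 0,
) -> Session:
    """Simulate one subject's full session of windowed recordings.

    Each trial's latent signal is a continuous process spanning the jittered
    1 s interval: Gaussian broadband noise plus a theta-band component whose
    RMS amplitude is ``base_theta_amplitude`` times the (subject-jittered)
    ``attend_auditory_gain`` on auditory-cue trials and times 1 otherwise.
    The process is synthesised at ``config.latent_rate`` and linearly
    interpolated onto each window's 1.2 MHz sample times; an independent
    Gaussian offset is then added per window and a deterministic decaying
    artifact is written over the first ``artifact_prefix_len`` samples of
    every window.  Identical ``(config, effect, subject_key)`` gives
    bit-identical output.
    """
    rng = child_rng(config.seed, STAGE_SESSION, subject_key)

    # one multiplicative gain jitter per subject, on the log scale
    log_gain = np.log(effect.attend_auditory_gain) if effect.attend_auditory_gain > 0 else -np.inf
    subject_gain = float(np.exp(log_gain + effect.per_subject_gain_sd * rng.standard_normal()))

    latent_dur_ms = config.start_jitter_max + config.trial_duration_ms + config.window_duration
    n_latent = int(np.ceil(latent_dur_ms / 1000.0 * config.latent_rate)) + 2
    latent_t = np.arange(n_latent) / config.latent_rate * 1000.0  # ms
    sos = _theta_sos(effect, config.latent_rate)
    times = _window_sample_times(config)
    artifact = _artifact(config)

    trials: list[RawTrial] = []
    ground_truth: dict[int, float] = {}
    trial_index = 0
    for block in range(config.n_blocks):
        design = _block_design(config, rng)
        for _, row in design.iterrows():
            amp = effect.base_theta_amplitude * (subject_gain if row.cue == AUDITORY else 1.0)
            jitter = float(rng.uniform(0.0, config.start_jitter_max))

            latent = rng.normal(0.0, effect.broadband_noise_sd, n_latent) if effect.broadband_noise_sd > 0 else np.zeros(n_latent)
            if amp > 0:
                narrow = signal.sosfiltfilt(sos, rng.standard_normal(n_latent))
                sd = narrow.std()
                if sd > 0:
                    latent = latent + narrow * (amp / sd)

            windows = np.interp((times + jitter).ravel(), latent_t, latent).reshape(times.shape)
            windows += rng.normal(0.0, config.offset_sd, config.n_windows_per_trial)[:, None]
            windows[:, : config.artifact_prefix_len] += artifact

            trials.append(
                RawTrial(
                    subject_id=subject_id,
                    block=block,
                    trial_index=trial_index,
                    cue=str(row.cue),
                    is_auditory_oddball=bool(row.is_auditory_oddball),
                    is_visual_oddball=bool(row.is_visual_oddball),
                    response_correct=True,
                    start_jitter=jitter,
                    windows=windows,
                )
            )
            ground_truth[trial_index] = amp
            trial_index += 1

    return Session(
        config=config,
        effect=effect,
        subject_id=subject_id,
        trials=trials,
        ground_truth=ground_truth,
        subject_gain=subject_gain,
    )


def simulate_behavior(session: Session, accuracy: float | None = None, subject_key: int = 0) -> Session:
    """Mark each trial correct/incorrect with independent probability ``accuracy``.

    Returns a new :class:`Session` sharing trial window arrays (only the
    response flags differ).  ``accuracy`` defaults to the session config's
    ``behavior_accuracy``.
    """
    if accuracy is None:
        accuracy = session.config.behavior_accuracy
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rng = child_rng(session.config.seed, STAGE_BEHAVIOR, subject_key)
    correct = rng.random(len(session.trials)) < accuracy
    trials = [dataclasses.replace(t, response_correct=bool(c)) for t, c in zip(session.trials, correct)]
    return dataclasses.replace(session, trials=trials)


def generate_eeg_companion(
    session: Session,
    n_channels: int = 55,
    mixing: np.ndarray | float | None = None,
    noise_sd: float = 1.0,
    n_samples: int | None = None,
    source: np.ndarray | None = None,
    subject_key: int = 0,
) -> EEGCompanion:
    """Simulate multichannel scalp series accompanying the CI recordings.

    Each channel is independent Gaussian noise plus ``mixing[c]`` times a
    shared latent cortical source.  ``source`` may be supplied explicitly
    (shape ``(n_trials, n_samples)``), e.g. the reconstructed CI series to
    emulate genuine volume conduction; by default an independent source is
    drawn, so the CI signal and the companion share nothing instantaneous.
    """
    if n_samples is None:
        n_samples = session.config.n_windows_per_trial
    if mixing is None:
        mixing = np.zeros(n_channels)
    mixing = np.broadcast_to(np.asarray(mixing, dtype=float), (n_channels,)).copy()
    if mixing.shape != (n_channels,):
        raise ValueError("mixing must have one coefficient per channel")
    if n_channels <= 0:
        raise ValueError("channel count must be positive")

    rng = child_rng(session.config.seed, STAGE_EEG, subject_key)
    n_trials = len(session.trials)
    if source is None:
        source = rng.standard_normal((n_trials, n_samples))
    else:
        source = np.asarray(source, dtype=float)
        if source.shape != (n_trials, n_samples):
            raise ValueError(f"source must have shape {(n_trials, n_samples)}")
    noise = rng.normal(0.0, noise_sd, (n_trials, n_channels, n_samples)) if noise_sd > 0 else np.zeros((n_trials, n_channels, n_samples))
    series = noise + mixing[None, :, None] * source[:, None, :]
    return EEGCompanion(n_channels=n_channels, series=series, mixing=mixing, source=source)


def metadata_frame(session: Session) -> pd.DataFrame:
    """Tidy per-trial metadata table (one row per trial)."""
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in session.trials],
            "block": [t.block for t in session.trials],
            "trial_index": [t.trial_index for t in session.trials],
            "cue": [t.cue for t in session.trials],
            "is_auditory_oddball": [t.is_auditory_oddball for t in session.trials],
            "is_visual_oddball": [t.is_visual_oddball for t in session.trials],
            "response_correct": [t.response_correct for t in session.trials],
            "start_jitter": [t.start_jitter for t in session.trials],
        }
    )


_LAYOUT_VERSION = 1


def save_session(session: Session, directory: str | pathlib.Path) -> None:
    """Write a session as metadata TSV + an NPZ of windows keyed by trial index."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metadata_frame(session).to_csv(directory / "metadata.tsv", sep="\t", index=False)
    np.savez_compressed(
        directory / "windows.npz",
        **{f"trial_{t.trial_index:05d}": t.windows for t in session.trials},
    )
    meta = {
        "layout_version": _LAYOUT_VERSION,
        "subject_id": session.subject_id,
        "subject_gain": session.subject_gain,
        "config": dataclasses.asdict(session.config),
        "effect": dataclasses.asdict(session.effect),
        "ground_truth": {str(k): v for k, v in session.ground_truth.items()},
    }
    (directory / "session.json").write_text(json.dumps(meta, indent=1))


def load_session(directory: str | pathlib.Path) -> Session:
    """Read a session written by :func:`save_session`."""
    directory = pathlib.Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    if meta.get("layout_version") != _LAYOUT_VERSION:
        raise ValueError("unsupported session layout version")
    effect_kw = dict(meta["effect"])
    effect_kw["theta_band"] = tuple(effect_kw["theta_band"])
    config = SessionConfig(**meta["config"])
    effect = EffectSpec(**effect_kw)
    table = pd.read_csv(directory / "metadata.tsv", sep="\t")
    with np.load(directory / "windows.npz") as npz:
        trials = [
            RawTrial(
                subject_id=str(row.subject_id),
                block=int(row.block),
                trial_index=int(row.trial_index),
                cue=str(row.cue),
                is_auditory_oddball=bool(row.is_auditory_oddball),
                is_visual_oddball=bool(row.is_visual_oddball),
                response_correct=bool(row.response_correct),
                start_jitter=float(row.start_jitter),
                windows=npz[f"trial_{int(row.trial_index):05d}"],
            )
            for row in table.itertuples()
        ]
    return Session(
        config=config,
        effect=effect,
        subject_id=meta["subject_id"],
        trials=trials,
        ground_truth={int(k): float(v) for k, v in meta["ground_truth"].items()},
        subject_gain=float(meta["subject_gain"]),
    )


def config_from_mapping(raw: dict) -> tuple[SessionConfig, EffectSpec]:
    """Build ``(SessionConfig, EffectSpec)`` from a parsed YAML/JSON mapping.

    Keys mirror the dataclass field names under ``session:`` and ``effect:``;
    unknown keys raise.
    """
    session_kw = dict(raw.get("session", {}))
    effect_kw = dict(raw.get("effect", {}))
    unknown = set(raw) - {"session", "effect"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    bad = set(session_kw) - {f.name for f in dataclasses.fields(SessionConfig)}
    if bad:
        raise ValueError(f"unknown session config keys: {sorted(bad)}")
    bad = set(effect_kw) - {f.name for f in dataclasses.fields(EffectSpec)}
    if bad:
        raise ValueError(f"unknown effect config keys: {sorted(bad)}")
    if "theta_band" in effect_kw:
        effect_kw["theta_band"] = tuple(effect_kw["theta_band"])
    return SessionConfig(**session_kw), EffectSpec(**effect_kw)


def load_config(path: str | pathlib.Path) -> tuple[SessionConfig, EffectSpec]:
    """Read a YAML (or JSON) config file mirroring the dataclass fields."""
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    return config_from_mapping(raw)
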