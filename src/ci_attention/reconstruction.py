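"""Reconstruction of 65 Hz trial series from windowed telemetry recordings.

Each 1.7 ms recording window carries a filter artifact on its first samples;
those are discarded, the remainder of the window is averaged to a single
value, and the 65 window means are concatenated into a 1 s, 65 Hz series.
An optional band-pass (4-25 Hz hamming-windowed sinc FIR, one-pass
zero-phase) mirrors standard EEG-style preprocessing of the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synthetic_session import RawTrial, Session

__all__ = [
    "TrialSeries",
    "FilterSpec",
    "window_average",
    "design_bandpass",
    "apply_zerophase",
    "filter_trials",
    "select_correct_trials",
    "reconstruct_session",
]


@dataclass
class TrialSeries:
    """One trial's reconstructed time series (65 samples at 65 Hz)."""

    subject_id: str
    trial_index: int
    cue: str
    samples: np.ndarray
    sampling_rate: float = 65.0
    filtered: bool = False


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR specification.

    ``order`` is the filter order (number of taps minus one) and must be
    even so the group delay ``order/2`` is an integer and one-pass
    zero-phase compensation is exact.  With a Hamming window, 424 taps at
    65 Hz give the nominal 0.5 Hz transition width.
    """

    low_cut: float = 4.0
    high_cut: float = 25.0
    order: int = 424
    transition_width: float = 0.5
    window_shape: str = "hamming"

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= sampling_rate / 2:
            raise ValueError("high_cut must be below Nyquist")
        if self.order % 2 != 0:
            raise ValueError("order must be even for exact group-delay compensation")


def window_average(trial: RawTrial, discard_n: int = 100) -> TrialSeries:
    """Collapse each recording window to the mean of its retained samples.

    The first ``discard_n`` samples of every window (the filter-artifact
    prefix) are dropped; sample ``i`` of the output is the arithmetic mean
    of window ``i``'s remaining samples.
    """
    n_windows, n_samples = trial.windows.shape
    if discard_n >= n_samples:
        raise ValueError(f"discard_n={discard_n} >= samples per window {n_samples}")
    if discard_n < 0:
        raise ValueError("discard_n must be non-negative")
    if not np.all(np.isfinite(trial.windows)):
        raise ValueError(f"non-finite samples in trial {trial.trial_index}")
    samples = trial.windows[:, discard_n:].mean(axis=1)
    return TrialSeries(
        subject_id=trial.subject_id,
        trial_index=trial.trial_index,
        cue=trial.cue,
        samples=samples,
        sampling_rate=65.0,
        filtered=False,
    )


def design_bandpass(spec: FilterSpec, sampling_rate: float = 65.0) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass kernel (``order + 1`` taps)."""
    spec.validate(sampling_rate)
    return signal.firwin(
        spec.order + 1,
        [spec.low_cut, spec.high_cut],
        window=spec.window_shape,
        pass_zero=False,
        fs=sampling_rate,
    )


def _pad(x: np.ndarray, n_pad: int, pad_mode: str) -> np.ndarray:
    if pad_mode == "mirror":
        return np.pad(x, n_pad, mode="reflect")
    if pad_mode == "zero":
        return np.pad(x, n_pad, mode="constant")
    if pad_mode == "wrap":
        # periodic continuation: exact for the integer-Hz components of a
        # 1 s window, hence minimal transients for in-band signals
        return np.pad(x, n_pad, mode="wrap")
    raise ValueError(f"unknown pad_mode {pad_mode!r}")


def apply_zerophase(series: TrialSeries, kernel: np.ndarray, pad_mode: str = "mirror") -> TrialSeries:
    """One forward pass of a linear-phase kernel with group-delay compensation.

    The trial is padded to at least three kernel lengths before filtering
    (the kernel is far longer than the 65-sample trial) and truncated back
    afterwards, so the output has the input's length and zero net phase
    shift for in-band components.
    """
    if series.filtered:
        raise ValueError("series is already filtered")
    n_taps = len(kernel)
    if n_taps % 2 == 0:
        raise ValueError("kernel must have odd length (even order)")
    delay = (n_taps - 1) // 2
    n = len(series.samples)
    n_pad = max(3 * (n_taps - 1) // 2, n)
    padded = _pad(np.asarray(series.samples, dtype=float), n_pad, pad_mode)
    full = np.convolve(padded, kernel, mode="full")
    out = full[delay + n_pad : delay + n_pad + n]
    return replace(series, samples=out, filtered=True)


def filter_trials(
    series_list: list[TrialSeries], kernel: np.ndarray, pad_mode: str = "mirror"
) -> list[TrialSeries]:
    """Zero-phase filter a collection of trials.

    ``pad_mode`` "mirror" or "zero" filters each trial independently;
    "concat" concatenates all trials into one continuous record, filters
    once (with mirror padding at the record's ends) and splits back, which
    trades inter-trial leakage for smaller per-trial edge transients.
    """
    if pad_mode in ("mirror", "zero", "wrap"):
        return [apply_zerophase(s, kernel, pad_mode) for s in series_list]
    if pad_mode != "concat":
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    if not series_list:
        return []
    n = len(series_list[0].samples)
    stacked = np.concatenate([s.samples for s in series_list])
    joint = TrialSeries(
        subject_id=series_list[0].subject_id,
        trial_index=-1,
        cue="",
        samples=stacked,
        filtered=False,
    )
    filt = apply_zerophase(joint, kernel, pad_mode="mirror").samples
    return [
        replace(s, samples=filt[i * n : (i + 1) * n], filtered=True)
        for i, s in enumerate(series_list)
    ]


def select_correct_trials(session: Session) -> Session:
    """Retain only trials answered correctly, preserving order."""
    kept = [t for t in session.trials if t.response_correct]
    if not kept:
        warnings.warn("no correct trials in session", stacklevel=2)
    return replace(session, trials=kept)


def reconstruct_session(
    session: Session,
    discard_n: int = 100,
    filter_spec: FilterSpec | None = None,
    pad_mode: str = "mirror",
) -> list[TrialSeries]:
    """Window-average every trial and optionally band-pass filter the series."""
    series = [window_average(t, discard_n=discard_n) for t in session.trials]
    if filter_spec is not None:
        kernel = design_bandpass(filter_spec, sampling_rate=session.config.sampling_rate)
        series = filter_trials(series, kernel, pad_mode=pad_mode)
    return series
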