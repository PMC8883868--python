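"""Power spectral density of the reconstructed 1 s trial series.

A 65-sample series at 65 Hz has exactly 1 Hz frequency resolution, so the
spectrum lives on integer-Hz bins; analysis is restricted to 4-25 Hz (22
bins).  Each trial is demeaned, linearly detrended, Hann-tapered and
Fourier-transformed; power is reported as a taper-energy-normalised
one-sided density (mV^2/Hz).  All downstream inference (condition
contrasts, classifiers on standardised features) is invariant to that
scale convention.

Bands of interest: theta 5-8 Hz, alpha 9-13 Hz, beta 14-24 Hz, and the
4-25 Hz broadband.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .reconstruction import TrialSeries

__all__ = [
    "PowerSpectrum",
    "FOIBand",
    "BANDS",
    "trial_psd",
    "full_periodogram",
    "condition_average",
    "band_average",
    "smooth_spectrum",
    "within_subject_sem",
]

FMIN, FMAX = 4.0, 25.0


@dataclass(frozen=True)
class FOIBand:
    """A named frequency band of interest, inclusive integer-Hz range."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not FMIN <= self.low <= self.high <= FMAX:
            raise ValueError(f"band [{self.low}, {self.high}] outside [{FMIN}, {FMAX}]")


BANDS: dict[str, FOIBand] = {
    "broadband": FOIBand("broadband", 4, 25),
    "theta": FOIBand("theta", 5, 8),
    "alpha": FOIBand("alpha", 9, 13),
    "beta": FOIBand("beta", 14, 24),
}


@dataclass
class PowerSpectrum:
    """Power on integer-Hz bins within [4, 25] Hz."""

    freqs: np.ndarray
    power: np.ndarray
    level: str = "trial"  # "trial" | "condition-average"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must align")


def _taper(n: int) -> np.ndarray:
    # periodic Hann, the standard taper for spectral estimation
    return signal.windows.hann(n, sym=False)


def full_periodogram(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Untruncated one-sided tapered periodogram of a demeaned/detrended series.

    Returned powers use the energy convention: their sum equals the tapered
    signal's energy ``sum((x * w)**2)`` exactly (Parseval), which anchors
    the scale of :func:`trial_psd`.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    x = signal.detrend(x - x.mean(), type="linear")
    w = _taper(n)
    spec = np.fft.rfft(x * w)
    p = np.abs(spec) ** 2 / n
    p[1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not doubled for even n
        p[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0)  # cycles per sample; scaled by caller
    return freqs, p


def trial_psd(series: TrialSeries) -> PowerSpectrum:
    """Demean, detrend, Hann-taper and Fourier-transform one trial.

    Requires the canonical 65-sample, 65 Hz series; returns density-scaled
    power (mV^2/Hz) on the integer bins 4..25 Hz.
    """
    x = np.asarray(series.samples, dtype=float)
    n = len(x)
    fs = series.sampling_rate
    if n != 65 or fs != 65:
        raise ValueError("trial_psd expects a 65-sample series at 65 Hz")
    freqs_cyc, p = full_periodogram(x)
    freqs = freqs_cyc * fs  # integer Hz since n == fs
    w = _taper(n)
    # energy periodogram -> one-sided density: divide by fs * mean(w^2)
    psd = p / (fs * (w**2).mean())
    keep = (freqs >= FMIN) & (freqs <= FMAX)
    return PowerSpectrum(freqs=freqs[keep], power=psd[keep], level="trial")


def condition_average(spectra: list[PowerSpectrum], labels: list[str]) -> dict[str, PowerSpectrum]:
    """Bin-wise mean spectrum per condition label."""
    if len(spectra) != len(labels):
        raise ValueError("one label per spectrum required")
    out: dict[str, PowerSpectrum] = {}
    for cond in dict.fromkeys(labels):
        group = [s.power for s, l in zip(spectra, labels) if l == cond]
        if not group:
            raise ValueError(f"condition {cond!r} has no trials")
        out[cond] = PowerSpectrum(
            freqs=spectra[0].freqs.copy(),
            power=np.mean(group, axis=0),
            level="condition-average",
        )
    if not out:
        raise ValueError("no conditions present")
    return out


def band_average(spectrum: PowerSpectrum, band: FOIBand | str) -> float:
    """Arithmetic mean of power over the band's integer bins (inclusive)."""
    if isinstance(band, str):
        band = BANDS[band]
    mask = (spectrum.freqs >= band.low) & (spectrum.freqs <= band.high)
    if not mask.any():
        raise ValueError(f"band {band.name} has no bins in the spectrum")
    return float(spectrum.power[mask].mean())


def smooth_spectrum(spectrum: PowerSpectrum, n_points: int = 5) -> PowerSpectrum:
    """Centred moving average for display; edges use shrinking windows.

    Smoothing is presentation-only and must never feed statistics.
    """
    if n_points % 2 == 0 or n_points < 1:
        raise ValueError("n_points must be odd and positive")
    half = n_points // 2
    kernel = np.ones(n_points)
    sums = np.convolve(spectrum.power, kernel, mode="same")
    counts = np.convolve(np.ones_like(spectrum.power), kernel, mode="same")
    smoothed = sums / counts
    assert half <= len(spectrum.power)
    return PowerSpectrum(freqs=spectrum.freqs.copy(), power=smoothed, level=spectrum.level)


def within_subject_sem(band_powers: np.ndarray) -> np.ndarray:
    """Cousineau-Morey within-subject SEM per condition.

    ``band_powers`` is a subjects x conditions matrix.  Each subject's
    cross-condition mean is removed and the grand mean restored, the
    per-condition SEM of the normalised scores is computed with an n-1
    denominator, and the Morey bias correction ``sqrt(C / (C - 1))`` is
    applied, with C the number of conditions.
    """
    x = np.asarray(band_powers, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    n, c = x.shape
    normalized = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(c / (c - 1))
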