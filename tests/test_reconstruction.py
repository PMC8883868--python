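"""Window averaging, band-pass design and zero-phase filtering contracts."""

import numpy as np
import pytest
from scipy import signal

from ci_attention.reconstruction import (
    FilterSpec,
    TrialSeries,
    apply_zerophase,
    design_bandpass,
    filter_trials,
    reconstruct_session,
    select_correct_trials,
    window_average,
)
from ci_attention.synthetic_session import EffectSpec, RawTrial, generate_session, simulate_behavior
from conftest import small_config


def make_trial(windows, idx=0, cue="auditory"):
    return RawTrial(
        subject_id="T",
        block=0,
        trial_index=idx,
        cue=cue,
        is_auditory_oddball=False,
        is_visual_oddball=False,
        response_correct=True,
        start_jitter=0.0,
        windows=np.asarray(windows, dtype=float),
    )


class TestWindowAverage:
    def test_constant_windows_give_their_constants(self):
        consts = np.arange(65, dtype=float)
        trial = make_trial(np.tile(consts[:, None], (1, 200)))
        out = window_average(trial, discard_n=20)
        assert np.allclose(out.samples, consts)
        assert len(out.samples) == 65 and out.sampling_rate == 65 and not out.filtered

    def test_artifact_prefix_never_influences_output(self, rng):
        base = rng.normal(size=(65, 300))
        corrupted = base.copy()
        corrupted[:, :100] = rng.normal(10, 50, size=(65, 100))
        a = window_average(make_trial(base), discard_n=100)
        b = window_average(make_trial(corrupted), discard_n=100)
        assert np.array_equal(a.samples, b.samples)

    def test_matches_brute_force_mean(self, rng):
        windows = rng.normal(size=(65, 2048))
        out = window_average(make_trial(windows), discard_n=100)
        # independent summation oracle
        expected = np.array(
            [sum(windows[w, s] for s in range(100, 2048)) / (2048 - 100) for w in range(65)]
        )
        assert np.allclose(out.samples, expected, rtol=0, atol=1e-12)

    def test_linearity(self, rng):
        x = rng.normal(size=(65, 128))
        y = rng.normal(size=(65, 128))
        a, b = 2.5, -1.25
        combo = window_average(make_trial(a * x + b * y), 16).samples
        parts = a * window_average(make_trial(x), 16).samples + b * window_average(make_trial(y), 16).samples
        assert np.allclose(combo, parts)

    def test_invalid_inputs_rejected(self, rng):
        trial = make_trial(rng.normal(size=(65, 128)))
        with pytest.raises(ValueError):
            window_average(trial, discard_n=128)
        bad = rng.normal(size=(65, 128))
        bad[3, 50] = np.nan
        with pytest.raises(ValueError):
            window_average(make_trial(bad), discard_n=16)

    def test_length_invariant_under_jitter_and_artifact(self):
        cfg = small_config(seed=13, trials_per_block=4)
        session = generate_session(cfg, EffectSpec())
        for trial in session.trials:
            assert len(window_average(trial, cfg.artifact_prefix_len).samples) == 65


class TestBandpassDesign:
    def test_kernel_frequency_response(self):
        kernel = design_bandpass(FilterSpec(), sampling_rate=65)
        assert len(kernel) == 425
        assert abs(kernel.sum()) < 0.01  # DC in stopband
        _, h = signal.freqz(kernel, worN=[1.0, 10.0], fs=65)
        assert np.abs(h[1]) == pytest.approx(1.0, abs=0.05)  # 10 Hz passband
        assert np.abs(h[0]) < 0.1  # 1 Hz stopband

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass(FilterSpec(order=423), sampling_rate=65)

    def test_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass(FilterSpec(high_cut=40.0), sampling_rate=65)


class TestZeroPhase:
    def _series(self, samples):
        return TrialSeries(subject_id="T", trial_index=0, cue="auditory", samples=np.asarray(samples, float))

    def test_zeros_map_to_zeros(self):
        kernel = design_bandpass(FilterSpec(), 65)
        out = apply_zerophase(self._series(np.zeros(65)), kernel)
        assert np.allclose(out.samples, 0.0)
        assert out.filtered

    def test_inband_sinusoid_keeps_phase_and_amplitude(self):
        # periodic padding continues an integer-Hz sinusoid exactly
        kernel = design_bandpass(FilterSpec(), 65)
        t = np.arange(65) / 65
        x = np.sin(2 * np.pi * 6 * t)
        out = apply_zerophase(self._series(x), kernel, pad_mode="wrap").samples
        # zero-phase contract: cross-correlation peaks at lag 0
        lags = signal.correlation_lags(65, 65)
        xc = signal.correlate(out - out.mean(), x - x.mean())
        assert lags[np.argmax(xc)] == 0
        assert np.abs(out).max() == pytest.approx(1.0, abs=0.1)

    def test_already_filtered_rejected(self):
        kernel = design_bandpass(FilterSpec(), 65)
        out = apply_zerophase(self._series(np.ones(65)), kernel)
        with pytest.raises(ValueError):
            apply_zerophase(out, kernel)

    def test_stopband_attenuated_by_20db(self, rng):
        kernel = design_bandpass(FilterSpec(), 65)
        long = TrialSeries(subject_id="T", trial_index=0, cue="a", samples=rng.normal(size=65 * 200))
        out = apply_zerophase(long, kernel).samples
        f, pxx = signal.welch(out, fs=65, nperseg=1024)
        inband = pxx[(f > 4.5) & (f < 24.5)].mean()
        outband = pxx[(f < 3.5) | (f > 25.5)].mean()
        assert outband < inband * 1e-2  # >= 20 dB down

    def test_inband_signal_nearly_idempotent(self, rng):
        # a signal already band-limited to 5-24 Hz changes by < 5% RMS
        # (long series, so kernel-length edge transients are negligible)
        kernel = design_bandpass(FilterSpec(), 65)
        inner = signal.firwin(201, [5.0, 24.0], window="hamming", pass_zero=False, fs=65)
        x = signal.filtfilt(inner, [1.0], rng.normal(size=65 * 60))
        out = apply_zerophase(
            TrialSeries(subject_id="T", trial_index=0, cue="a", samples=x), kernel
        ).samples
        assert np.sqrt(np.mean((out - x) ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_concat_mode_returns_per_trial_series(self, rng):
        kernel = design_bandpass(FilterSpec(), 65)
        series = [self._series(rng.normal(size=65)) for _ in range(4)]
        out = filter_trials(series, kernel, pad_mode="concat")
        assert len(out) == 4 and all(len(s.samples) == 65 and s.filtered for s in out)


class TestTrialSelection:
    def test_identity_when_all_correct(self, small_session):
        out = select_correct_trials(small_session)
        assert [t.trial_index for t in out.trials] == [t.trial_index for t in small_session.trials]

    def test_mixed_flags_match_enumeration(self):
        cfg = small_config(seed=21, trials_per_block=5)
        session = simulate_behavior(generate_session(cfg, EffectSpec()), 0.5)
        expected = [t.trial_index for t in session.trials if t.response_correct]
        out = select_correct_trials(session)
        assert [t.trial_index for t in out.trials] == expected
        assert 0 < len(expected) < len(session.trials)

    def test_none_correct_warns_and_returns_empty(self, small_session):
        session = simulate_behavior(small_session, 0.0)
        with pytest.warns(UserWarning):
            out = select_correct_trials(session)
        assert len(out.trials) == 0

    def test_reconstruct_session_shapes(self, small_session):
        series = reconstruct_session(small_session, discard_n=10, filter_spec=FilterSpec())
        assert len(series) == len(small_session.trials)
        assert all(len(s.samples) == 65 and s.filtered for s in series)
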