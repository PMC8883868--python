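import numpy as np
import pytest

from ci_attention import reconstruction as rec
from ci_attention import spectral as sp
from ci_attention.synthetic_session import EffectSpec, SessionConfig, generate_session


def small_config(seed: int = 1, trials_per_block: int = 12, n_blocks: int = 2, spw: int = 64) -> SessionConfig:
    """Reduced-scale recording config: same 65-window structure, small windows."""
    n_aud = trials_per_block // 2
    return SessionConfig(
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        n_auditory_cues_per_block=n_aud,
        n_visual_cues_per_block=trials_per_block - n_aud,
        n_visual_oddballs_per_block=1,
        n_auditory_oddballs_per_block=1,
        samples_per_window=spw,
        artifact_prefix_len=10,
        seed=seed,
    )


def null_effect() -> EffectSpec:
    """Zero injected condition effect, no subject gain jitter."""
    return EffectSpec(attend_auditory_gain=1.0, per_subject_gain_sd=0.0)


def subject_spectra(config: SessionConfig, effect: EffectSpec, subject_key: int = 0, filtered: bool = True):
    """Generate, reconstruct and transform one subject's trials."""
    session = generate_session(config, effect, subject_key=subject_key)
    series = rec.reconstruct_session(
        session,
        discard_n=config.artifact_prefix_len,
        filter_spec=rec.FilterSpec() if filtered else None,
    )
    spectra = [sp.trial_psd(s) for s in series]
    cues = [s.cue for s in series]
    return session, spectra, cues


def subject_band_powers(config, effect, subject_key=0, band="theta"):
    _, spectra, cues = subject_spectra(config, effect, subject_key=subject_key)
    aud = np.mean([sp.band_average(p, band) for p, c in zip(spectra, cues) if c == "auditory"])
    vis = np.mean([sp.band_average(p, band) for p, c in zip(spectra, cues) if c == "visual"])
    return float(aud), float(vis)


@pytest.fixture(scope="session")
def small_session():
    """A deterministic reduced-scale session shared across tests."""
    return generate_session(small_config(), EffectSpec())


@pytest.fixture(scope="session")
def default_session():
    """A full default-design session (510 trials, 65 x 2048 windows)."""
    return generate_session(SessionConfig(seed=7), null_effect())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
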