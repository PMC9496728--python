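import numpy as np
import pytest

import tgpac as tg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_rec():
    """Tiny voltage recording: 3 channels x 4 trials of simple waveforms."""
    fs = 250.0
    times = -400.0 + np.arange(300) * 1000.0 / fs
    rng = np.random.default_rng(7)
    data = rng.standard_normal((3, 4, times.size))
    montage = tg.make_montage(2, 1)
    return tg.EpochedRecording(
        data=data,
        fs=fs,
        times=times,
        ch_names=montage.ch_names,
        conditions=np.array(["a", "a", "b", "b"]),
        montage=montage,
    )


def single_channel_recording(
    m: float,
    seed: int,
    n_trials: int = 30,
    fs: float = 500.0,
    noise_amp: float = 5.0,
    phi_c: float = 0.0,
    m_pre: float = 0.0,
):
    """One frontal + one posterior channel recording with known coupling."""
    cfg = tg.SynthConfig(
        fs=fs,
        m=m,
        phi_c=phi_c,
        noise_amp=noise_amp,
        coupling_windows={"pre": m_pre, "post": m},
        n_trials=n_trials,
        conditions=("c",),
        montage=tg.make_montage(1, 1),
        seed=seed,
    )
    return tg.generate_epoched_dataset(cfg)


def coupling_phases(rec, gamma_band=(40.0, 40.0), theta=6.0):
    """Morlet theta phase + gamma amplitude for a synthetic recording."""
    lo, hi = gamma_band
    freqs = np.unique(np.concatenate(([theta], np.arange(lo, hi + 0.5))))
    dec = tg.morlet_decompose(rec, freqs)
    th = tg.extract_phase(dec, theta)
    amp, gf = tg.extract_amplitude(dec, gamma_band)
    return th, amp, gf
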