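"""Synthetic epoched EEG with known theta-gamma coupling, and matched behavior.

The generative model for one trial of one channel is

    s(t) = a_theta * cos(2*pi*f_theta*t + psi)
         + a_gamma * [1 + m(t) * cos(2*pi*f_theta*t + psi - phi_c)] * cos(2*pi*f_gamma*t)
         + noise(t)

i.e. a theta oscillation plus a gamma carrier whose amplitude envelope is
multiplicatively modulated by the concurrent theta phase, on top of 1/f
background noise.  ``m(t)`` switches between a pre-stimulus and a
post-stimulus modulation depth through a short raised-cosine crossfade at
stimulus onset, so the coupling change does not inject broadband transients.
``psi`` is a fresh uniform theta phase per trial (shared across channels, as
for a common theta source), and each channel may add a fixed offset to the
preferred coupling phase ``phi_c`` — the knob used to study how coupling-phase
heterogeneity within an electrode cluster flattens cluster-averaged
phase-binned amplitude profiles without touching per-electrode coupling.

The behavioral generator is the high-threshold observer that the Pashler and
Cowan capacity formulas invert exactly: K of S items are stored; a probed or
displayed change is detected iff the relevant item is stored, otherwise the
observer guesses "change" with probability g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import EpochedRecording, Montage

__all__ = [
    "SynthConfig",
    "BehavioralConfig",
    "CONDITIONS",
    "make_montage",
    "one_over_f_noise",
    "make_coupled_timeseries",
    "generate_epoched_dataset",
    "generate_behavioral_data",
]

#: Task conditions of the three-way design: change detection (working memory),
#: active target search (attention, no storage), and passive viewing.
CONDITIONS = ("ActiveWM+", "ActiveWM-", "PassiveWM-")


def make_montage(
    n_frontal: int = 4,
    n_posterior: int = 4,
    frontal_phase_spread: float = 0.0,
    posterior_phase_spread: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Montage:
    """Build a synthetic montage with frontal and posterior clusters.

    Channels are placed on the unit sphere (frontal ring toward +y, posterior
    ring toward -y).  ``*_phase_spread`` > 0 draws each channel's preferred
    coupling-phase offset uniformly from ``[0, spread)`` radians; 0 gives a
    phase-homogeneous cluster.
    """
    rng = np.random.default_rng() if rng is None else rng
    names, positions, offsets = [], {}, {}

    def ring(n: int, prefix: str, y_sign: float, spread: float) -> list[str]:
        labels = [f"{prefix}{i + 1}" for i in range(n)]
        for i, lab in enumerate(labels):
            az = (i - (n - 1) / 2) * (math.pi / max(n, 2)) / 2
            elev = math.radians(30.0)
            x = math.cos(elev) * math.sin(az)
            y = y_sign * math.cos(elev) * math.cos(az)
            z = math.sin(elev) + 0.05 * (i % 2)
            r = math.sqrt(x * x + y * y + z * z)
            positions[lab] = (x / r, y / r, z / r)
            offsets[lab] = float(rng.uniform(0.0, spread)) if spread > 0 else 0.0
        return labels

    frontal = ring(n_frontal, "F", +1.0, frontal_phase_spread)
    posterior = ring(n_posterior, "P", -1.0, posterior_phase_spread)
    names = frontal + posterior
    return Montage(
        ch_names=names,
        positions=positions,
        frontal=frontal,
        posterior=posterior,
        phi_offsets=offsets,
    )


@dataclass
class SynthConfig:
    """Parameters of the coupled-EEG generator.

    ``coupling_windows`` maps ``"pre"``/``"post"`` to the modulation depth in
    force before/after stimulus onset; ``condition_depths`` optionally
    overrides it per condition label.  Amplitudes are in μV; ``noise_amp`` is
    the standard deviation of the 1/f background and is a free parameter of
    the generator (there is no published single-trial gamma SNR to match).
    """

    fs: float = 1000.0
    f_theta: float = 6.0
    f_gamma: float = 40.0
    m: float = 0.5
    phi_c: float = 0.0
    a_theta: float = 10.0
    a_gamma: float = 2.0
    noise_amp: float = 5.0
    epoch_ms: tuple[float, float] = (-1500.0, 2500.0)
    n_trials: int = 100
    conditions: tuple[str, ...] = CONDITIONS
    coupling_windows: dict[str, float] | None = None
    condition_depths: dict[str, dict[str, float]] | None = None
    crossfade_ms: float = 50.0
    montage: Montage | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.coupling_windows is None:
            self.coupling_windows = {"pre": 0.0, "post": self.m}
        self.validate()

    def validate(self) -> None:
        depths = [self.m, *self.coupling_windows.values()]
        for override in (self.condition_depths or {}).values():
            depths.extend(override.values())
        for d in depths:
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"modulation depth must be in [0, 1], got {d}")
        if self.fs <= 2.0 * self.f_gamma:
            raise ValueError(
                f"fs={self.fs} Hz aliases the {self.f_gamma} Hz gamma carrier; "
                "need fs > 2*f_gamma"
            )
        if self.epoch_ms[0] >= self.epoch_ms[1]:
            raise ValueError("epoch start must precede epoch end")
        if not self.conditions:
            raise ValueError("at least one condition label is required")

    @property
    def times_ms(self) -> np.ndarray:
        start, end = self.epoch_ms
        n = int(round((end - start) * self.fs / 1000.0))
        return start + np.arange(n) * 1000.0 / self.fs

    def depths_for(self, condition: str) -> dict[str, float]:
        base = dict(self.coupling_windows)
        if self.condition_depths and condition in self.condition_depths:
            base.update(self.condition_depths[condition])
        return base


def one_over_f_noise(
    n: int, fs: float, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent.

    White Gaussian noise is shaped in the frequency domain (amplitude scaled
    by f**(-exponent/2), DC removed) and inverse-transformed.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _modulation_timecourse(config: SynthConfig, depths: dict[str, float]) -> np.ndarray:
    """m(t): pre-stimulus depth crossfading to the post depth at onset."""
    t = config.times_ms
    m_pre = depths.get("pre", 0.0)
    m_post = depths.get("post", config.m)
    w = np.clip(t / max(config.crossfade_ms, 1e-9), 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * w))  # raised cosine 0 -> 1 over the fade
    return m_pre + (m_post - m_pre) * w


def make_coupled_timeseries(
    config: SynthConfig,
    rng: np.random.Generator,
    psi: float | None = None,
    phi_offset: float = 0.0,
    depths: dict[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """One trial of the coupled signal; returns ``(signal, psi)``.

    ``psi`` is the trial's theta phase at t=0 (drawn uniform if not given);
    ``phi_offset`` shifts the channel's preferred coupling phase relative to
    ``config.phi_c``.
    """
    config.validate()
    if psi is None:
        psi = float(rng.uniform(0.0, 2.0 * np.pi))
    t = config.times_ms / 1000.0
    theta_arg = 2.0 * np.pi * config.f_theta * t + psi
    m_t = (
        _modulation_timecourse(config, depths)
        if depths is not None
        else np.full(t.shape, config.m)
    )
    envelope = 1.0 + m_t * np.cos(theta_arg - (config.phi_c + phi_offset))
    s = (
        config.a_theta * np.cos(theta_arg)
        + config.a_gamma * envelope * np.cos(2.0 * np.pi * config.f_gamma * t)
    )
    if config.noise_amp > 0:
        s = s + config.noise_amp * one_over_f_noise(t.size, config.fs, rng)
    return s, psi


def generate_epoched_dataset(config: SynthConfig) -> EpochedRecording:
    """Simulate the full epoched dataset for every condition.

    Trials are stacked condition-by-condition; the theta phase ``psi`` is
    shared across channels within a trial while noise is independent per
    channel.  All ground-truth parameters land in ``rec.info["ground_truth"]``
    so they round-trip through the container format.
    """
    config.validate()
    montage = config.montage if config.montage is not None else make_montage()
    if len(montage.ch_names) < 2:
        raise ValueError("montage must define at least 2 channels")
    rng = np.random.default_rng(config.seed)

    times = config.times_ms
    n_ch = len(montage.ch_names)
    n_total = config.n_trials * len(config.conditions)
    data = np.empty((n_ch, n_total, times.size))
    cond_labels: list[str] = []
    psis = np.empty(n_total)

    tr = 0
    for cond in config.conditions:
        depths = config.depths_for(cond)
        for _ in range(config.n_trials):
            psi = float(rng.uniform(0.0, 2.0 * np.pi))
            for ci, ch in enumerate(montage.ch_names):
                sig, _ = make_coupled_timeseries(
                    config, rng, psi=psi,
                    phi_offset=montage.phi_offsets[ch], depths=depths,
                )
                data[ci, tr] = sig
            cond_labels.append(cond)
            psis[tr] = psi
            tr += 1

    ground_truth = {
        "fs": config.fs,
        "f_theta": config.f_theta,
        "f_gamma": config.f_gamma,
        "phi_c": config.phi_c,
        "a_theta": config.a_theta,
        "a_gamma": config.a_gamma,
        "noise_amp": config.noise_amp,
        "crossfade_ms": config.crossfade_ms,
        "seed": config.seed,
        "condition_depths": {c: config.depths_for(c) for c in config.conditions},
        "phi_offsets": dict(montage.phi_offsets),
        "trial_theta_phase": psis.tolist(),
    }
    return EpochedRecording(
        data=data,
        fs=config.fs,
        times=times,
        ch_names=list(montage.ch_names),
        conditions=np.asarray(cond_labels),
        montage=montage,
        units="uV",
        info={"ground_truth": ground_truth},
    )


@dataclass
class BehavioralConfig:
    """Ground truth for the change-detection behavior generator."""

    true_K: float = 3.0
    set_sizes: tuple[int, ...] = (2, 4, 6)
    g: float = 0.3
    n_trials: int = 100
    paradigm: str = "whole-display"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("guess rate g must be in [0, 1]")
        if self.true_K < 0 or self.true_K > max(self.set_sizes):
            raise ValueError("true_K must be in [0, max set size]")
        if self.paradigm not in ("whole-display", "single-probe"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")


def generate_behavioral_data(
    config: BehavioralConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Trial table (set_size, change_present, response) from the observer model.

    Both paradigms share P(hit) = k + (1-k) g with k = min(K/S, 1); false
    alarms are pure guesses (P = g) for whole-display test arrays, but only
    occur for unmemorized probes (P = (1-k) g) in the single-probe paradigm.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    parts = []
    for S in config.set_sizes:
        k = min(config.true_K / S, 1.0)
        p_hit = k + (1.0 - k) * config.g
        if config.paradigm == "whole-display":
            p_fa = config.g
        else:
            p_fa = (1.0 - k) * config.g
        n_change = config.n_trials // 2
        n_same = config.n_trials - n_change
        parts.append(
            pd.DataFrame(
                {
                    "set_size": S,
                    "change_present": np.repeat([True, False], [n_change, n_same]),
                    "response": np.concatenate(
                        [rng.random(n_change) < p_hit, rng.random(n_same) < p_fa]
                    ),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
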