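"""Morlet wavelet time-frequency decomposition.

Each frequency f is analyzed with a complex Morlet wavelet of temporal SD
sigma_t = n_cycles / (2*pi*f) (default 5 cycles), truncated at +/-5 sigma_t
and amplitude-normalized so a unit-amplitude sinusoid at f yields modulus ~1
in the epoch interior.  Amplitude is the modulus and phase the argument of
the complex coefficient; with this convention the phase of a cosine is 0 at
its maxima.

A validity mask marks edge samples where the wavelet's nominal support
(n_cycles/(2f) seconds, i.e. half the n-cycle span) hangs off the epoch;
downstream analysis windows must stay inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .recording import EpochedRecording

__all__ = [
    "SpectralDecomposition",
    "morlet_wavelet",
    "morlet_decompose",
    "extract_phase",
    "extract_amplitude",
    "default_freq_grid",
]


def default_freq_grid(lo: float = 2.0, hi: float = 70.0, step: float = 1.0) -> np.ndarray:
    """Integer-spaced analysis grid, 2-70 Hz at 1 Hz by default."""
    return np.arange(lo, hi + 0.5 * step, step, dtype=float)


@dataclass
class SpectralDecomposition:
    """Complex wavelet coefficients: channels x trials x frequencies x samples."""

    coeffs: np.ndarray
    freqs: np.ndarray
    fs: float
    times: np.ndarray
    n_cycles: float
    valid_mask: np.ndarray  # (n_freqs, n_samples) bool

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-9:
            raise ValueError(f"{f} Hz is not on the frequency grid")
        return i

    def valid_slice(self, f: float) -> slice:
        """Largest interior slice where frequency f's coefficients are valid."""
        row = self.valid_mask[self.freq_index(f)]
        idx = np.flatnonzero(row)
        if idx.size == 0:
            raise ValueError(f"no valid samples at {f} Hz (wavelet too long)")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def morlet_wavelet(f: float, fs: float, n_cycles: float = 5.0) -> np.ndarray:
    """Complex Morlet kernel at frequency f, normalized for unit-sinusoid gain.

    The kernel is g(t)*exp(i*2*pi*f*t) with Gaussian g of SD
    sigma_t = n_cycles/(2*pi*f), truncated at +/-5 sigma_t, and scaled by
    2/sum(g) so convolution maps cos(2*pi*f*t) to ~exp(i*2*pi*f*t).
    """
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = gauss * np.exp(2j * np.pi * f * t)
    return 2.0 * kernel / gauss.sum()


def morlet_decompose(
    rec: EpochedRecording,
    freqs: np.ndarray | list[float],
    n_cycles: float = 5.0,
) -> SpectralDecomposition:
    """Decompose an epoched recording over ``freqs``.

    Convolution is FFT-based along the time axis.  Edge samples within
    n_cycles/(2f) seconds of either epoch boundary are flagged invalid for
    that frequency rather than padded.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    nyq = rec.fs / 2.0
    if (freqs >= nyq).any():
        raise ValueError(f"frequencies must be below Nyquist ({nyq} Hz)")
    n_samp = rec.n_samples
    # complex64 storage: phase precision ~1e-7 rad, ample for PLV work, and
    # half the footprint of complex128 for full 2-70 Hz grids
    coeffs = np.empty(
        (rec.n_channels, rec.n_trials, freqs.size, n_samp), dtype=np.complex64
    )
    valid = np.zeros((freqs.size, n_samp), dtype=bool)
    for fi, f in enumerate(freqs):
        kernel = morlet_wavelet(f, rec.fs, n_cycles)
        if kernel.size > n_samp:
            raise ValueError(
                f"{n_cycles}-cycle wavelet at {f} Hz is longer than the epoch"
            )
        coeffs[:, :, fi, :] = fftconvolve(
            rec.data, kernel[np.newaxis, np.newaxis, :], mode="same", axes=2
        )
        edge = int(np.ceil(n_cycles / (2.0 * f) * rec.fs))
        if edge < n_samp - edge:
            valid[fi, edge : n_samp - edge] = True
    return SpectralDecomposition(
        coeffs=coeffs,
        freqs=freqs,
        fs=rec.fs,
        times=rec.times.copy(),
        n_cycles=n_cycles,
        valid_mask=valid,
    )


def extract_phase(decomp: SpectralDecomposition, f: float = 6.0) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) at one frequency.

    Returns channels x trials x samples; this is the theta phase series
    phi_theta when f is the theta frequency.
    """
    fi = decomp.freq_index(f)
    return np.angle(decomp.coeffs[:, :, fi, :]).astype(np.float64)


def extract_amplitude(
    decomp: SpectralDecomposition, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude envelope for every grid frequency inside ``band`` (inclusive).

    Returns ``(amplitude, band_freqs)`` with amplitude shaped
    channels x trials x band-frequencies x samples (float32, matching the
    coefficient storage; downstream phase math upcasts per channel).  No
    averaging across frequencies happens here; band averaging is applied to
    PLV downstream.
    """
    lo, hi = band
    sel = (decomp.freqs >= lo - 1e-9) & (decomp.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"no grid frequencies inside band {band}")
    return np.abs(decomp.coeffs[:, :, sel, :]), decomp.freqs[sel]
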