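"""Theta-gamma phase-amplitude coupling via the envelope-phase PLV.

For each trial, electrode and gamma frequency, the gamma amplitude envelope
inside an analysis window is demeaned and Hilbert-transformed to obtain the
envelope phase phi_Agamma(n); the coupling statistic is the phase locking
value between it and the concurrent theta phase phi_theta(n):

    PLV = | (1/N) * sum_n exp( i * (phi_theta(n) - phi_Agamma(n)) ) |

PLV is 1 for a constant phase difference and ~N^(-1/2) for unrelated phases;
it is invariant to a global rotation of either phase series, so it measures
coupling strength but not the preferred coupling phase.  Single-trial PLVs
are averaged across trials per condition, electrode and gamma frequency, and
then across band frequencies and cluster electrodes.

Because the pre-stimulus window is shorter than the post-stimulus one, its
(theta phase, envelope phase) sample pairs can be spliced — resampled with
pairs kept intact — up to the post window's length so both windows enter the
statistics with equal N.  Chance level then still tracks the number of
*unique* samples, which :func:`shuffle_null` characterizes rather than hides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

__all__ = [
    "WindowSpec",
    "PRE_WINDOW",
    "POST_WINDOW",
    "PhaseBinProfile",
    "NullDistribution",
    "envelope_phase",
    "plv_single_trial",
    "splice_to_length",
    "splice_indices",
    "windowed_plv",
    "shuffle_null",
    "aggregate",
    "phase_bin_profile",
    "average_profiles",
    "modulation_depth",
    "preferred_phase",
]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window in ms relative to stimulus onset; half-open [start, end)."""

    name: str
    start_ms: float
    end_ms: float

    def sample_slice(self, times: np.ndarray) -> slice:
        i0 = int(np.searchsorted(times, self.start_ms, side="left"))
        i1 = int(np.searchsorted(times, self.end_ms, side="left"))
        if i1 - i0 < 2:
            raise ValueError(f"window {self.name!r} covers fewer than 2 samples")
        return slice(i0, i1)

    def n_samples(self, times: np.ndarray) -> int:
        s = self.sample_slice(times)
        return s.stop - s.start


#: The study windows: a 740 ms pre-stimulus baseline and a 1600 ms
#: post-stimulus (retention) window, in ms relative to onset.
PRE_WINDOW = WindowSpec("pre", -940.0, -200.0)
POST_WINDOW = WindowSpec("post", 300.0, 1900.0)


def envelope_phase(amplitude: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase of the amplitude-envelope fluctuations along ``axis``.

    The (nonnegative) envelope is demeaned along the window so its analytic
    signal captures the fluctuation phase rather than the DC offset.  A
    constant envelope has no defined phase: those rows come back NaN and
    downstream PLV cells are marked invalid.
    """
    amp = np.asarray(amplitude, dtype=float)
    if np.nanmin(amp) < 0:
        raise ValueError("amplitude envelope must be nonnegative")
    amp = np.moveaxis(amp, axis, -1)
    centered = amp - amp.mean(axis=-1, keepdims=True)
    phase = np.angle(hilbert(centered, axis=-1))
    flat = centered.std(axis=-1) == 0.0
    if flat.any():
        phase = np.where(flat[..., np.newaxis], np.nan, phase)
    return np.moveaxis(phase, -1, axis)


def plv_single_trial(theta_phase: np.ndarray, env_phase: np.ndarray) -> float:
    """PLV between two phase series of equal length N >= 2."""
    th = np.asarray(theta_phase, dtype=float).ravel()
    ep = np.asarray(env_phase, dtype=float).ravel()
    if th.shape != ep.shape:
        raise ValueError("phase series must have equal length")
    if th.size < 2:
        raise ValueError("need at least 2 paired samples")
    return float(np.abs(np.exp(1j * (th - ep)).mean()))


def splice_indices(n: int, target_n: int, rng: np.random.Generator) -> np.ndarray:
    """Random resampling indices of length ``target_n`` over ``n`` samples.

    Full random permutations of the n samples are concatenated, and the
    remainder is a without-replacement random draw, so sample multiplicities
    differ by at most one and chance level stays close to the n-unique-sample
    level.  ``target_n <= n`` returns a plain permutation-truncation only for
    target_n == n; smaller targets are a caller error handled upstream.
    """
    if n < 1:
        raise ValueError("cannot splice an empty window")
    reps, rem = divmod(target_n, n)
    parts = [rng.permutation(n) for _ in range(reps)]
    if rem:
        parts.append(rng.choice(n, size=rem, replace=False))
    return np.concatenate(parts) if parts else np.empty(0, dtype=int)


def splice_to_length(
    theta_phase: np.ndarray,
    env_phase: np.ndarray,
    target_n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample paired (theta phase, envelope phase) samples to ``target_n``.

    The same time-point draw is applied to both series, so pairs are never
    broken.  ``target_n`` below the input length is returned unchanged with a
    warning (splicing never subsamples).
    """
    th = np.asarray(theta_phase, dtype=float)
    ep = np.asarray(env_phase, dtype=float)
    n = th.shape[-1]
    if ep.shape[-1] != n:
        raise ValueError("paired series must share their time axis")
    if n == 0:
        raise ValueError("cannot splice an empty window")
    if target_n < n:
        warnings.warn(
            f"splice target {target_n} < window length {n}; returning input unchanged",
            stacklevel=2,
        )
        return th, ep
    idx = splice_indices(n, target_n, rng)
    return th[..., idx], ep[..., idx]


def _channel_window_pairs(
    theta_phase: np.ndarray,
    amplitude: np.ndarray,
    ci: int,
    window_slice: slice,
) -> tuple[np.ndarray, np.ndarray]:
    """One channel's windowed (theta (tr, 1, ns), env (tr, nf, ns)) phases.

    Processing per channel keeps peak temporaries (Hilbert transform,
    phasor products) to a fraction of the full decomposition's footprint.
    """
    th = np.asarray(theta_phase[ci, :, window_slice], dtype=float)
    ep = envelope_phase(np.asarray(amplitude[ci, :, :, window_slice], dtype=float))
    return th[:, np.newaxis, :], ep


def _trial_plv(th3: np.ndarray, ep3: np.ndarray) -> np.ndarray:
    """Per-trial PLV (tr, nf) from one channel's broadcastable phase arrays."""
    return np.abs(np.exp(1j * (th3 - ep3)).mean(axis=-1))


def windowed_plv(
    theta_phase: np.ndarray,
    amplitude: np.ndarray,
    window: WindowSpec,
    *,
    times: np.ndarray,
    conditions: np.ndarray,
    ch_names: list[str],
    gamma_freqs: np.ndarray,
    equalize_to: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial-averaged PLV table for one analysis window.

    ``theta_phase`` is channels x trials x samples (full epoch) and
    ``amplitude`` channels x trials x gamma-frequencies x samples.  When
    ``equalize_to`` is given, each trial's windowed pairs are spliced to that
    length (used to match the short pre-stimulus window to the post window).
    Returns tidy rows: condition, window, channel, gamma_freq, plv, n_trials,
    n_points.  Cells whose envelope was flat in a trial average over the
    remaining valid trials; a condition with no valid trial yields NaN.
    """
    sl = window.sample_slice(times)
    n_win = sl.stop - sl.start
    n_ch, n_tr = theta_phase.shape[0], theta_phase.shape[1]
    n_points = n_win
    idx = None
    if equalize_to is not None and equalize_to > n_win:
        if rng is None:
            raise ValueError("splicing requires an rng")
        # one splice draw per trial, shared across channels
        idx = np.stack([splice_indices(n_win, equalize_to, rng) for _ in range(n_tr)])
        n_points = equalize_to
    elif equalize_to is not None and equalize_to < n_win:
        warnings.warn(
            f"equalize_to={equalize_to} < window length {n_win}; not subsampling",
            stacklevel=2,
        )

    plv_tr = np.empty((n_ch, n_tr, amplitude.shape[2]))
    for ci in range(n_ch):
        th3, ep3 = _channel_window_pairs(theta_phase, amplitude, ci, sl)
        if idx is not None:
            th3 = np.take_along_axis(th3, idx[:, np.newaxis, :], axis=-1)
            ep3 = np.take_along_axis(ep3, idx[:, np.newaxis, :], axis=-1)
        plv_tr[ci] = _trial_plv(th3, ep3)
    conditions = np.asarray(conditions)
    rows = []
    for cond in pd.unique(conditions):
        sel = conditions == cond
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_plv = np.nanmean(plv_tr[:, sel, :], axis=1)  # (ch, nf)
        n_valid = np.isfinite(plv_tr[:, sel, :]).sum(axis=1)
        for ci, ch in enumerate(ch_names):
            for fi, f in enumerate(np.asarray(gamma_freqs, dtype=float)):
                rows.append(
                    {
                        "condition": cond,
                        "window": window.name,
                        "channel": ch,
                        "gamma_freq": f,
                        "plv": mean_plv[ci, fi],
                        "n_trials": int(n_valid[ci, fi]),
                        "n_points": n_points,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class NullDistribution:
    """Permutation null PLVs, computed along the observed aggregation path.

    ``table`` is tidy with columns perm, condition, window, channel,
    gamma_freq, plv; ``method`` tags how theta was decoupled from the
    envelope.
    """

    table: pd.DataFrame
    method: str
    n_perm: int

    def percentile(self, q: float, band=None, channels=None) -> pd.DataFrame:
        """Per-permutation aggregate percentile by condition (and window)."""
        tab = self.table
        if band is not None or channels is not None:
            tab = aggregate(
                tab,
                band=band or (tab.gamma_freq.min(), tab.gamma_freq.max()),
                channels=channels or list(tab.channel.unique()),
            )
        keys = [c for c in ("condition", "window") if c in tab.columns]
        return (
            tab.groupby(keys, observed=True)
            .plv.quantile(q / 100.0)
            .reset_index()
            .rename(columns={"plv": f"q{q:g}"})
        )


def _all_shift_plv(
    th3: np.ndarray, ep3: np.ndarray, mult: np.ndarray | None, total: float
) -> np.ndarray:
    """|c[s]|/total for every circular shift s of the theta series.

    c[s] = sum_n w_n * z_{(n+s) mod N} with z = exp(i*phi_theta),
    w = mult * exp(-i*phi_env); evaluated with FFTs along the last axis for
    one channel's broadcastable (tr, 1, N) / (tr, nf, N) phase arrays;
    returns (tr, nf, N).  ``total`` is the effective sample count (the
    splice target when mult carries splice multiplicities, else N).
    """
    z = np.exp(1j * th3)
    w = np.exp(-1j * ep3)
    if mult is not None:
        w = w * mult
    w_rev = np.roll(w[..., ::-1], 1, axis=-1)  # w_rev[s] = w[(-s) mod N]
    c = np.fft.ifft(np.fft.fft(z, axis=-1) * np.fft.fft(w_rev, axis=-1), axis=-1)
    return np.abs(c) / total


def shuffle_null(
    theta_phase: np.ndarray,
    amplitude: np.ndarray,
    window: WindowSpec,
    n_perm: int,
    *,
    times: np.ndarray,
    conditions: np.ndarray,
    ch_names: list[str],
    gamma_freqs: np.ndarray,
    method: str = "circular_shift",
    equalize_to: int | None = None,
    rng: np.random.Generator | None = None,
    min_shift_frac: float = 0.0,
) -> NullDistribution:
    """Permutation null for the trial-averaged PLV.

    ``method="circular_shift"`` (default) rotates each trial's theta-phase
    series by a random nonzero lag, preserving its autocorrelation — the
    calibrated choice.  With trial averaging, near-zero lags in a few trials
    cannot push a permutation's mean toward the observed value, so the full
    lag range is used by default; for single-trial or very-few-trial nulls
    set ``min_shift_frac`` > 0 to keep lags away from 0 and N, where a
    rhythmic theta series is still essentially coupled.
    ``method="timepoint_shuffle"`` permutes theta-phase time points within
    the trial, the literal phase-scrambling surrogate.  The full
    window/splice/trial-average aggregation is recomputed for every
    permutation.  Percentile use wants ``n_perm >= 100``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if method not in ("circular_shift", "timepoint_shuffle"):
        raise ValueError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng() if rng is None else rng

    sl = window.sample_slice(times)
    n_win = sl.stop - sl.start
    n_ch, n_tr = theta_phase.shape[0], theta_phase.shape[1]
    mult = None
    n_points = n_win
    if equalize_to is not None and equalize_to > n_win:
        # Splice multiplicities enter as weights; drawn once per trial, like
        # the observed path.
        mult = np.stack(
            [
                np.bincount(splice_indices(n_win, equalize_to, rng), minlength=n_win)
                for _ in range(n_tr)
            ]
        ).astype(float)[:, np.newaxis, :]  # (tr, 1, n_win)
        n_points = equalize_to

    conditions = np.asarray(conditions)
    gamma_freqs = np.asarray(gamma_freqs, dtype=float)
    # fixed draws shared by all channels, like the observed aggregation path
    if method == "circular_shift":
        lo = max(1, int(np.floor(min_shift_frac * n_win)))
        hi = n_win - lo
        if hi <= lo:
            lo, hi = 1, n_win
        shifts = rng.integers(lo, hi, size=(n_perm, n_tr))
    else:
        perm_idx = np.argsort(rng.random((n_perm, n_tr, n_win)), axis=-1)

    rows = []
    for ci in range(n_ch):
        th3, ep3 = _channel_window_pairs(theta_phase, amplitude, ci, sl)
        if method == "circular_shift":
            plv_shift = _all_shift_plv(th3, ep3, mult, float(n_points))
            # gather plv at each trial's shift, then average trials per condition
            per_trial = np.take_along_axis(
                plv_shift[np.newaxis, :, :, :],
                shifts[:, :, np.newaxis, np.newaxis],
                axis=-1,
            )[..., 0]  # (n_perm, tr, nf)
        else:  # timepoint_shuffle
            z = np.exp(1j * th3)  # (tr, 1, n_win)
            w = np.exp(-1j * ep3)
            if mult is not None:
                w = w * mult
            per_trial = np.empty((n_perm, n_tr, ep3.shape[1]))
            for p in range(n_perm):
                z_p = np.take_along_axis(z, perm_idx[p][:, np.newaxis, :], axis=-1)
                per_trial[p] = np.abs((z_p * w).sum(axis=-1)) / float(n_points)
        for cond in pd.unique(conditions):
            sel = conditions == cond
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                mean_plv = np.nanmean(per_trial[:, sel, :], axis=1)  # (n_perm, nf)
            for p in range(n_perm):
                for fi, f in enumerate(gamma_freqs):
                    rows.append(
                        {
                            "perm": p,
                            "condition": cond,
                            "window": window.name,
                            "channel": ch_names[ci],
                            "gamma_freq": f,
                            "plv": mean_plv[p, fi],
                        }
                    )
    return NullDistribution(table=pd.DataFrame(rows), method=method, n_perm=n_perm)


def aggregate(
    table: pd.DataFrame,
    band: tuple[float, float],
    channels: list[str],
) -> pd.DataFrame:
    """Average PLV over a gamma band's frequency rows, then over a cluster.

    Works on observed PLV tables and on permutation-null tables alike (every
    column other than channel/gamma_freq/plv bookkeeping is kept as a
    grouping key).  Both stages are unweighted means.
    """
    if not channels:
        raise ValueError("empty electrode cluster")
    lo, hi = band
    sub = table[
        (table["gamma_freq"] >= lo - 1e-9)
        & (table["gamma_freq"] <= hi + 1e-9)
        & table["channel"].isin(channels)
    ]
    if sub.empty:
        raise ValueError(f"no PLV cells for band {band} and cluster {channels}")
    keys = [
        c
        for c in sub.columns
        if c not in ("channel", "gamma_freq", "plv", "n_trials", "n_points")
    ]
    per_ch = sub.groupby(keys + ["channel"], observed=True)["plv"].mean().reset_index()
    return per_ch.groupby(keys, observed=True)["plv"].mean().reset_index()


# ---------------------------------------------------------------------------
# Phase-binned amplitude profiles
# ---------------------------------------------------------------------------


@dataclass
class PhaseBinProfile:
    """Mean normalized gamma amplitude per theta-phase bin on (-pi, pi]."""

    bin_edges: np.ndarray  # n_bins + 1
    means: np.ndarray  # n_bins, NaN where a bin is empty
    counts: np.ndarray  # n_bins, sums to pooled sample count

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def phase_bin_profile(
    theta_phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = 18,
) -> PhaseBinProfile:
    """Bin per-trial mean-normalized gamma amplitude by concurrent theta phase.

    ``theta_phase`` and ``amplitude`` are trials x window-samples for one
    electrode and gamma frequency (1-D input is treated as a single trial).
    Each trial's amplitude is divided by its within-window mean, then all
    (phase, amplitude) samples are pooled into ``n_bins`` equal-width bins.
    The count-weighted mean of bin means is exactly 1.
    """
    th = np.atleast_2d(np.asarray(theta_phase, dtype=float))
    amp = np.atleast_2d(np.asarray(amplitude, dtype=float))
    if th.shape != amp.shape:
        raise ValueError("phase and amplitude must share their shape")
    trial_means = amp.mean(axis=-1, keepdims=True)
    if (trial_means <= 0).any():
        raise ValueError("amplitude must have positive mean in the window")
    norm = (amp / trial_means).ravel()
    phases = th.ravel()

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # map (-pi, pi] onto bins 0..n_bins-1; exact -pi wraps to the last bin
    idx = np.ceil((phases + np.pi) / (2.0 * np.pi) * n_bins).astype(int) - 1
    idx = np.where(idx < 0, n_bins - 1, np.clip(idx, 0, n_bins - 1))
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=norm, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PhaseBinProfile(bin_edges=edges, means=means, counts=counts)


def average_profiles(profiles: list[PhaseBinProfile]) -> PhaseBinProfile:
    """Unweighted average of per-electrode profiles (cluster averaging)."""
    if not profiles:
        raise ValueError("no profiles to average")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles must share their bin edges")
    means = np.nanmean(np.stack([p.means for p in profiles]), axis=0)
    counts = np.stack([p.counts for p in profiles]).sum(axis=0)
    return PhaseBinProfile(bin_edges=edges, means=means, counts=counts)


def modulation_depth(profile: PhaseBinProfile) -> float:
    """First-harmonic amplitude of the profile around its mean of 1.

    For a profile 1 + d*cos(theta - phi) this returns ~d; it is robust to
    bin noise because it projects on the fundamental rather than taking a
    max-minus-min range.
    """
    ok = np.isfinite(profile.means)
    centers = profile.bin_centers[ok]
    vals = profile.means[ok]
    return float(2.0 * np.abs(np.mean(vals * np.exp(1j * centers))))


def preferred_phase(profile: PhaseBinProfile) -> float:
    """Phase (radians) at which the profile peaks, from its first harmonic."""
    ok = np.isfinite(profile.means)
    centers = profile.bin_centers[ok]
    vals = profile.means[ok]
    return float(np.angle(np.mean(vals * np.exp(1j * centers))))
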