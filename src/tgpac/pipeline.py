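"""End-to-end in-silico study: simulate -> preprocess -> decompose -> PLV ->
subject cell table -> planned statistics.

A *study* simulates ``n_subjects`` independent participants with the same
generator settings (each from its own child seed), runs the full coupling
pipeline per subject, aggregates PLV to condition x window x cluster x band
cells, and applies the planned contrasts.  ``run_pipeline`` additionally
writes every product (tables, manifest) to a run directory; rerunning with
the same config reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .capacity import estimate_capacity
from .pac import (
    POST_WINDOW,
    PRE_WINDOW,
    WindowSpec,
    aggregate,
    shuffle_null,
    windowed_plv,
)
from .preprocess import (
    baseline_correct,
    log_skipped_steps,
    reject_high_amplitude_trials,
    surface_laplacian,
)
from .stats import WM_CONTRAST, focused_contrast_test
from .synth import BehavioralConfig, SynthConfig, generate_behavioral_data
from .synth import generate_epoched_dataset
from .tfr import extract_amplitude, extract_phase, morlet_decompose

__all__ = ["StudyConfig", "run_subject", "run_study", "run_pipeline"]

_DEFAULT_BANDS = {"low": (25.0, 35.0), "high": (45.0, 55.0)}


@dataclass
class StudyConfig:
    """Everything needed to reproduce an in-silico study run.

    ``bands`` maps band labels to (lo, hi) Hz; ``gamma_freqs`` defaults to
    the integer grid covering all bands.  ``csd`` is "none", "hjorth" or
    "spline"; ``splice`` resamples the shorter window's phase pairs up to the
    longest window's length.  ``n_perm`` > 0 adds a per-subject shuffle null.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    behavior: BehavioralConfig | None = field(default_factory=BehavioralConfig)
    n_subjects: int = 20
    theta_freq: float = 6.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )
    gamma_freqs: tuple[float, ...] | None = None
    windows: tuple[WindowSpec, ...] = (PRE_WINDOW, POST_WINDOW)
    splice: bool = True
    n_perm: int = 0
    shuffle_method: str = "circular_shift"
    csd: str = "none"
    reject_uV: float = 150.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    contrast_weights: tuple[float, ...] = WM_CONTRAST
    seed: int = 0

    def resolved_gamma_freqs(self) -> np.ndarray:
        if self.gamma_freqs is not None:
            return np.asarray(self.gamma_freqs, dtype=float)
        freqs: set[float] = set()
        for lo, hi in self.bands.values():
            freqs.update(np.arange(np.ceil(lo), np.floor(hi) + 0.5))
        return np.asarray(sorted(freqs), dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["montage"] = (
            self.synth.montage.to_dict() if self.synth.montage else None
        )
        d["windows"] = [
            {"name": w.name, "start_ms": w.start_ms, "end_ms": w.end_ms}
            for w in self.windows
        ]
        return d


def _preprocess(rec, config: StudyConfig):
    rec = baseline_correct(rec, config.baseline_ms)
    rec, rej = reject_high_amplitude_trials(rec, config.reject_uV)
    rec = log_skipped_steps(rec)
    if config.csd != "none":
        rec = surface_laplacian(rec, method=config.csd)
    else:
        warnings.warn(
            "running coupling analysis on voltage (no CSD transform)",
            stacklevel=2,
        )
    return rec, rej


def run_subject(
    config: StudyConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline for one simulated subject.

    Returns ``(plv_table, cells)``: the per-electrode, per-gamma-frequency
    PLV table and its cluster x band aggregation (one row per condition x
    window x cluster x band).
    """
    synth_cfg = replace(config.synth, seed=config.seed if seed is None else seed)
    rec = generate_epoched_dataset(synth_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        rec, _ = _preprocess(rec, config)

    gamma = config.resolved_gamma_freqs()
    freqs = np.concatenate(([config.theta_freq], gamma))
    decomp = morlet_decompose(rec, freqs)
    for w in config.windows:
        for f in freqs:
            valid = decomp.valid_slice(f)
            wsl = w.sample_slice(rec.times)
            if wsl.start < valid.start or wsl.stop > valid.stop:
                raise ValueError(
                    f"window {w.name!r} leaves the valid wavelet support at {f} Hz"
                )
    theta_phase = extract_phase(decomp, config.theta_freq)
    amplitude, gamma_freqs = extract_amplitude(decomp, (gamma.min(), gamma.max()))

    rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else seed, 0xE17]).generate_state(1)
    )
    target = max(w.n_samples(rec.times) for w in config.windows)
    tables = []
    for w in config.windows:
        eq = target if (config.splice and w.n_samples(rec.times) < target) else None
        tables.append(
            windowed_plv(
                theta_phase,
                amplitude,
                w,
                times=rec.times,
                conditions=rec.conditions,
                ch_names=rec.ch_names,
                gamma_freqs=gamma_freqs,
                equalize_to=eq,
                rng=rng,
            )
        )
    plv_table = pd.concat(tables, ignore_index=True)

    cells = []
    montage = rec.montage
    for band_name, band in config.bands.items():
        for cluster in ("frontal", "posterior"):
            channels = [c for c in montage.cluster(cluster) if c in rec.ch_names]
            if not channels:
                continue
            agg = aggregate(plv_table, band=band, channels=channels)
            agg["cluster"] = cluster
            agg["band"] = band_name
            cells.append(agg)
    return plv_table, pd.concat(cells, ignore_index=True)


def run_study(config: StudyConfig) -> dict:
    """Simulate and analyze a multi-subject study.

    Returns a dict with ``cells`` (subject x condition x window x cluster x
    band PLV table), ``contrasts`` (planned-test results per cluster x band),
    ``capacity`` (per-subject K estimates, if behavior is configured), and
    ``null`` (per-subject aggregated shuffle-null summaries when
    ``n_perm > 0``).
    """
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_subjects)]

    all_cells = []
    for si, sseed in enumerate(subject_seeds):
        _, cells = run_subject(config, seed=sseed)
        cells.insert(0, "subject", si)
        all_cells.append(cells)
    cells = pd.concat(all_cells, ignore_index=True)

    contrasts = focused_contrast_test(
        cells,
        weights=config.contrast_weights,
        conditions=list(config.synth.conditions),
    )

    out = {"cells": cells, "contrasts": contrasts, "config": config}

    if config.behavior is not None:
        cap_rows = []
        for si, sseed in enumerate(subject_seeds):
            beh_cfg = replace(config.behavior, seed=(sseed + 1) % (2**31))
            table = generate_behavioral_data(beh_cfg)
            est = estimate_capacity(table, paradigm=beh_cfg.paradigm)
            cap_rows.append(
                {"subject": si, "K": est.overall_K, "formula": est.formula}
            )
        out["capacity"] = pd.DataFrame(cap_rows)

    if config.n_perm > 0:
        out["null"] = _study_null(config, subject_seeds)
    return out


def _study_null(config: StudyConfig, subject_seeds: list[int]) -> pd.DataFrame:
    """Per-subject shuffle-null summaries on the cluster/band aggregate."""
    rows = []
    gamma = config.resolved_gamma_freqs()
    for si, sseed in enumerate(subject_seeds):
        synth_cfg = replace(config.synth, seed=sseed)
        rec = generate_epoched_dataset(synth_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            rec, _ = _preprocess(rec, config)
        freqs = np.concatenate(([config.theta_freq], gamma))
        decomp = morlet_decompose(rec, freqs)
        theta_phase = extract_phase(decomp, config.theta_freq)
        amplitude, gamma_freqs = extract_amplitude(decomp, (gamma.min(), gamma.max()))
        rng = np.random.default_rng(
            np.random.SeedSequence([sseed, 0x5EED]).generate_state(1)
        )
        target = max(w.n_samples(rec.times) for w in config.windows)
        for w in config.windows:
            eq = target if (config.splice and w.n_samples(rec.times) < target) else None
            null = shuffle_null(
                theta_phase,
                amplitude,
                w,
                config.n_perm,
                times=rec.times,
                conditions=rec.conditions,
                ch_names=rec.ch_names,
                gamma_freqs=gamma_freqs,
                method=config.shuffle_method,
                equalize_to=eq,
                rng=rng,
            )
            for band_name, band in config.bands.items():
                for cluster in ("frontal", "posterior"):
                    channels = rec.montage.cluster(cluster)
                    agg = aggregate(null.table, band=band, channels=channels)
                    summ = (
                        agg.groupby(["condition", "window"], observed=True)["plv"]
                        .agg(
                            null_mean="mean",
                            null_q025=lambda v: v.quantile(0.025),
                            null_q975=lambda v: v.quantile(0.975),
                        )
                        .reset_index()
                    )
                    summ.insert(0, "subject", si)
                    summ["cluster"] = cluster
                    summ["band"] = band_name
                    rows.append(summ)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> Path:
    """Run the study and write tables plus a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_study(config)
    result["cells"].to_csv(out / "cells.csv", index=False)
    result["contrasts"].to_csv(out / "contrasts.csv", index=False)
    if "capacity" in result:
        result["capacity"].to_csv(out / "capacity.csv", index=False)
    if "null" in result:
        result["null"].to_csv(out / "null.csv", index=False)
    manifest = {
        "tgpac_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
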