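"""Epoched EEG container and its on-disk format.

The native container is a directory holding a ``data.npy`` array
(channels x trials x samples, float32) and a ``meta.json`` sidecar with the
sampling rate, time axis, channel labels, per-trial condition labels, montage
and units.  Ground-truth simulation metadata, when present, is stored in the
sidecar under ``info`` so it round-trips unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "EpochedRecording"]


@dataclass
class Montage:
    """Channel layout: labels, unit-sphere positions and cluster membership.

    ``phi_offsets`` holds the per-channel preferred-coupling-phase offset
    (radians) used by the synthetic generator; it is 0.0 for every channel of
    a phase-homogeneous montage.
    """

    ch_names: list[str]
    positions: dict[str, tuple[float, float, float]]
    frontal: list[str]
    posterior: list[str]
    phi_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.frontal) & set(self.posterior)
        if overlap:
            raise ValueError(f"clusters must be disjoint, overlap: {sorted(overlap)}")
        for name in self.frontal + self.posterior:
            if name not in self.ch_names:
                raise ValueError(f"cluster channel {name!r} not in montage")
        for name in self.ch_names:
            self.phi_offsets.setdefault(name, 0.0)

    def cluster(self, name: str) -> list[str]:
        if name == "frontal":
            return list(self.frontal)
        if name == "posterior":
            return list(self.posterior)
        raise KeyError(f"unknown cluster {name!r}")

    def position_array(self, ch_names: list[str] | None = None) -> np.ndarray:
        names = ch_names or self.ch_names
        missing = [c for c in names if c not in self.positions]
        if missing:
            raise ValueError(f"montage has no positions for {missing}")
        return np.asarray([self.positions[c] for c in names], dtype=float)

    def to_dict(self) -> dict:
        return {
            "ch_names": list(self.ch_names),
            "positions": {k: list(v) for k, v in self.positions.items()},
            "frontal": list(self.frontal),
            "posterior": list(self.posterior),
            "phi_offsets": dict(self.phi_offsets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            ch_names=list(d["ch_names"]),
            positions={k: tuple(v) for k, v in d["positions"].items()},
            frontal=list(d["frontal"]),
            posterior=list(d["posterior"]),
            phi_offsets={k: float(v) for k, v in d.get("phi_offsets", {}).items()},
        )


@dataclass
class EpochedRecording:
    """Epoched multichannel recording: channels x trials x samples.

    ``times`` is in milliseconds relative to stimulus onset; ``units`` is
    ``"uV"`` for scalp voltage and ``"CSD"`` after the surface-Laplacian
    transform.  ``info`` is free-form metadata (e.g. simulation ground truth,
    processing log entries).
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    ch_names: list[str]
    conditions: np.ndarray
    montage: Montage | None = None
    units: str = "uV"
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x trials x samples")
        n_ch, n_tr, n_samp = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length does not match data")
        if len(self.conditions) != n_tr:
            raise ValueError("every trial needs a condition label")
        if len(self.times) != n_samp:
            raise ValueError("time axis length must equal sample count")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("stimulus onset (t=0) must lie within the epoch")

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def t0_index(self) -> int:
        """Sample index of stimulus onset (first sample with t >= 0)."""
        return int(np.searchsorted(self.times, 0.0))

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label {name!r}") from None

    def copy_with(self, data: np.ndarray, **updates) -> "EpochedRecording":
        kwargs = dict(
            fs=self.fs,
            times=self.times.copy(),
            ch_names=list(self.ch_names),
            conditions=self.conditions.copy(),
            montage=self.montage,
            units=self.units,
            info=dict(self.info),
        )
        kwargs.update(updates)
        return EpochedRecording(data=data, **kwargs)

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write the native container (``data.npy`` + ``meta.json``)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "data.npy", self.data.astype(np.float32))
        meta = {
            "fs": self.fs,
            "times_ms": self.times.tolist(),
            "ch_names": list(self.ch_names),
            "conditions": [str(c) for c in self.conditions],
            "units": self.units,
            "montage": self.montage.to_dict() if self.montage else None,
            "info": self.info,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EpochedRecording":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        data = np.load(path / "data.npy").astype(float)
        montage = Montage.from_dict(meta["montage"]) if meta.get("montage") else None
        return cls(
            data=data,
            fs=float(meta["fs"]),
            times=np.asarray(meta["times_ms"], dtype=float),
            ch_names=list(meta["ch_names"]),
            conditions=np.asarray(meta["conditions"]),
            montage=montage,
            units=meta.get("units", "uV"),
            info=meta.get("info", {}),
        )
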