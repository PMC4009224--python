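"""Containers and file I/O for traces, event sets and model files.

All times are seconds internally.  Trace files are little-endian binary
(float32 or int16) or one-sample-per-line text; event files are delimited
text with a header row (``time_s, w0..w{D-1}[, label]``) plus a key-value
sidecar; model files are flat key-value text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "EventSet",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_model",
    "write_model",
    "read_config",
]

_TRACE_FORMATS = {"binary-f32": np.dtype("<f4"), "binary-i16": np.dtype("<i2")}


@dataclass
class Trace:
    """A uniformly sampled voltage trace.

    Sample ``i`` occurs at time ``t0 + i / rate`` seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class EventSet:
    """Detected firing times plus per-event waveforms or features.

    ``z`` holds N strictly increasing times in seconds; ``X`` is the N x D
    waveform/feature matrix; ``labels``, when present, are cluster indices
    in ``[0, K)``.
    """

    z: np.ndarray
    X: np.ndarray
    labels: Optional[np.ndarray] = None
    rate: Optional[float] = None
    window_ms: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.z.size:
            raise ValueError(
                f"waveform rows ({self.X.shape[0]}) != event count ({self.z.size})"
            )
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).ravel()
            if self.labels.size != self.z.size:
                raise ValueError("labels length != event count")
            if self.labels.size and self.labels.min() < 0:
                raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return self.z.size

    @property
    def n_events(self) -> int:
        return self.z.size

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def with_labels(self, labels: np.ndarray) -> "EventSet":
        return EventSet(self.z, self.X, labels=labels, rate=self.rate,
                        window_ms=self.window_ms, meta=dict(self.meta))


def read_trace(path: str, fmt: str = "binary-f32", rate: float = 20000.0) -> Trace:
    """Read a voltage trace from ``path``.

    ``fmt`` is one of ``binary-f32``, ``binary-i16`` (little-endian) or
    ``delimited-text`` (one sample per line).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt in _TRACE_FORMATS:
        samples = np.fromfile(path, dtype=_TRACE_FORMATS[fmt]).astype(float)
    elif fmt == "delimited-text":
        try:
            samples = np.loadtxt(path, dtype=float).ravel()
        except ValueError as exc:
            raise ValueError(f"non-numeric trace text in {path}") from exc
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    if samples.size == 0:
        raise ValueError(f"empty trace file {path}")
    return Trace(samples, rate)


def write_trace(trace: Trace, path: str, fmt: str = "binary-f32") -> None:
    if fmt in _TRACE_FORMATS:
        np.asarray(trace.samples, dtype=_TRACE_FORMATS[fmt]).tofile(path)
    elif fmt == "delimited-text":
        np.savetxt(path, trace.samples, fmt="%.12g")
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def _sidecar_path(path: str) -> str:
    return path + ".meta"


def write_events(events: EventSet, path: str) -> None:
    """Write an event set as delimited text with a key-value sidecar."""
    d = events.n_features
    cols = {"time_s": events.z}
    for j in range(d):
        cols[f"w{j}"] = events.X[:, j]
    if events.labels is not None:
        cols["label"] = events.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    meta = {"n_events": events.n_events, "n_features": d}
    if events.rate is not None:
        meta["rate"] = events.rate
    if events.window_ms is not None:
        meta["window_ms"] = events.window_ms
    meta.update(events.meta)
    with open(_sidecar_path(path), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")


def read_events(path: str) -> EventSet:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path} has no time_s column")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    z = df.pop("time_s").to_numpy(dtype=float)
    X = df.to_numpy(dtype=float)
    meta: dict = {}
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            for line in fh:
                line = line.strip()
                if not line or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                meta[k] = v
    rate = float(meta.pop("rate")) if "rate" in meta else None
    window_ms = float(meta.pop("window_ms")) if "window_ms" in meta else None
    return EventSet(z, X, labels=labels, rate=rate, window_ms=window_ms, meta=meta)


def write_model(model, path: str) -> None:
    """Serialize a ModelSet as flat key-value text (times in seconds)."""
    with open(path, "w") as fh:
        fh.write(f"K={model.K}\nD={model.D}\ntau_win={float(model.tau_win)!r}\n"
                 f"L={model.L}\nunits=seconds\n")
        for j, c in enumerate(model.clusters):
            fh.write(f"cluster{j}.mu_w="
                     f"{' '.join(repr(float(v)) for v in c.mu_w)}\n")
            fh.write(f"cluster{j}.cov_w="
                     f"{' '.join(repr(float(v)) for v in c.cov_w.ravel())}\n")
            fh.write(f"cluster{j}.mu_isi={float(c.mu_isi)!r}\n")
            fh.write(f"cluster{j}.var_isi={float(c.var_isi)!r}\n")
            fh.write(f"cluster{j}.beta={float(c.beta)!r}\n")
            fh.write(f"cluster{j}.prior={float(c.prior)!r}\n")


def read_model(path: str):
    """Inverse of :func:`write_model`."""
    from .models import ClusterParams, ModelSet

    kv = dict(read_config(path))
    K, d = int(kv["K"]), int(kv["D"])
    clusters = []
    for j in range(K):
        mu_w = np.array([float(v) for v in kv[f"cluster{j}.mu_w"].split()])
        cov_w = np.array([float(v) for v in kv[f"cluster{j}.cov_w"].split()])
        clusters.append(ClusterParams(
            mu_w, cov_w.reshape(d, d), float(kv[f"cluster{j}.mu_isi"]),
            float(kv[f"cluster{j}.var_isi"]), float(kv[f"cluster{j}.beta"]),
            float(kv[f"cluster{j}.prior"])))
    return ModelSet(clusters, float(kv["tau_win"]), L=int(kv["L"]))


def read_config(path: str) -> dict:
    """Flat key=value text file -> dict of strings."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
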