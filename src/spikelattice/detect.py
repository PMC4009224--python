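"""Spike detection on continuous traces.

High-pass filtering, robust noise estimation, amplitude-threshold spike
detection with peak-aligned waveform extraction, intracellular (IC) spike
detection, and matching of extracellular events to IC ground-truth times.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal

from .io import EventSet, Trace

__all__ = [
    "highpass",
    "noise_sigma",
    "detect_spikes",
    "detect_ic_spikes",
    "match_ic_labels",
]

# median(|N(0,1)|) — converts the median absolute value to a Gaussian sigma
_MAD_NORM = 0.6745


def highpass(trace: Trace, cutoff: float = 300.0, order: int = 4) -> Trace:
    """Zero-phase Butterworth high-pass filter (removes baseline drift)."""
    nyq = trace.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=trace.rate, output="sos")
    return Trace(signal.sosfiltfilt(sos, trace.samples), trace.rate, trace.t0)


def noise_sigma(x) -> float:
    """Robust noise standard deviation: ``median(|x|) / 0.6745``.

    Insensitive to the sparse large-amplitude spikes that inflate the plain
    standard deviation.
    """
    samples = x.samples if isinstance(x, Trace) else np.asarray(x, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot estimate noise on an empty trace")
    return float(np.median(np.abs(samples)) / _MAD_NORM)


def _excursion_peaks(sig: np.ndarray, thresh: float) -> np.ndarray:
    """Index of the |signal| maximum of each contiguous supra-threshold run."""
    above = np.abs(sig) > thresh
    if not above.any():
        return np.empty(0, dtype=int)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    peaks = np.empty(starts.size, dtype=int)
    absig = np.abs(sig)
    for i, (a, b) in enumerate(zip(starts, stops)):
        peaks[i] = a + int(np.argmax(absig[a:b]))
    return peaks


def _merge_close(peaks: np.ndarray, amps: np.ndarray, min_sep: int) -> np.ndarray:
    """Merge peaks closer than ``min_sep`` samples, keeping the larger one."""
    if peaks.size <= 1:
        return peaks
    kept = [0]
    for i in range(1, peaks.size):
        if peaks[i] - peaks[kept[-1]] < min_sep:
            if amps[i] > amps[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return peaks[kept]


def window_samples(window_ms: float, rate: float) -> int:
    """Window length in samples, forced odd so a unique center exists."""
    n = int(round(window_ms * rate / 1000.0))
    return n + 1 if n % 2 == 0 else n


def detect_spikes(
    trace: Trace,
    thresh_mult: float = 5.0,
    window_ms: float = 4.0,
    merge_ms: float = 1.0,
    sigma: Optional[float] = None,
) -> EventSet:
    """Detect threshold-crossing spikes and extract peak-centered waveforms.

    An event is the local-maximum sample of each contiguous excursion of
    ``|signal|`` above ``thresh_mult * noise_sigma``.  Events closer than
    ``merge_ms`` are merged keeping the larger peak; events whose waveform
    window would overrun the trace are dropped.
    """
    sig = trace.samples
    sd = noise_sigma(trace) if sigma is None else sigma
    peaks = _excursion_peaks(sig, thresh_mult * sd)
    peaks = _merge_close(peaks, np.abs(sig[peaks]), int(round(merge_ms * trace.rate / 1000.0)))
    wlen = window_samples(window_ms, trace.rate)
    half = wlen // 2
    peaks = peaks[(peaks >= half) & (peaks + half < sig.size)]
    X = np.stack([sig[p - half: p + half + 1] for p in peaks]) if peaks.size else np.empty((0, wlen))
    z = trace.t0 + peaks / trace.rate
    return EventSet(z, X, rate=trace.rate, window_ms=window_ms,
                    meta={"thresh_mult": thresh_mult, "sigma": sd})


def detect_ic_spikes(ic: Trace, thresh_mult: float = 5.0,
                     merge_ms: float = 1.0) -> np.ndarray:
    """Firing times from an intracellular trace.

    Peaks of the first backward difference exceeding a robust threshold
    (``thresh_mult * noise_sigma`` of the differenced signal) mark the fast
    rising edge of each action potential; peaks closer than ``merge_ms``
    belong to one depolarization and are merged keeping the larger slope.
    """
    if ic.samples.size < 2:
        raise ValueError("IC trace too short to difference")
    d = np.diff(ic.samples)
    sd = noise_sigma(d)
    if sd == 0:
        # flat trace (plus possible isolated steps): fall back to absolute scale
        if not np.any(np.abs(d) > 0):
            return np.empty(0)
        sd = float(np.max(np.abs(d))) / (2.0 * thresh_mult)
    peaks = _excursion_peaks(d, thresh_mult * sd)
    peaks = _merge_close(peaks, np.abs(d[peaks]),
                         int(round(merge_ms * ic.rate / 1000.0)))
    # backward difference d[i] = x[i+1] - x[i]: edge belongs to sample i+1
    return ic.t0 + (peaks + 1) / ic.rate


def match_ic_labels(ec_times, ic_times, tol_ms: float = 1.0) -> np.ndarray:
    """Boolean mask: EC events within ``tol_ms`` (inclusive) of any IC spike."""
    ec = np.asarray(ec_times, dtype=float).ravel()
    ic = np.asarray(ic_times, dtype=float).ravel()
    if ic.size == 0:
        return np.zeros(ec.size, dtype=bool)
    idx = np.searchsorted(ic, ec)
    left = ic[np.clip(idx - 1, 0, ic.size - 1)]
    right = ic[np.clip(idx, 0, ic.size - 1)]
    dist = np.minimum(np.abs(ec - left), np.abs(ec - right))
    return dist <= tol_ms / 1000.0 + 1e-12
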