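"""Waveform features: PCA dimensionality reduction and SNR-controlled noise.

A deterministic sign convention (largest-|loading| element positive) is
applied on top of the underlying PCA fit so repeated fits agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PCAModel", "fit_pca", "transform", "inverse_transform", "add_noise_snr"]


@dataclass
class PCAModel:
    mean: np.ndarray                 # (D,)
    components: np.ndarray           # (n_comp, D), orthonormal rows
    explained_variance: np.ndarray   # (n_comp,), non-increasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(X: np.ndarray, n_comp: int) -> PCAModel:
    """Top principal components of the sample covariance of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if not 1 <= n_comp <= min(n, d):
        raise ValueError(f"n_comp must be in [1, {min(n, d)}]")
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(pca.mean_.copy(), comps, pca.explained_variance_.copy())


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError("feature dimension mismatch")
    return (X - model.mean) @ model.components.T


def inverse_transform(model: PCAModel, Y: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return Y @ model.components + model.mean


def add_noise_snr(X: np.ndarray, snr_db: float, seed) -> np.ndarray:
    """Add i.i.d. Gaussian noise at a target signal-to-noise ratio.

    ``SNR_dB = 10*log10(mean(X**2) / noise_variance)`` over all entries of
    the clean matrix; ``snr_db = inf`` returns ``X`` unchanged.  ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    X = np.asarray(X, dtype=float)
    if np.isinf(snr_db) and snr_db > 0:
        return X.copy()
    p_signal = float(np.mean(X ** 2))
    if p_signal == 0:
        raise ValueError("SNR is undefined for an all-zero signal")
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)
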