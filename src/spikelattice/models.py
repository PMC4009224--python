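"""Probability models of the joint waveform / spike-train likelihood.

Each neuronal cluster j carries three stationary distributions:

* waveform: multivariate Gaussian ``N(x; mu_j, Sigma_j)``,
* interspike interval (ISI): lognormal with parameters ``(mu_isi, var_isi)``
  on the log of the interval,
* first firing after an empty history window: Poisson with rate ``beta``
  evaluated at event count k = 1, i.e. ``w(t) = beta*t*exp(-beta*t)``,

plus an empirical cluster prior.  All computation is in the log domain;
internal time unit is seconds (lognormal parameters are therefore in
log-seconds; conversion helpers handle the millisecond convention used when
quoting ISI statistics).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import ndtri

__all__ = [
    "ClusterParams",
    "ModelSet",
    "gaussian_loglik",
    "lognormal_logpdf",
    "lognormal_logsf",
    "first_firing_loglik",
    "event_time_loglik",
    "estimate_params",
    "estimate_tau",
    "logms_to_logs",
    "logs_to_logms",
]

LOG_2PI = math.log(2.0 * math.pi)
_LN_1000 = math.log(1000.0)

#: default ridge scale for covariance regularization
RIDGE = 1e-6
#: floor on the lognormal log-variance (unit-free: variance of a log)
VAR_FLOOR = 1e-4


def logms_to_logs(mu_logms: float) -> float:
    """Lognormal location parameter: log-milliseconds -> log-seconds."""
    return mu_logms - _LN_1000


def logs_to_logms(mu_logs: float) -> float:
    return mu_logs + _LN_1000


@dataclass
class ClusterParams:
    """Parameters of one neuronal cluster."""

    mu_w: np.ndarray          # waveform mean (D,)
    cov_w: np.ndarray         # waveform covariance (D, D)
    mu_isi: float             # lognormal location, log-seconds
    var_isi: float            # lognormal squared scale
    beta: float               # first-firing Poisson rate, 1/s
    prior: float              # cluster prior probability

    def __post_init__(self) -> None:
        self.mu_w = np.asarray(self.mu_w, dtype=float).ravel()
        self.cov_w = np.atleast_2d(np.asarray(self.cov_w, dtype=float))
        if self.var_isi <= 0:
            raise ValueError("var_isi must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class ModelSet:
    """A complete model: K clusters plus the decoder hyperparameters."""

    clusters: List[ClusterParams]
    tau_win: float            # history window, seconds
    L: int = 10000
    refractory: float = 0.0   # metadata only (seconds)

    def __post_init__(self) -> None:
        if len(self.clusters) < 1:
            raise ValueError("need at least one cluster")
        if self.tau_win <= 0:
            raise ValueError("tau_win must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def K(self) -> int:
        return len(self.clusters)

    @property
    def D(self) -> int:
        return self.clusters[0].mu_w.size

    def priors(self) -> np.ndarray:
        return np.array([c.prior for c in self.clusters])

    def permuted(self, perm) -> "ModelSet":
        """Model with cluster blocks reordered: new cluster i = old cluster perm[i]."""
        cl = [copy.deepcopy(self.clusters[p]) for p in perm]
        return ModelSet(cl, self.tau_win, self.L, self.refractory)


def gaussian_loglik(x, mu_w, cov_w) -> float:
    """Log density of a multivariate Gaussian at ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(mu_w, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov_w, dtype=float))
    d = x.size
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular waveform covariance") from exc
    sol = np.linalg.solve(chol, x - mu)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (d * LOG_2PI + logdet + sol @ sol))


def lognormal_logpdf(t, mu_isi: float, var_isi: float):
    """Log density of LogNormal(mu, var) at ``t > 0`` (array-friendly)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("lognormal support is t > 0")
    lt = np.log(t)
    out = -lt - 0.5 * (LOG_2PI + np.log(var_isi)) - (lt - mu_isi) ** 2 / (2.0 * var_isi)
    return float(out) if out.ndim == 0 else out


def lognormal_logsf(t, mu_isi: float, var_isi: float):
    """Log survival function of the lognormal (used by the full-train likelihood)."""
    from scipy.stats import norm

    t = np.asarray(t, dtype=float)
    out = norm.logsf((np.log(np.maximum(t, 1e-300)) - mu_isi) / math.sqrt(var_isi))
    out = np.where(t <= 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def first_firing_loglik(tau_win: float, beta: float) -> float:
    """Log probability of exactly one firing in a window of length ``tau_win``.

    Poisson pmf with k = 1: ``log(beta*tau) - beta*tau``.  ``beta = 0``
    yields ``-inf`` (an empty cluster can never fire), not an exception.
    """
    if tau_win <= 0:
        raise ValueError("tau_win must be positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta == 0.0:
        return -math.inf
    bt = beta * tau_win
    return math.log(bt) - bt


def event_time_loglik(
    z_n: float, zeta_j: Optional[float], params: ClusterParams, tau_win: float
) -> float:
    """Piecewise temporal term for one event.

    First-firing branch when the cluster has no occurrence in the history
    window (``zeta_j is None``), ISI branch otherwise.  The first-firing
    distribution is evaluated at the window length itself, not the elapsed
    time.
    """
    if zeta_j is None:
        return first_firing_loglik(tau_win, params.beta)
    if zeta_j >= z_n:
        raise ValueError("zeta_j must precede z_n")
    return float(lognormal_logpdf(z_n - zeta_j, params.mu_isi, params.var_isi))


def _pooled_cluster(z: np.ndarray, X: np.ndarray, T_total: float,
                    ridge: float, var_floor: float) -> ClusterParams:
    """All-data fallback parameters for degenerate clusters."""
    mu_w = X.mean(axis=0)
    cov_w = _reg_cov(X, mu_w, ridge)
    isis = np.diff(z)
    isis = isis[isis > 0]
    if isis.size >= 2:
        lg = np.log(isis)
        mu_isi, var_isi = float(lg.mean()), max(float(lg.var(ddof=1)), var_floor)
    elif isis.size == 1:
        mu_isi, var_isi = float(np.log(isis[0])), var_floor
    else:
        mu_isi, var_isi = math.log(0.02), 1.0  # weak default: 20 ms median
    beta = z.size / T_total if T_total > 0 else 0.0
    return ClusterParams(mu_w, cov_w, mu_isi, var_isi, beta, 1.0)


def _reg_cov(Xj: np.ndarray, mu: np.ndarray, ridge: float) -> np.ndarray:
    d = Xj.shape[1]
    if Xj.shape[0] >= 2:
        cov = np.cov(Xj, rowvar=False, ddof=1).reshape(d, d)
    else:
        cov = np.zeros((d, d))
    tr = np.trace(cov)
    eps = ridge * (tr / d if tr > 0 else 1.0)
    return cov + max(eps, 1e-12) * np.eye(d)


def estimate_params(
    events,
    K: int,
    T_total: float,
    prev: Optional[ModelSet] = None,
    ridge: float = RIDGE,
    var_floor: float = VAR_FLOOR,
    uniform_prior: bool = False,
    tau_win: Optional[float] = None,
    L: int = 10000,
) -> ModelSet:
    """Maximum-likelihood parameters from a labeled event set.

    Per cluster: waveform sample mean/covariance (ridge-regularized),
    lognormal parameters from the log of within-cluster ISIs, first-firing
    rate ``beta = N_j / T_total`` and empirical prior ``N_j / N``.  Clusters
    with fewer than 2 members or 2 ISIs keep the previous iteration's
    parameters, or pooled all-data estimates at initialization.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    z, X, labels = events.z, events.X, events.labels
    if labels is None:
        raise ValueError("estimate_params requires labels")
    if z.size == 0:
        raise ValueError("empty event set")
    if labels.max() >= K:
        raise ValueError("labels must lie in [0, K)")
    if T_total < z.max():
        raise ValueError("T_total must cover the last event")

    pooled = _pooled_cluster(z, X, T_total, ridge, var_floor)
    n = z.size
    clusters: List[ClusterParams] = []
    counts = np.array([(labels == j).sum() for j in range(K)])
    for j in range(K):
        mask = labels == j
        nj = int(counts[j])
        zj = z[mask]
        isis = np.diff(zj)
        isis = isis[isis > 0]
        fallback = prev.clusters[j] if prev is not None else pooled
        if nj >= 2:
            mu_w = X[mask].mean(axis=0)
            cov_w = _reg_cov(X[mask], mu_w, ridge)
        else:
            mu_w, cov_w = fallback.mu_w.copy(), fallback.cov_w.copy()
        if isis.size >= 2:
            lg = np.log(isis)
            mu_isi = float(lg.mean())
            var_isi = max(float(lg.var(ddof=1)), var_floor)
        elif isis.size == 1:
            mu_isi, var_isi = float(np.log(isis[0])), max(fallback.var_isi, var_floor)
        else:
            mu_isi, var_isi = fallback.mu_isi, fallback.var_isi
        beta = nj / T_total
        if beta == 0.0:
            warnings.warn(f"cluster {j} is empty; keeping fallback rate")
            beta = fallback.beta
        prior = 1.0 / K if uniform_prior else max(nj, 1e-12) / n
        clusters.append(ClusterParams(mu_w, cov_w, mu_isi, var_isi, beta, prior))
    tot = sum(c.prior for c in clusters)
    for c in clusters:
        c.prior /= tot
    tw = tau_win if tau_win is not None else (prev.tau_win if prev is not None else 1.0)
    return ModelSet(clusters, tw, L=L)


def estimate_tau(model: ModelSet, coverage: float = 0.99) -> float:
    """History window covering ``coverage`` of each ISI density; max over clusters.

    The lognormal quantile has the closed form
    ``exp(mu + sigma * Phi^-1(coverage))``; the window is the largest
    cluster quantile so that the empty-history branch fires rarely.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    q = ndtri(coverage)
    taus = [math.exp(c.mu_isi + math.sqrt(c.var_isi) * q) for c in model.clusters]
    return max(taus)
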