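"""The iterative sorting procedure, packaged as a scikit-learn estimator.

The procedure: (1) waveform-only EM-GMM clustering initializes the labels;
(2) all distribution parameters (waveform Gaussians, lognormal ISIs,
first-firing rates, priors) are estimated from that clustering and the
history window tau is chosen to cover 99% of each ISI density; (3) beam
decoding and parameter re-estimation alternate until the labels reach a
fixed point.  The procedure maximizes the joint likelihood only
approximately, so convergence is declared on unchanged labels rather than
on likelihood monotonicity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .decoder import decode, sequence_loglik
from .io import EventSet
from .models import ModelSet, estimate_params, estimate_tau

__all__ = ["SortingResult", "fit_gmm", "SpikeSorter", "sort"]


@dataclass
class SortingResult:
    labels: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    model: ModelSet
    init_labels: np.ndarray
    history: List[dict] = field(default_factory=list)


def fit_gmm(features: np.ndarray, K: int, seed=None, n_restarts: int = 5
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Full-covariance EM-GMM; MAP component per point.

    Best of ``n_restarts`` k-means++-seeded runs by log-likelihood.
    Returns ``(labels, means, covariances, weights)``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] < K:
        raise ValueError("need at least K points")
    gmm = GaussianMixture(
        n_components=K, covariance_type="full", n_init=n_restarts,
        init_params="k-means++", tol=1e-6, max_iter=500, random_state=seed,
    )
    labels = gmm.fit_predict(X)
    return labels, gmm.means_, gmm.covariances_, gmm.weights_


class SpikeSorter(ClusterMixin, BaseEstimator):
    """Joint waveform / spike-train spike sorter.

    Parameters
    ----------
    n_clusters : int
        Number of neuronal clusters K (fixed; never pruned).
    n_paths : int
        Beam width L of the lattice decoder.
    tau : float or None
        History window in seconds; estimated from the initial clustering
        via the coverage rule when None.
    coverage : float
        ISI density mass the window must cover when ``tau`` is None.
    max_iter : int
        Maximum decode/re-estimate iterations; 0 returns the GMM labels.
    n_restarts : int
        EM-GMM initializations.
    reestimate_tau : bool
        Re-derive tau after every re-estimation instead of holding it fixed.
    uniform_prior : bool
        Use fixed 1/K cluster priors (default) instead of per-iteration
        empirical proportions; empirical priors let large clusters absorb
        small ones over iterations (a rich-get-richer feedback), so the
        uniform prior is the stable default.
    random_state : int or None
        Seed for the GMM initialization; the whole fit is deterministic
        given it.

    Attributes
    ----------
    labels_ : final cluster labels.
    init_labels_ : waveform-only GMM labels.
    model_ : fitted :class:`ModelSet`.
    loglik_ : joint log-likelihood of ``labels_`` under ``model_``.
    n_iter_, converged_, history_ : iteration diagnostics.
    """

    def __init__(self, n_clusters: int = 3, n_paths: int = 10000,
                 tau: Optional[float] = None, coverage: float = 0.99,
                 max_iter: int = 20, n_restarts: int = 5,
                 reestimate_tau: bool = False, uniform_prior: bool = True,
                 random_state: Optional[int] = None):
        self.n_clusters = n_clusters
        self.n_paths = n_paths
        self.tau = tau
        self.coverage = coverage
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.reestimate_tau = reestimate_tau
        self.uniform_prior = uniform_prior
        self.random_state = random_state

    def fit(self, X, times, T_total: Optional[float] = None):
        """Sort events given features ``X`` (N x d) and firing times (s)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = np.asarray(times, dtype=float).ravel()
        if X.shape[0] != z.size:
            raise ValueError("X rows must match number of times")
        K = self.n_clusters
        T = float(T_total) if T_total is not None else float(z.max())

        init_labels, *_ = fit_gmm(X, K, seed=self.random_state,
                                  n_restarts=self.n_restarts)
        if len(np.unique(init_labels)) == 1 and K > 1:
            import warnings
            warnings.warn("degenerate initialization: one occupied cluster")
        events = EventSet(z, X, labels=init_labels)
        model = estimate_params(events, K, T, uniform_prior=self.uniform_prior,
                                L=self.n_paths)
        tau = self.tau if self.tau is not None else estimate_tau(model, self.coverage)
        model.tau_win = tau

        labels = init_labels.copy()
        history: List[dict] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            res = decode(events.with_labels(None), model, L=self.n_paths)
            n_changed = int(np.sum(res.labels != labels))
            model = estimate_params(events.with_labels(res.labels), K, T,
                                    prev=model, uniform_prior=self.uniform_prior,
                                    tau_win=model.tau_win, L=self.n_paths)
            if self.reestimate_tau and self.tau is None:
                model.tau_win = estimate_tau(model, self.coverage)
            labels = res.labels
            history.append({
                "loglik": float(sequence_loglik(events, labels, model)),
                "n_changed": n_changed,
                "model": copy.deepcopy(model),
            })
            if n_changed == 0:
                converged = True
                break
        else:
            it = self.max_iter

        self.labels_ = labels
        self.init_labels_ = init_labels
        self.model_ = model
        self.n_iter_ = len(history)
        self.converged_ = converged
        self.history_ = history
        self.loglik_ = float(sequence_loglik(events, labels, model))
        return self

    def fit_predict(self, X, times, T_total: Optional[float] = None):
        return self.fit(X, times, T_total=T_total).labels_

    def result(self) -> SortingResult:
        check_is_fitted(self, "labels_")
        return SortingResult(self.labels_, self.loglik_, self.n_iter_,
                             self.converged_, self.model_, self.init_labels_,
                             self.history_)


def sort(events: EventSet, K: int, L: int = 10000, tau: Optional[float] = None,
         seed: Optional[int] = None, max_iter: int = 20, coverage: float = 0.99,
         **kwargs) -> SortingResult:
    """Functional wrapper over :class:`SpikeSorter`."""
    est = SpikeSorter(n_clusters=K, n_paths=L, tau=tau, coverage=coverage,
                      max_iter=max_iter, random_state=seed, **kwargs)
    est.fit(events.X, events.z)
    return est.result()
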