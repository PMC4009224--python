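"""L-best beam-search decoding of the joint waveform / firing-time likelihood.

The label sequence ``c`` maximizing ``P(X, z, c)`` is searched on an event
lattice: events are processed in time order and at each event every retained
path (partial labeling) is extended by all K labels.  A path's state is the
label content of its history window ``(z_n - tau_win, z_n]``; paths with
identical window content are merged keeping the higher likelihood (the
future score depends only on the window), and the top L paths survive.

Per-event score for label j:

    log N(x_n; mu_j, Sigma_j) + log p(z_n | c_n = j, zeta_j) + log P(c_n = j)

where ``zeta_j`` is the most recent in-window occurrence time of label j;
when absent the first-firing distribution is evaluated at the window length.
Each of the three log terms is floored at -745 so a single impossible event
cannot annihilate a whole beam; the number of floored terms is reported.

Ties are broken deterministically: likelihood descending, then label
sequence lexicographically ascending (resolved only within exactly-equal
likelihood groups, which keeps the beam step vectorized).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import solve_triangular

from .io import EventSet
from .models import (
    LOG_2PI,
    ModelSet,
    event_time_loglik,
    first_firing_loglik,
    gaussian_loglik,
    lognormal_logpdf,
    lognormal_logsf,
)

__all__ = [
    "Path",
    "DecodeResult",
    "step_loglik",
    "decode",
    "sequence_loglik",
    "brute_force_decode",
    "ensemble_loglik",
    "gaussian_loglik_matrix",
]

#: floor applied to every per-event log term
CLIP = -745.0


@dataclass
class Path:
    """One beam-search hypothesis.

    ``window`` holds the (time, label) pairs inside the current history
    window, oldest first; ``full_labels`` is the complete label sequence so
    far and ``loglik`` its cumulative joint log-likelihood.
    """

    window: List[Tuple[float, int]] = field(default_factory=list)
    full_labels: List[int] = field(default_factory=list)
    loglik: float = 0.0

    def zeta(self, j: int) -> Optional[float]:
        """Most recent in-window occurrence time of label ``j`` (None if absent)."""
        for t, lab in reversed(self.window):
            if lab == j:
                return t
        return None


@dataclass
class DecodeResult:
    labels: np.ndarray
    loglik: float
    n_clipped: int = 0
    n_first_branch: int = 0


def gaussian_loglik_matrix(X: np.ndarray, model: ModelSet) -> np.ndarray:
    """N x K matrix of per-cluster Gaussian waveform log-likelihoods."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    G = np.empty((n, model.K))
    for j, c in enumerate(model.clusters):
        chol = np.linalg.cholesky(c.cov_w)
        sol = solve_triangular(chol, (X - c.mu_w).T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        G[:, j] = -0.5 * (d * LOG_2PI + logdet + np.sum(sol * sol, axis=0))
    return G


def step_loglik(x_n, z_n: float, j: int, path: Path, model: ModelSet) -> float:
    """Score of extending ``path`` with label ``j`` at event ``(x_n, z_n)``."""
    if path.window and z_n <= path.window[-1][0]:
        raise ValueError("z_n must exceed all window times")
    c = model.clusters[j]
    g = max(gaussian_loglik(x_n, c.mu_w, c.cov_w), CLIP)
    t = max(event_time_loglik(z_n, path.zeta(j), c, model.tau_win), CLIP)
    p = max(math.log(c.prior) if c.prior > 0 else -math.inf, CLIP)
    return g + t + p


def _model_arrays(model: ModelSet):
    mu = np.array([c.mu_isi for c in model.clusters])
    var = np.array([c.var_isi for c in model.clusters])
    w_const = np.array(
        [max(first_firing_loglik(model.tau_win, c.beta), CLIP) for c in model.clusters]
    )
    logprior = np.array(
        [max(math.log(c.prior) if c.prior > 0 else -math.inf, CLIP)
         for c in model.clusters]
    )
    return mu, var, w_const, logprior


def sequence_loglik(events: EventSet, labels, model: ModelSet,
                    return_detail: bool = False):
    """Joint log-likelihood of a full labeling, stated directly.

    Sums, over events in time order, the Gaussian waveform term, the
    piecewise temporal term (ISI density against the most recent in-window
    same-label event, first-firing otherwise) and the log prior.  This is
    the objective the beam decoder maximizes; the two branches of the
    temporal term need not agree at the window edge.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size != events.n_events:
        raise ValueError("labels length must equal event count")
    z = events.z
    tau = model.tau_win
    G = np.maximum(gaussian_loglik_matrix(events.X, model), CLIP)
    mu, var, w_const, logprior = _model_arrays(model)
    last: List[Optional[float]] = [None] * model.K
    total = 0.0
    n_first = 0
    n_clipped = int((G[np.arange(labels.size), labels] <= CLIP).sum())
    for n in range(labels.size):
        j = labels[n]
        lt = last[j]
        if lt is not None and lt > z[n] - tau:
            t = lognormal_logpdf(z[n] - lt, mu[j], var[j])
            if t < CLIP:
                t = CLIP
                n_clipped += 1
        else:
            t = w_const[j]
            n_first += 1
        total += (G[n, j] + t) + logprior[j]
        last[j] = z[n]
    if return_detail:
        return total, {"n_first_branch": n_first, "n_clipped": n_clipped}
    return total


def _reconstruct(parents: List[np.ndarray], labs: List[np.ndarray], idx: int,
                 upto: Optional[int] = None) -> list:
    """Label sequence of retained path ``idx`` after step ``upto`` (inclusive)."""
    out = []
    stop = len(labs) - 1 if upto is None else upto
    for step in range(stop, -1, -1):
        out.append(int(labs[step][idx]))
        idx = int(parents[step][idx])
    return out[::-1]


#: largest exactly-tied group resolved by full lexicographic comparison;
#: larger (degenerate, all-floored) groups fall back to stable candidate order
MAX_TIE_RUN = 64


def _refine_ties(order: np.ndarray, values: np.ndarray, seq_of) -> np.ndarray:
    """Reorder equal-value runs of ``order`` lexicographically by label sequence."""
    out = order.copy()
    i = 0
    n = order.size
    while i < n:
        k = i + 1
        while k < n and values[order[k]] == values[order[i]]:
            k += 1
        if 1 < k - i <= MAX_TIE_RUN:
            out[i:k] = sorted(out[i:k], key=seq_of)
        i = k
    return out


def decode(events: EventSet, model: ModelSet, L: Optional[int] = None) -> DecodeResult:
    """Approximate maximum-likelihood labeling by L-best beam search."""
    L = model.L if L is None else int(L)
    if L < 1:
        raise ValueError("L must be >= 1")
    n_ev = events.n_events
    if n_ev < 1:
        raise ValueError("need at least one event")
    z = events.z
    K = model.K
    tau = model.tau_win

    G = gaussian_loglik_matrix(events.X, model)
    n_clipped = int((G < CLIP).sum())
    G = np.maximum(G, CLIP)
    mu, var, w_const, logprior = _model_arrays(model)

    # beam state: P rows = paths, columns = labels of in-window events
    P = np.zeros((1, 0), dtype=np.int8)
    ll = np.zeros(1)
    win_start = 0
    parents: List[np.ndarray] = []
    labs: List[np.ndarray] = []

    for n in range(n_ev):
        # slide the history window: keep events with z_m > z_n - tau
        ns = min(int(np.searchsorted(z, z[n] - tau, side="right")), n)
        slid = ns > win_start
        if slid:
            P = np.ascontiguousarray(P[:, ns - win_start:])
            win_start = ns
        keep_idx = np.arange(P.shape[0])
        # merge paths with identical window content (lossless for the future);
        # duplicates can only appear when the window just shed a column
        if slid and P.shape[0] > 1:
            if P.shape[1] == 0:
                best = int(np.argmax(ll))
                ties = np.flatnonzero(ll == ll[best])
                if ties.size > 1:
                    best = min((int(i) for i in ties),
                               key=lambda i: _reconstruct(parents, labs, i, n - 1))
                keep_idx = np.array([best])
            else:
                w_bytes = P.shape[1] * P.itemsize
                raw = P.tobytes()
                best_of: dict = {}
                for i in range(P.shape[0]):
                    key = raw[i * w_bytes:(i + 1) * w_bytes]
                    cur = best_of.get(key)
                    if cur is None or ll[i] > ll[cur]:
                        best_of[key] = i
                    elif ll[i] == ll[cur] and len(best_of) <= MAX_TIE_RUN and (
                        _reconstruct(parents, labs, i, n - 1)
                        < _reconstruct(parents, labs, cur, n - 1)
                    ):
                        best_of[key] = i
                if len(best_of) < P.shape[0]:
                    keep_idx = np.array(sorted(best_of.values()))
            if keep_idx.size < P.shape[0]:
                P = P[keep_idx]
                ll = ll[keep_idx]

        npaths, w = P.shape
        # temporal term per (path, label)
        event_term = np.tile(w_const, (npaths, 1))
        if w > 0:
            for j in range(K):
                mask = P == j
                has = mask.any(axis=1)
                if not has.any():
                    continue
                lastpos = w - 1 - np.argmax(mask[:, ::-1], axis=1)
                dt = z[n] - z[win_start + lastpos[has]]
                event_term[has, j] = np.maximum(
                    lognormal_logpdf(dt, mu[j], var[j]), CLIP)

        cand = ll[:, None] + G[n] + event_term + logprior
        flat = cand.ravel()
        m = min(L, flat.size)
        order = np.argsort(-flat, kind="stable")
        lo = flat[order[m - 1]]
        end = int(np.searchsorted(-flat[order], -lo, side="right"))
        prefix = order[:end]
        if end > m:
            # ties straddle the beam boundary: resolve lexicographically
            def seq_of(flt):
                return _reconstruct(parents, labs, int(keep_idx[int(flt) // K]),
                                    n - 1) + [int(flt) % K]
            prefix = _refine_ties(prefix, flat, seq_of)
        sel = prefix[:m]

        prow = sel // K
        jlab = (sel % K).astype(np.int8)
        parents.append(keep_idx[prow])
        labs.append((sel % K).astype(int))
        ll = flat[sel]
        P = np.column_stack([P[prow], jlab]) if w > 0 else jlab[:, None].copy()
        n_clipped += int((event_term[prow, sel % K] <= CLIP).sum())

    # final best path; resolve exact-likelihood ties lexicographically
    top = np.flatnonzero(ll == ll[0])
    best_idx = 0
    if top.size > 1:
        best_idx = min((int(i) for i in top),
                       key=lambda i: _reconstruct(parents, labs, i))
    best_labels = np.array(_reconstruct(parents, labs, best_idx), dtype=int)
    res = DecodeResult(best_labels, float(ll[best_idx]), n_clipped=n_clipped)
    _, detail = sequence_loglik(events, best_labels, model, return_detail=True)
    res.n_first_branch = detail["n_first_branch"]
    return res


def brute_force_decode(events: EventSet, model: ModelSet) -> Tuple[np.ndarray, float]:
    """Exhaustive argmax of ``sequence_loglik`` (test oracle; K^N <= 1e6).

    Ties are broken lexicographically (the first maximizer in label order).
    """
    n, K = events.n_events, model.K
    if K ** n > 10 ** 6:
        raise ValueError("instance too large for brute force")
    z = events.z
    tau = model.tau_win
    G = np.maximum(gaussian_loglik_matrix(events.X, model), CLIP)
    mu, var, w_const, logprior = _model_arrays(model)
    best_ll = -math.inf
    best = None
    for labeling in itertools.product(range(K), repeat=n):
        last: List[Optional[float]] = [None] * K
        total = 0.0
        for i in range(n):
            j = labeling[i]
            lt = last[j]
            if lt is not None and lt > z[i] - tau:
                t = max(lognormal_logpdf(z[i] - lt, mu[j], var[j]), CLIP)
            else:
                t = w_const[j]
            total += (G[i, j] + t) + logprior[j]
            last[j] = z[i]
        if total > best_ll:
            best_ll = total
            best = labeling
    return np.array(best, dtype=int), float(best_ll)


def ensemble_loglik(events: EventSet, labels, model: ModelSet, T_total: float) -> float:
    """Full-train diagnostic likelihood including the survival term.

    Per cluster: first-firing density at the actual first firing time, the
    product of ISI densities over consecutive same-cluster events, and the
    survival probability of the unfinished final interval; plus the label
    priors.  Unlike the decoding objective this uses no history window and
    keeps the censored last interval, so the two likelihoods differ exactly
    by the survival terms and the first-firing argument convention.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    z = events.z
    if T_total < z.max():
        raise ValueError("T_total must cover the last event")
    total = 0.0
    for k, c in enumerate(model.clusters):
        tk = z[labels == k]
        if tk.size == 0:
            warnings.warn(f"cluster {k} has no events; contributes 0")
            continue
        t1 = tk[0]
        if c.beta > 0 and t1 > 0:
            total += math.log(c.beta * t1) - c.beta * t1
        else:
            total += -math.inf
        if tk.size > 1:
            total += float(np.sum(lognormal_logpdf(np.diff(tk), c.mu_isi, c.var_isi)))
        total += float(lognormal_logsf(T_total - tk[-1], c.mu_isi, c.var_isi))
    logprior = np.log(np.maximum(model.priors(), 1e-300))
    total += float(logprior[labels].sum())
    return total
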