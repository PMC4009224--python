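"""Scoring of sorting results.

Fully labeled data: best-match error — one minus the accuracy under the
optimal one-to-one assignment between true and putative clusters.
Partially labeled data (one neuron known from an intracellular electrode):
false-positive + false-negative rate for the putative cluster assigned to
that neuron.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["EvalReport", "best_match_error", "partial_error"]


@dataclass
class EvalReport:
    confusion: np.ndarray
    assignment: Dict[int, int]
    error_rate: float
    fp: Optional[int] = None
    fn: Optional[int] = None


def _confusion(true_labels: np.ndarray, pred_labels: np.ndarray) -> np.ndarray:
    kt = int(true_labels.max()) + 1
    kp = int(pred_labels.max()) + 1
    conf = np.zeros((kt, kp), dtype=int)
    np.add.at(conf, (true_labels, pred_labels), 1)
    return conf


def best_match_error(true_labels, pred_labels) -> EvalReport:
    """Best-match clustering error under the optimal one-to-one assignment.

    Exhaustive over permutations for small K, optimal bipartite matching
    (Hungarian) otherwise; both give identical results where both apply.
    Ties are broken toward the lowest cluster indices.
    """
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(pred_labels, dtype=int).ravel()
    if t.size != p.size:
        raise ValueError("label vectors must have equal length")
    if t.size == 0:
        raise ValueError("empty labelings")
    conf = _confusion(t, p)
    kt, kp = conf.shape
    if max(kt, kp) <= 6:
        k = max(kt, kp)
        sq = np.zeros((k, k), dtype=int)
        sq[:kt, :kp] = conf
        best_perm, best_matched = None, -1
        for perm in permutations(range(k)):
            matched = int(sq[range(k), perm].sum())
            if matched > best_matched:
                best_matched, best_perm = matched, perm
        assignment = {i: best_perm[i] for i in range(kt) if best_perm[i] < kp}
        matched = best_matched
    else:
        rows, cols = linear_sum_assignment(-conf)
        assignment = {int(r): int(c) for r, c in zip(rows, cols)}
        matched = int(conf[rows, cols].sum())
    error = 1.0 - matched / t.size
    return EvalReport(conf, assignment, float(error))


def partial_error(pred_labels, ic_mask) -> EvalReport:
    """FP + FN error rate for the single neuron with known firing times.

    The putative cluster representing the known neuron is the one minimizing
    FP + FN over all clusters (lowest index on ties).  FN counts known
    firings assigned elsewhere, FP counts other events assigned to that
    cluster; the rate divides by the total event count.
    """
    p = np.asarray(pred_labels, dtype=int).ravel()
    mask = np.asarray(ic_mask, dtype=bool).ravel()
    if p.size != mask.size:
        raise ValueError("pred_labels and ic_mask must have equal length")
    if not mask.any():
        raise ValueError("no known (IC) events in the mask")
    n = p.size
    best_c, best_fp, best_fn = None, None, None
    for c in range(int(p.max()) + 1):
        inc = p == c
        fp = int((inc & ~mask).sum())
        fn = int((mask & ~inc).sum())
        if best_c is None or fp + fn < best_fp + best_fn:
            best_c, best_fp, best_fn = c, fp, fn
    conf = _confusion(mask.astype(int), p)
    return EvalReport(conf, {1: best_c}, (best_fp + best_fn) / n,
                      fp=best_fp, fn=best_fn)
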