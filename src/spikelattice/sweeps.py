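"""Hyperparameter studies: sorting error versus beam width L and window tau."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluate import best_match_error
from .features import fit_pca, transform
from .io import EventSet
from .models import estimate_tau
from .simulate import SimSpec, simulate_dataset
from .sorter import SpikeSorter

__all__ = ["SweepSpec", "sweep_L", "sweep_tau", "DEFAULT_L_GRID", "DEFAULT_TAU_GRID_MS"]

#: log-spaced beam widths
DEFAULT_L_GRID = (100, 316, 1000, 3162, 10000)
#: history windows in ms
DEFAULT_TAU_GRID_MS = (10.0, 25.0, 50.0, 100.0, 200.0, 300.0)


@dataclass
class SweepSpec:
    grid: Sequence[float]
    fixed: float                       # the other hyperparameter (L or tau_s)
    dataset: Union[SimSpec, EventSet]
    seeds: Sequence[int] = (0,)
    n_components: int = 2
    K: Optional[int] = None
    max_iter: int = 10

    def __post_init__(self) -> None:
        if len(self.grid) == 0 or min(self.grid) <= 0:
            raise ValueError("grid must be non-empty and positive")


def _prepare(spec: SweepSpec, seed: int):
    if isinstance(spec.dataset, SimSpec):
        sim = SimSpec(**{**spec.dataset.__dict__, "seed": seed})
        ev = simulate_dataset(sim)
        K = spec.K or sim.K
    else:
        ev = spec.dataset
        K = spec.K or (int(ev.labels.max()) + 1 if ev.labels is not None else 3)
    pca = fit_pca(ev.X, spec.n_components)
    feats = transform(pca, ev.X)
    return ev, feats, K


def _run_rows(spec: SweepSpec, vary: str) -> pd.DataFrame:
    rows = []
    for seed in spec.seeds:
        ev, feats, K = _prepare(spec, seed)
        for g in spec.grid:
            if vary == "L":
                L = int(g)
                tau = float(spec.fixed) if spec.fixed else None
            else:
                L = int(spec.fixed)
                tau = float(g) / 1000.0
            t0 = time.perf_counter()
            est = SpikeSorter(n_clusters=K, n_paths=L, tau=tau,
                              max_iter=spec.max_iter, random_state=seed)
            est.fit(feats, ev.z)
            dt = time.perf_counter() - t0
            err = (best_match_error(ev.labels, est.labels_).error_rate
                   if ev.labels is not None else np.nan)
            rows.append({
                vary: g, "seed": seed, "error": err, "loglik": est.loglik_,
                "n_iter": est.n_iter_, "tau_s": est.model_.tau_win,
                "runtime_s": dt, "is_default_tau": vary == "tau" and tau is None,
                "n_first_branch": _first_branch(ev.z, feats, est),
            })
    df = pd.DataFrame(rows)
    agg = df.groupby(vary)["error"].agg(["mean", "std"]).reset_index()
    return df.merge(agg.rename(columns={"mean": "mean_error", "std": "sd_error"}),
                    on=vary)


def _first_branch(z, feats, est: SpikeSorter) -> int:
    from .decoder import sequence_loglik

    _, detail = sequence_loglik(EventSet(z, feats), est.labels_, est.model_,
                                return_detail=True)
    return detail["n_first_branch"]


def sweep_L(spec: SweepSpec) -> pd.DataFrame:
    """Sorting error per beam width L (``spec.fixed`` = tau in seconds, or 0
    to use the coverage-rule estimate)."""
    return _run_rows(spec, "L")


def sweep_tau(spec: SweepSpec) -> pd.DataFrame:
    """Sorting error per history window tau in ms (``spec.fixed`` = L).

    Passing 0 in the grid is invalid; include the coverage-rule default by
    appending :func:`spikelattice.models.estimate_tau`'s value to the grid.
    """
    return _run_rows(spec, "tau")


def default_tau_row(spec: SweepSpec, seed: int = 0) -> float:
    """The coverage-rule tau (ms) for the sweep's dataset, for grid inclusion."""
    ev, feats, K = _prepare(spec, seed)
    est = SpikeSorter(n_clusters=K, max_iter=0, random_state=seed)
    est.fit(feats, ev.z)
    return estimate_tau(est.model_, 0.99) * 1000.0
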