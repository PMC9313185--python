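"""State temporal metrics and cross-fit state matching.

Fractional occupancy (fraction of time), mean dwell time, group occupancy
timecourses, and the early/late period split of occupancy.  Because two
independently fitted models label their states arbitrarily,
:func:`match_states` aligns states across fits by the similarity of their
connectivity (correlation) patterns before any paired comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hmm import HMMParams, fc_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "fraction_of_time",
    "mean_dwell_time",
    "run_lengths",
    "occupancy_timecourse",
    "period_occupancy",
    "state_metrics_table",
    "StateMatching",
    "match_states",
]


def fraction_of_time(path: np.ndarray, K: int) -> np.ndarray:
    """Proportion of time points spent in each state (sums to 1)."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    return np.bincount(path, minlength=K) / path.size


def run_lengths(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(states, lengths) of the maximal constant runs of the path."""
    path = np.asarray(path)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    return path[starts], ends - starts


def mean_dwell_time(path: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-state mean run length in samples, and visit counts.

    A state never visited gets dwell NaN and 0 visits.  The identity
    sum_k(n_visits_k * dwell_k) == T holds over visited states.
    """
    states, lengths = run_lengths(np.asarray(path))
    dwell = np.full(K, np.nan)
    visits = np.zeros(K, dtype=int)
    for k in range(K):
        sel = states == k
        visits[k] = sel.sum()
        if visits[k]:
            dwell[k] = lengths[sel].mean()
    return dwell, visits


def occupancy_timecourse(items, mode: str = "posterior-mean", K: int | None = None) -> np.ndarray:
    """Group-level state probability at each time point, (K, T).

    mode 'posterior-mean': ``items`` are per-subject (T, K) posterior
    matrices; the result is their element-wise mean, transposed.
    mode 'viterbi-proportion': ``items`` are per-subject decoded paths; the
    result is the fraction of subjects in each state at each time point
    (``K`` required).  Columns sum to 1 in both modes.
    """
    items = list(items)
    if not items:
        raise ValueError("no subjects")
    if mode == "posterior-mean":
        T = items[0].shape[0]
        if any(g.shape != items[0].shape for g in items):
            raise ValueError("all subjects must share T (and K)")
        return np.mean(items, axis=0).T
    if mode == "viterbi-proportion":
        if K is None:
            raise ValueError("K is required for viterbi-proportion mode")
        T = items[0].shape[0]
        if any(p.shape[0] != T for p in items):
            raise ValueError("all subjects must share T")
        counts = np.zeros((K, T))
        for p in items:
            counts[p, np.arange(T)] += 1
        return counts / len(items)
    raise ValueError("mode must be 'posterior-mean' or 'viterbi-proportion'")


def period_occupancy(
    path: np.ndarray,
    split_ms: float,
    fs: float,
    t_origin_ms: float = 0.0,
    K: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional occupancy separately for the early (t <= split_ms) and
    late (t > split_ms) portions of the path.

    Sample times are t_origin_ms + index * 1000 / fs.  Each period's
    fractions sum to 1, and the period-weighted combination reconstructs
    the overall fraction of time.
    """
    path = np.asarray(path)
    if K is None:
        K = int(path.max()) + 1
    t = t_origin_ms + np.arange(path.size) * 1000.0 / fs
    early = t <= split_ms + 1e-9
    if not early.any() or early.all():
        raise ValueError("split_ms must fall strictly inside the path's time span")
    return (
        fraction_of_time(path[early], K),
        fraction_of_time(path[~early], K),
    )


def state_metrics_table(
    paths: dict,
    K: int,
    split_ms: float,
    fs: float,
    t_origin_ms: float = 0.0,
) -> pd.DataFrame:
    """Per subject x condition x state summary of a set of decoded paths.

    ``paths`` maps (subject, condition) -> state path.  Columns: fraction,
    dwell_samples, dwell_ms, n_visits, fraction_early, fraction_late,
    present.
    """
    rows = []
    for (subj, cond), path in paths.items():
        frac = fraction_of_time(path, K)
        dwell, visits = mean_dwell_time(path, K)
        early, late = period_occupancy(path, split_ms, fs, t_origin_ms, K=K)
        for k in range(K):
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "state": k,
                    "fraction": frac[k],
                    "dwell_samples": dwell[k],
                    "dwell_ms": dwell[k] * 1000.0 / fs,
                    "n_visits": visits[k],
                    "fraction_early": early[k],
                    "fraction_late": late[k],
                    "present": bool(visits[k] > 0),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StateMatching:
    """Bijection aligning fit B's state labels onto fit A's.

    ``perm[b] = a`` means state b of fit B plays the role of state a of
    fit A; ``similarity[b]`` is the Pearson correlation of the matched
    pair's connectivity patterns.
    """

    perm: np.ndarray
    similarity: np.ndarray

    def relabel(self, path_b: np.ndarray) -> np.ndarray:
        """Rewrite a fit-B path in fit-A state labels."""
        return self.perm[np.asarray(path_b)]


def _fc_vectors(params: HMMParams) -> np.ndarray:
    iu = np.triu_indices(params.M, k=1)
    return np.stack([fc_matrix(params, k, "correlation")[iu] for k in range(params.K)])


def match_states(fit_a: HMMParams, fit_b: HMMParams) -> StateMatching:
    """Optimal assignment of fit B's states onto fit A's by connectivity
    similarity (Pearson correlation of the off-diagonal correlation
    entries), solved as a linear assignment problem."""
    if fit_a.K != fit_b.K or fit_a.M != fit_b.M:
        raise ValueError("fits must share K and M")
    if fit_a.M < 2:
        raise ValueError("connectivity-based matching needs at least 2 channels")
    va, vb = _fc_vectors(fit_a), _fc_vectors(fit_b)
    K = fit_a.K
    sim = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            sa, sb = va[a].std(), vb[b].std()
            if sa == 0 or sb == 0:
                logger.warning(
                    "degenerate (constant) connectivity vector for pair (%d, %d); "
                    "similarity set to 0", a, b,
                )
                continue
            sim[a, b] = np.corrcoef(va[a], vb[b])[0, 1]
    rows, cols = linear_sum_assignment(-sim)  # rows are fit-A states, in order
    perm = np.empty(K, dtype=int)
    similarity = np.empty(K)
    for a, b in zip(rows, cols):
        perm[b] = a
        similarity[b] = sim[a, b]
    return StateMatching(perm=perm, similarity=similarity)
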