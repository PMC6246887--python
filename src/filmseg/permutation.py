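"""Duration-shuffling permutation nulls.

The null hypothesis preserves the multiset of inter-boundary intervals (event
durations) while randomising boundary positions: the interval vector from run
start to the first boundary, then boundary to boundary, is permuted and
cumulatively summed; the tail after the last boundary is held fixed so the
occupied span and boundary count are exact invariants of every draw.

p-values use the add-one estimator (r + 1) / (n_perm + 1), which can never
be zero (a statistic exceeding every permutation gives p = 1/(n_perm + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import HrfSpec, _convolved_column, build_design
from .annotations import match_boundaries

__all__ = ["PermutationResult", "shuffle_durations", "amplitude_null",
           "match_null"]


@dataclass
class PermutationResult:
    observed: float
    null_samples: np.ndarray
    p: float
    n_perm: int
    tail: str = "two-sided"


def shuffle_durations(boundary_times, rng, include_start: bool = True) -> np.ndarray:
    """One duration-shuffled draw of a boundary set.

    With ``include_start`` the run-start-to-first-boundary interval joins the
    shuffle (run length is preserved exactly either way since the tail after
    the last boundary is never moved).
    """
    times = np.sort(np.asarray(boundary_times, dtype=float))
    if times.size < 2:
        raise ValueError("need at least 2 boundaries to shuffle durations")
    intervals = np.diff(np.concatenate([[0.0], times]))
    if include_start:
        shuffled = rng.permutation(intervals)
    else:
        shuffled = np.concatenate([[intervals[0]],
                                   rng.permutation(intervals[1:])])
    return np.cumsum(shuffled)


def _p_value(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "two-sided":
        r = int((np.abs(null) >= np.abs(observed)).sum())
    elif tail == "greater":
        r = int((null >= observed).sum())
    else:
        raise ValueError("tail must be 'two-sided' or 'greater'")
    return (r + 1) / (len(null) + 1)


def amplitude_null(tc, boundary_times, tr: float,
                   spec: HrfSpec | None = None, n_perm: int = 1000,
                   seed=None, include_start: bool = True,
                   highpass_cutoff: float = 256.0) -> PermutationResult:
    """Two-tailed duration-shuffle test of the pooled boundary amplitude.

    The observed statistic is the single-regressor GLM amplitude at the true
    boundaries; the null refits the same GLM at each duration-shuffled
    boundary set. Confound projection is precomputed once, so each draw only
    costs one convolved regressor.
    """
    spec = spec or HrfSpec()
    rng = np.random.default_rng(seed)
    y = np.asarray(getattr(tc, "values", tc), dtype=float)
    n_tr = len(y)
    design = build_design(boundary_times, n_tr=n_tr, tr=tr, spec=spec,
                          scheme="single", highpass_cutoff=highpass_cutoff)
    confounds = design.frame[design.confound_cols].to_numpy()
    # residual-maker for the confound span (Frisch-Waugh-Lovell)
    q, _ = np.linalg.qr(confounds)
    y_res = y - q @ (q.T @ y)

    def _beta(times) -> float:
        x = _convolved_column(times, n_tr, tr, spec)
        x_res = x - q @ (q.T @ x)
        denom = x_res @ x_res
        if denom == 0:
            return 0.0
        return float((x_res @ y_res) / denom)

    observed = _beta(boundary_times)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _beta(shuffle_durations(boundary_times, rng,
                                          include_start=include_start))
    p = _p_value(observed, null, "two-sided")
    return PermutationResult(observed=observed, null_samples=null, p=p,
                             n_perm=n_perm, tail="two-sided")


def match_null(reference_events, test_events, window: float,
               n_perm: int = 1000, seed=None,
               include_start: bool = True) -> PermutationResult:
    """One-tailed duration-shuffle test of a boundary match count.

    Counts one-to-one matches of ``test_events`` to ``reference_events``
    within ``window`` seconds, against the count obtained when the reference
    events are duration-shuffled.
    """
    rng = np.random.default_rng(seed)
    reference_events = np.sort(np.asarray(reference_events, dtype=float))
    test_events = np.asarray(test_events, dtype=float)
    observed = match_boundaries(reference_events, test_events, window)
    if test_events.size == 0:
        return PermutationResult(observed=0.0, null_samples=np.zeros(n_perm),
                                 p=1.0, n_perm=n_perm, tail="greater")
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_durations(reference_events, rng,
                                     include_start=include_start)
        null[i] = match_boundaries(shuffled, test_events, window)
    p = _p_value(observed, null, "greater")
    return PermutationResult(observed=float(observed), null_samples=null,
                             p=p, n_perm=n_perm, tail="greater")
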