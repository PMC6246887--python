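"""Greedy data-driven detection of ROI "events".

Rather than asking how the ROI responds at annotated boundaries, this module
asks which moments the ROI itself "chose": starting from a constant-only
GLM, it greedily adds one HRF-convolved stick regressor per iteration — the
candidate TR whose addition most reduces the residual sum of squares — under
two constraints: the new event's beta must be positive, and adding it must
not flip the sign of any previously selected event's beta (all betas are
re-fit jointly at every step). Selection stops at ``k`` events (the number
of annotated boundaries in the run) or when no admissible candidate remains.
The specificity of the detected events is then tested by matching them to
the annotated boundaries within 1 TR against a duration-shuffling null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import HrfSpec, _convolved_column
from .annotations import match_boundaries
from .permutation import PermutationResult, match_null

__all__ = ["HippocampalEventSet", "greedy_event_search", "specificity_test"]


@dataclass
class HippocampalEventSet:
    """Result of the greedy search: TRs in selection order, joint betas,
    and the RSS after each addition."""

    event_trs: np.ndarray
    betas: np.ndarray
    rss_trace: np.ndarray
    k_target: int
    stopped_early: bool
    tr: float

    @property
    def event_times_s(self) -> np.ndarray:
        return self.event_trs * self.tr


def greedy_event_search(tc, k: int, tr: float | None = None,
                        spec: HrfSpec | None = None) -> HippocampalEventSet:
    """Forward selection of stick-regressor events on a group time course.

    ``tc`` should already be high-pass filtered and z-scored (and averaged
    across participants). Candidate regressors are sticks at every TR-grid
    time, built exactly as in the hypothesis-driven GLM. Ties in RSS
    reduction go to the earlier TR.
    """
    y = np.asarray(getattr(tc, "values", tc), dtype=float)
    tr = tr if tr is not None else getattr(tc, "tr", None)
    if tr is None:
        raise ValueError("tr must be given when tc is a plain array")
    spec = spec or HrfSpec()
    n_tr = len(y)
    if not 1 <= k <= n_tr:
        raise ValueError("k must lie in [1, n_TR]")

    # candidate bank: one convolved stick per TR
    candidates = np.column_stack([
        _convolved_column([t * tr], n_tr, tr, spec) for t in range(n_tr)])

    const = np.ones((n_tr, 1))
    selected: list[int] = []
    design = const
    resid = y - const @ np.linalg.lstsq(const, y, rcond=None)[0]
    rss_trace = []
    betas = np.array([])
    stopped_early = False

    while len(selected) < k:
        best = None  # (rss, tr_index, betas_full)
        for cand in range(n_tr):
            if cand in selected:
                continue
            x = np.column_stack([design, candidates[:, cand]])
            beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            new_beta = beta[-1]
            old_betas = beta[1:-1]  # previously selected events
            if new_beta <= 0:
                continue
            if len(selected) and np.any(old_betas <= 0):
                continue  # sign flip of a previously positive event beta
            r = y - x @ beta
            rss = float(r @ r)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, cand, beta)
        if best is None:
            stopped_early = True
            break
        rss, cand, beta = best
        selected.append(cand)
        design = np.column_stack([design, candidates[:, cand]])
        betas = beta[1:]
        rss_trace.append(rss)

    return HippocampalEventSet(event_trs=np.asarray(selected, dtype=int),
                               betas=np.asarray(betas, dtype=float),
                               rss_trace=np.asarray(rss_trace, dtype=float),
                               k_target=k, stopped_early=stopped_early, tr=tr)


def specificity_test(events: HippocampalEventSet, boundary_times,
                     tr: float | None = None, window_tr: float = 1.0,
                     n_perm: int = 1000, seed=None) -> dict:
    """Match data-driven events to annotated boundaries within 1 TR.

    Returns the one-to-one match count, the matched fraction of detected
    events, and a one-tailed duration-shuffling permutation test of the
    count (boundaries are the shuffled set).
    """
    tr = tr if tr is not None else events.tr
    event_times = events.event_trs * tr
    boundary_times = np.asarray(boundary_times, dtype=float)
    window = window_tr * tr
    if events.event_trs.size == 0:
        return {"n_matched": 0, "fraction": 0.0,
                "permutation": PermutationResult(observed=0.0,
                                                 null_samples=np.zeros(n_perm),
                                                 p=1.0, n_perm=n_perm,
                                                 tail="greater")}
    result = match_null(boundary_times, event_times, window=window,
                        n_perm=n_perm, seed=seed)
    n_matched = int(result.observed)
    return {"n_matched": n_matched,
            "fraction": n_matched / len(event_times),
            "permutation": result}
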