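"""Ordered-event HMM segmentation of multi-voxel cortical patterns.

Event structure in high-level cortex shows up as piecewise-stable
multi-voxel activity patterns. The model is a strictly left-to-right hidden
Markov model over K event states: the chain starts in state 1, may only stay
or advance by one (k -> k or k -> k+1), and must end in state K. Emissions
are Gaussian with one mean pattern per event and a shared isotropic
variance; stay/advance probability, means and variance are all estimated by
EM. Pattern shifts — the TRs where the modal state increments — are then
classified by whether they fall shortly after an annotated event boundary,
and the ROI response around matching/non-matching shifts is averaged and
tested with a duration-shuffling permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import match_boundaries
from .permutation import PermutationResult, shuffle_durations, _p_value

__all__ = ["HmmFit", "fit_event_hmm", "classify_shifts",
           "peri_shift_response"]


@dataclass
class HmmFit:
    n_events: int
    state_posterior: np.ndarray  # TR x K
    event_means: np.ndarray      # K x voxels
    shift_times: np.ndarray      # TR indices where the modal state increments
    loglik_trace: np.ndarray
    converged: bool
    stay_prob: float
    emission_var: float


def _forward_backward(ll: np.ndarray, log_stay: float, log_adv: float):
    t_len, k = ll.shape
    neg = -np.inf
    alpha = np.full((t_len, k), neg)
    alpha[0, 0] = ll[0, 0]
    for t in range(1, t_len):
        stay = alpha[t - 1] + log_stay
        adv = np.full(k, neg)
        adv[1:] = alpha[t - 1, :-1] + log_adv
        alpha[t] = np.logaddexp(stay, adv) + ll[t]
    beta = np.full((t_len, k), neg)
    beta[t_len - 1, k - 1] = 0.0  # must end in the last state
    for t in range(t_len - 2, -1, -1):
        stay = log_stay + ll[t + 1] + beta[t + 1]
        adv = np.full(k, neg)
        adv[:-1] = log_adv + ll[t + 1, 1:] + beta[t + 1, 1:]
        beta[t] = np.logaddexp(stay, adv)
    loglik = alpha[t_len - 1, k - 1]
    log_gamma = alpha + beta - loglik
    gamma = np.exp(log_gamma)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, alpha, beta, loglik


def fit_event_hmm(patterns: np.ndarray, k_events: int, max_iter: int = 100,
                  tol: float = 1e-4) -> HmmFit:
    """EM fit of the left-to-right event HMM to a voxel x TR matrix.

    ``k_events`` is fixed from the number of annotated boundaries + 1 rather
    than estimated from the data. Patterns should be z-scored per voxel.
    Warns (does not raise) when EM hits ``max_iter`` without the relative
    log-likelihood change dropping below ``tol``.
    """
    x = np.asarray(patterns, dtype=float).T  # TR x voxels
    t_len, n_vox = x.shape
    k = int(k_events)
    if k < 1 or k > t_len:
        raise ValueError("k_events must lie in [1, n_TR]")

    if k == 1:
        mean = x.mean(axis=0, keepdims=True)
        var = float(np.mean((x - mean) ** 2)) or 1.0
        ll = float(-0.5 * t_len * n_vox * np.log(2 * np.pi * var)
                   - np.sum((x - mean) ** 2) / (2 * var))
        return HmmFit(n_events=1, state_posterior=np.ones((t_len, 1)),
                      event_means=mean, shift_times=np.array([], dtype=int),
                      loglik_trace=np.array([ll]), converged=True,
                      stay_prob=1.0, emission_var=var)

    # init: uniform segmentation
    edges = np.linspace(0, t_len, k + 1).astype(int)
    means = np.stack([x[a:b].mean(axis=0) if b > a else x[min(a, t_len - 1)]
                      for a, b in zip(edges[:-1], edges[1:])])
    var = float(np.mean((x - np.repeat(means, np.diff(edges), axis=0)) ** 2))
    var = max(var, 1e-8)
    p_adv = min(max((k - 1) / max(t_len - 1, 1), 1e-6), 1 - 1e-6)

    trace = []
    converged = False
    gamma = None
    for it in range(max_iter):
        log_stay, log_adv = np.log1p(-p_adv), np.log(p_adv)
        sq = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        ll = -0.5 * n_vox * np.log(2 * np.pi * var) - sq / (2 * var)
        gamma, alpha, beta, loglik = _forward_backward(ll, log_stay, log_adv)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (
                abs(trace[-2]) + 1e-12):
            converged = True
            break
        # M-step
        w = gamma.sum(axis=0)
        means = (gamma.T @ x) / np.maximum(w[:, None], 1e-12)
        sq = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        var = max(float(np.sum(gamma * sq) / (t_len * n_vox)), 1e-10)
        # expected stay/advance counts
        ll_new = -0.5 * n_vox * np.log(2 * np.pi * var) - sq / (2 * var)
        e_stay = e_adv = 0.0
        for t in range(t_len - 1):
            stay = np.exp(alpha[t] + log_stay + ll[t + 1] + beta[t + 1]
                          - loglik)
            adv = np.exp(alpha[t, :-1] + log_adv + ll[t + 1, 1:]
                         + beta[t + 1, 1:] - loglik)
            e_stay += stay.sum()
            e_adv += adv.sum()
        if e_stay + e_adv > 0:
            p_adv = min(max(e_adv / (e_stay + e_adv), 1e-6), 1 - 1e-6)

    if not converged:
        import warnings
        warnings.warn("event HMM did not converge; returning best fit",
                      RuntimeWarning, stacklevel=2)

    modal = np.maximum.accumulate(gamma.argmax(axis=1))
    shifts = np.nonzero(np.diff(modal) > 0)[0] + 1
    return HmmFit(n_events=k, state_posterior=gamma, event_means=means,
                  shift_times=shifts.astype(int),
                  loglik_trace=np.asarray(trace), converged=converged,
                  stay_prob=1 - p_adv, emission_var=var)


def classify_shifts(shift_trs, boundary_times, tr: float,
                    window_tr: int = 2, symmetric: bool = False) -> pd.DataFrame:
    """Label pattern shifts as matching an event boundary or not.

    A shift matches when a boundary occurred up to ``window_tr`` TRs before
    it (the shift follows the boundary; ``symmetric=True`` allows either
    side). Shifts live on the TR grid, so the comparison is in TR units: a
    boundary belongs to the TR during which it occurred, and a shift in that
    same TR (gap 0) already counts as following it. Assignment is greedy
    one-to-one by ascending gap.
    """
    shift_trs = np.asarray(shift_trs, dtype=int)
    boundary_times = np.asarray(boundary_times, dtype=float)
    boundary_trs = np.floor(boundary_times / tr + 1e-9)
    pairs = []
    for i, st in enumerate(shift_trs):
        for j, bt in enumerate(boundary_trs):
            gap = st - bt
            ok = (0 <= gap <= window_tr) if not symmetric else (
                abs(gap) <= window_tr)
            if ok:
                pairs.append((abs(gap), i, j))
    pairs.sort()
    used_s, used_b = set(), set()
    matched = np.zeros(len(shift_trs), dtype=bool)
    matched_time = np.full(len(shift_trs), np.nan)
    for _, i, j in pairs:
        if i not in used_s and j not in used_b:
            used_s.add(i)
            used_b.add(j)
            matched[i] = True
            matched_time[i] = boundary_times[j]
    return pd.DataFrame({"shift_tr": shift_trs, "matched": matched,
                         "boundary_time_s": matched_time})


def peri_shift_response(tc, shifts: pd.DataFrame,
                        epoch_tr: tuple[int, int] = (-4, 8),
                        amplitude_window: tuple[int, int] = (0, 2),
                        n_perm: int = 1000, seed=None) -> dict:
    """Average ROI response around matched vs non-matched pattern shifts.

    Epochs of ``epoch_tr`` TRs around each shift are averaged within class;
    the response amplitude is the mean over TRs ``amplitude_window``
    (inclusive) after the shift. Significance per class comes from
    duration-shuffling the shift times (preserving inter-shift epochs) and
    recomputing the amplitude, two-tailed.
    """
    y = np.asarray(getattr(tc, "values", tc), dtype=float)
    tr = getattr(tc, "tr", 1.0)
    rng = np.random.default_rng(seed)
    lags = np.arange(epoch_tr[0], epoch_tr[1] + 1)
    a_lo, a_hi = amplitude_window

    def _amplitude(trs) -> float:
        vals = []
        for s in trs:
            idx = np.arange(s + a_lo, s + a_hi + 1)
            idx = idx[(idx >= 0) & (idx < len(y))]
            if idx.size:
                vals.append(y[idx].mean())
        return float(np.mean(vals)) if vals else 0.0

    out = {"epoch_lags_tr": lags}
    for label, grp in (("match", shifts[shifts["matched"]]),
                       ("non-match", shifts[~shifts["matched"]])):
        trs = grp["shift_tr"].to_numpy(dtype=int)
        curves = []
        for s in trs:
            idx = s + lags
            valid = (idx >= 0) & (idx < len(y))
            curve = np.full(len(lags), np.nan)
            curve[valid] = y[idx[valid]]
            curves.append(curve)
        if curves:
            stack = np.stack(curves)
            mean_curve = np.nanmean(stack, axis=0)
            sem = (np.nanstd(stack, axis=0, ddof=1) / np.sqrt(stack.shape[0])
                   if stack.shape[0] > 1 else np.zeros(len(lags)))
        else:
            mean_curve = np.full(len(lags), np.nan)
            sem = np.full(len(lags), np.nan)
        observed = _amplitude(trs)
        perm_result = None
        if len(trs) >= 2 and n_perm > 0:
            null = np.empty(n_perm)
            shift_secs = trs * tr
            for i in range(n_perm):
                shuffled = shuffle_durations(shift_secs, rng)
                null[i] = _amplitude(np.round(shuffled / tr).astype(int))
            perm_result = PermutationResult(
                observed=observed, null_samples=null,
                p=_p_value(observed, null, "two-sided"), n_perm=n_perm)
        out[label] = {"curve": mean_curve, "sem": sem, "n_shifts": len(trs),
                      "amplitude": observed, "permutation": perm_result}
    return out
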