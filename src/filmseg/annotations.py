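"""Consensus event boundaries from observer keypress logs.

A panel of observers watches the film and presses a key whenever they feel
one meaningful unit of experience ends and another begins. This module turns
those per-observer press logs into a consensus boundary set: reaction-time
correction, two-pass merging on the TR grid, removal of run-end boundaries,
observer-count thresholding, salience binning, and a permutation comparison
of two observer subgroups.

Press logs are tidy DataFrames with columns ``observer_id``, ``run_id``,
``press_time_s`` (TSV on disk); consensus boundaries are DataFrames with
``run_id``, ``time_s``, ``n_observers`` and, after binning, ``salience_bin``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "correct_rt",
    "merge_boundaries",
    "drop_run_end",
    "select_threshold",
    "apply_threshold",
    "bin_salience",
    "consensus_boundaries",
    "match_boundaries",
    "compare_observer_groups",
]

ANNOTATION_COLUMNS = ["observer_id", "run_id", "press_time_s"]


def _check_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    return annotations


def correct_rt(annotations: pd.DataFrame, rt: float = 0.9) -> pd.DataFrame:
    """Subtract the mean reaction time from every logged press.

    Times are clamped at 0. The output carries ``attrs['rt_corrected']`` and
    re-correcting an already corrected table raises (the shift must be
    applied exactly once).
    """
    _check_annotations(annotations)
    if rt < 0:
        raise ValueError("rt must be nonnegative")
    if annotations.attrs.get("rt_corrected", False):
        raise ValueError("annotations are already RT-corrected")
    out = annotations.copy()
    out["press_time_s"] = np.maximum(out["press_time_s"] - rt, 0.0)
    out.attrs["rt_corrected"] = True
    return out


def _cluster_presses(times: np.ndarray, observers: np.ndarray, tr: float):
    """Pass 1: single-linkage chaining — a press joins the open cluster while
    within ``tr`` of the previous member. Yields (member_times, member_obs)."""
    order = np.argsort(times, kind="stable")
    times, observers = times[order], observers[order]
    clusters = []
    start = 0
    for i in range(1, len(times) + 1):
        if i == len(times) or times[i] - times[i - 1] > tr:
            clusters.append((times[start:i], observers[start:i]))
            start = i
    return clusters


def _cluster_to_boundary(member_times, member_obs):
    # one vote per observer: average an observer's multiple presses first
    obs_means = pd.Series(member_times).groupby(pd.Series(member_obs)).mean()
    return {"time_s": float(obs_means.mean()),
            "n_observers": int(obs_means.size),
            "member_times": [list(member_times)],
            "member_obs": [list(member_obs)]}


def merge_boundaries(annotations: pd.DataFrame, tr: float,
                     pass1: str = "chain") -> pd.DataFrame:
    """Two-pass merge of observer presses into consensus boundaries.

    Pass 1 clusters presses within 1 TR of one another (``pass1='chain'``:
    single-linkage chaining in time order; ``'anchor'``: fixed window from
    the first press of each cluster); the boundary time is the mean press
    time (one vote per observer) and ``n_observers`` the number of distinct
    observers. Pass 2 runs once: adjacent pass-1 boundaries that each carry
    at least 2 observers and lie < 2 TR apart are replaced by one boundary
    at the mean of all member presses with summed observer counts. A single
    pass avoids chaining widely separated boundaries together.
    """
    _check_annotations(annotations)
    if tr <= 0:
        raise ValueError("tr must be positive")
    if pass1 not in ("chain", "anchor"):
        raise ValueError("pass1 must be 'chain' or 'anchor'")

    out_rows = []
    for run_id, grp in annotations.groupby("run_id", sort=False):
        times = grp["press_time_s"].to_numpy(dtype=float)
        observers = grp["observer_id"].to_numpy()
        if pass1 == "chain":
            clusters = _cluster_presses(times, observers, tr)
        else:
            order = np.argsort(times, kind="stable")
            ts, obs = times[order], observers[order]
            clusters, start = [], 0
            for i in range(1, len(ts) + 1):
                if i == len(ts) or ts[i] - ts[start] > tr:
                    clusters.append((ts[start:i], obs[start:i]))
                    start = i
        b = [_cluster_to_boundary(t, o) for t, o in clusters]

        # pass 2: single sweep over adjacent qualifying pairs
        merged, i = [], 0
        while i < len(b):
            if (i + 1 < len(b)
                    and b[i]["n_observers"] >= 2 and b[i + 1]["n_observers"] >= 2
                    and b[i + 1]["time_s"] - b[i]["time_s"] < 2 * tr):
                all_t = np.concatenate([b[i]["member_times"][0],
                                        b[i + 1]["member_times"][0]])
                all_o = np.concatenate([b[i]["member_obs"][0],
                                        b[i + 1]["member_obs"][0]])
                merged.append({"time_s": float(all_t.mean()),
                               "n_observers": b[i]["n_observers"] + b[i + 1]["n_observers"],
                               "member_times": [list(all_t)],
                               "member_obs": [list(all_o)]})
                i += 2
            else:
                merged.append(b[i])
                i += 1
        for row in merged:
            row["run_id"] = run_id
            out_rows.append(row)

    if not out_rows:
        return pd.DataFrame(columns=["run_id", "time_s", "n_observers"])
    out = pd.DataFrame(out_rows)[["run_id", "time_s", "n_observers",
                                  "member_times", "member_obs"]]
    return out.sort_values(["run_id", "time_s"], kind="stable").reset_index(drop=True)


def drop_run_end(boundaries: pd.DataFrame, run_duration: float,
                 margin: float = 10.0) -> pd.DataFrame:
    """Remove boundaries within ``margin`` seconds of the end of the run
    (their responses cannot be estimated from the truncated time course)."""
    if boundaries.empty:
        return boundaries.copy()
    keep = boundaries["time_s"] <= run_duration - margin
    return boundaries[keep].reset_index(drop=True)


def select_threshold(boundaries: pd.DataFrame,
                     annotations: pd.DataFrame) -> int:
    """Pick the observer-count threshold matching the observers' own totals.

    The expected "true" number of boundaries is the mean number of presses
    per observer; for each candidate threshold k the number of consensus
    boundaries with ``n_observers >= k`` is counted, and the k whose count is
    closest to the expectation wins (ties resolved toward the lower,
    more inclusive k).
    """
    _check_annotations(annotations)
    target = annotations.groupby("observer_id")["press_time_s"].size().mean()
    counts = boundaries["n_observers"].to_numpy()
    best_k, best_err = 1, np.inf
    for k in range(1, int(counts.max()) + 1):
        err = abs(int((counts >= k).sum()) - target)
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def apply_threshold(boundaries: pd.DataFrame, threshold: int) -> pd.DataFrame:
    return boundaries[boundaries["n_observers"] >= threshold].reset_index(drop=True)


def bin_salience(boundaries: pd.DataFrame) -> pd.DataFrame:
    """Partition boundaries into low/med/high salience by observer count.

    The sorted distinct ``n_observers`` values are split into three
    contiguous ranges whose event counts are as equal as possible
    (minimising the sum of squared deviations from N/3; ties broken by the
    smallest |low - high| count difference). With fewer than 3 distinct
    counts the binning is degenerate and flagged in ``attrs``.
    """
    out = boundaries.copy()
    counts = out["n_observers"].to_numpy()
    values = np.unique(counts)
    n = len(counts)
    if len(values) < 3:
        out["salience_bin"] = "low"
        out.attrs["degenerate_salience_bins"] = True
        return out

    best = None
    target = n / 3.0
    for i, j in itertools.combinations(range(1, len(values)), 2):
        lo, me, hi = values[:i], values[i:j], values[j:]
        c = [int(np.isin(counts, v).sum()) for v in (lo, me, hi)]
        sse = sum((ck - target) ** 2 for ck in c)
        tie = abs(c[0] - c[2])
        key = (sse, tie)
        if best is None or key < best[0]:
            best = (key, (lo[-1], me[-1]))
    cut_low, cut_med = best[1]
    labels = np.where(counts <= cut_low, "low",
                      np.where(counts <= cut_med, "med", "high"))
    out["salience_bin"] = labels
    out.attrs["degenerate_salience_bins"] = False
    return out


def consensus_boundaries(annotations: pd.DataFrame, tr: float,
                         run_duration: float | None = None,
                         rt: float | None = 0.9, margin: float = 10.0,
                         threshold: int | None = None,
                         pass1: str = "chain") -> pd.DataFrame:
    """Full chain: RT-correct, merge, drop run-end, threshold, bin salience."""
    ann = annotations
    if rt is not None and not ann.attrs.get("rt_corrected", False):
        ann = correct_rt(ann, rt)
    b = merge_boundaries(ann, tr, pass1=pass1)
    if run_duration is not None:
        b = drop_run_end(b, run_duration, margin)
    if b.empty:
        return b
    if threshold is None:
        threshold = select_threshold(b, ann)
    b = apply_threshold(b, threshold)
    b = bin_salience(b)
    b.attrs["threshold"] = threshold
    return b.drop(columns=["member_times", "member_obs"], errors="ignore")


def match_boundaries(times_a, times_b, window: float) -> int:
    """Greedy one-to-one matching of two boundary sets within ``window`` s.

    Candidate pairs are considered in ascending |time difference| so no
    boundary is matched twice. Returns the number of matched pairs.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        return 0
    diff = np.abs(times_a[:, None] - times_b[None, :])
    pairs = [(diff[i, j], i, j) for i in range(len(times_a))
             for j in range(len(times_b)) if diff[i, j] <= window]
    pairs.sort()
    used_a, used_b, n = set(), set(), 0
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            n += 1
    return n


def compare_observer_groups(annotations_a: pd.DataFrame,
                            annotations_b: pd.DataFrame, tr: float,
                            run_duration: float | None = None,
                            n_perm: int = 1000, rng=None,
                            rt: float | None = 0.9) -> dict:
    """Compare two observer subgroups' consensus boundaries against chance.

    The full consensus procedure is run per subgroup, matching boundaries up
    to 1 TR apart; the observed match count is referred to the distribution
    obtained by randomly re-dividing the pooled observers into two groups of
    the original sizes. p is the fraction of random divisions with a match
    count *lower* than observed (high p = the two groups agree at least as
    well as arbitrary splits).
    """
    rng = np.random.default_rng(rng)

    def _consensus_times(ann):
        b = consensus_boundaries(ann, tr, run_duration=run_duration, rt=rt)
        return b["time_s"].to_numpy() if not b.empty else np.array([])

    def _match(ann_a, ann_b):
        ta, tb = _consensus_times(ann_a), _consensus_times(ann_b)
        return match_boundaries(ta, tb, window=tr)

    observed = _match(annotations_a, annotations_b)
    pooled = pd.concat([annotations_a, annotations_b], ignore_index=True)
    pooled.attrs["rt_corrected"] = (annotations_a.attrs.get("rt_corrected", False)
                                    and annotations_b.attrs.get("rt_corrected", False))
    obs_a = list(pd.unique(annotations_a["observer_id"]))
    obs_b = list(pd.unique(annotations_b["observer_id"]))
    all_obs = np.array(obs_a + obs_b, dtype=object)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(all_obs)
        in_a = set(perm[: len(obs_a)])
        mask = pooled["observer_id"].isin(in_a)
        ga, gb = pooled[mask], pooled[~mask]
        ga.attrs["rt_corrected"] = pooled.attrs["rt_corrected"]
        gb.attrs["rt_corrected"] = pooled.attrs["rt_corrected"]
        null[p] = _match(ga, gb)
    p_lower = float((null < observed).mean())
    return {"observed_match": observed, "null_matches": null,
            "p_lower": p_lower, "n_perm": n_perm}
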