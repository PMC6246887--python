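"""Boundary-evoked GLM machinery for ROI time courses.

Builds stick-function design matrices at microtime resolution, convolves them
with a canonical double-gamma hemodynamic response function (HRF), appends a
cosine high-pass confound set, and estimates boundary response amplitudes by
ordinary least squares: one pooled amplitude per run (``scheme='single'``),
one amplitude per boundary (``scheme='per-boundary'``, the single-trial model
whose betas feed the mixed models), and an unconstrained FIR deconvolution on
a 1-s grid for plotting peri-boundary response curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HrfSpec",
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "cosine_basis",
    "build_design",
    "estimate_amplitude",
    "single_trial_betas",
    "fir_timecourse",
    "exclude_close_boundaries",
]


@dataclass(frozen=True)
class HrfSpec:
    """Parameters of the canonical double-gamma HRF.

    ``undershoot_ratio`` is the peak-to-undershoot amplitude ratio (SPM's
    convention, default 6: the undershoot is one sixth of the peak).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    microtime_bins_per_tr: int = 16

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfSpec.{name} must be positive")
        if self.kernel_length < 24.0:
            raise ValueError("HRF kernel must span at least 24 s")
        if self.microtime_bins_per_tr < 1:
            raise ValueError("microtime_bins_per_tr must be >= 1")


def canonical_hrf(spec: HrfSpec, tr: float) -> np.ndarray:
    """Sample the double-gamma HRF at microtime resolution, unit-peak scaled.

    The kernel is ``g(t; peak) - g(t; undershoot)/ratio`` with gamma-density
    lobes, sampled every ``tr / microtime_bins_per_tr`` seconds from 0 to
    ``kernel_length``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / spec.microtime_bins_per_tr
    t = np.arange(0.0, spec.kernel_length, dt)
    peak = gamma_dist.pdf(t, a=spec.peak_delay / spec.peak_dispersion,
                          scale=spec.peak_dispersion)
    under = gamma_dist.pdf(t, a=spec.undershoot_delay / spec.undershoot_dispersion,
                           scale=spec.undershoot_dispersion)
    h = peak - under / spec.undershoot_ratio
    return h / h.max()


def cosine_basis(n_tr: int, tr: float, cutoff: float = 256.0) -> np.ndarray:
    """Discrete-cosine high-pass confound set (periods longer than ``cutoff``).

    Returns an ``n_tr x (1 + K)`` array whose first column is the constant
    term; K = floor(2 * run_length / cutoff) drifting cosines follow.
    """
    n_basis = int(np.floor(2.0 * n_tr * tr / cutoff))
    t = np.arange(n_tr)
    cols = [np.ones(n_tr)]
    for k in range(1, n_basis + 1):
        cols.append(np.sqrt(2.0 / n_tr) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_tr)))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """A named GLM design: event regressors plus high-pass confounds."""

    frame: pd.DataFrame
    event_cols: list[str]
    confound_cols: list[str]
    rank_deficient: bool = False
    truncated_events: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_tr(self) -> int:
        return len(self.frame)


def _microtime_sticks(times: np.ndarray, weights: np.ndarray, n_micro: int,
                      dt: float) -> np.ndarray:
    sticks = np.zeros(n_micro)
    idx = np.round(np.asarray(times, dtype=float) / dt).astype(int)
    np.add.at(sticks, np.clip(idx, 0, n_micro - 1), weights)
    return sticks


def _convolved_column(times, n_tr: int, tr: float, spec: HrfSpec,
                      weights=None) -> np.ndarray:
    """HRF-convolved stick regressor sampled at the middle microtime bin."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if weights is None:
        weights = np.ones_like(times)
    m = spec.microtime_bins_per_tr
    dt = tr / m
    n_micro = n_tr * m
    sticks = _microtime_sticks(times, np.asarray(weights, dtype=float), n_micro, dt)
    kernel = canonical_hrf(spec, tr)
    full = np.convolve(sticks, kernel)[:n_micro]
    return full[m // 2::m][:n_tr]


def build_design(boundary_times, n_tr: int, tr: float,
                 spec: HrfSpec | None = None, scheme: str = "single",
                 highpass_cutoff: float = 256.0) -> DesignMatrix:
    """Construct the boundary design matrix for one run.

    scheme='single' places all boundaries in one pooled stick regressor;
    'per-boundary' gives each boundary its own column (single-trial model).
    Cosine high-pass confounds (constant + drifts) are always appended.
    """
    spec = spec or HrfSpec()
    if tr <= 0:
        raise ValueError("tr must be positive")
    times = np.sort(np.atleast_1d(np.asarray(boundary_times, dtype=float)))
    run_length = n_tr * tr
    truncated = bool(times.size and times[-1] + spec.kernel_length > run_length)
    if times.size and (times[0] < 0 or times[-1] >= run_length):
        raise ValueError("boundary times must lie within the run")

    cols: dict[str, np.ndarray] = {}
    event_cols: list[str] = []
    if times.size:
        if scheme == "single":
            cols["events"] = _convolved_column(times, n_tr, tr, spec)
            event_cols = ["events"]
        elif scheme == "per-boundary":
            dt = tr / spec.microtime_bins_per_tr
            bins = np.round(times / dt).astype(int)
            if len(np.unique(bins)) < len(bins):
                raise ValueError(
                    "two boundaries fall in the same microtime bin; the "
                    "per-boundary design would be perfectly collinear")
            for i, t in enumerate(times):
                name = f"boundary_{i:03d}"
                cols[name] = _convolved_column([t], n_tr, tr, spec)
                event_cols.append(name)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

    confounds = cosine_basis(n_tr, tr, highpass_cutoff)
    confound_cols = ["constant"] + [f"cosine_{k:02d}" for k in range(1, confounds.shape[1])]
    for name, col in zip(confound_cols, confounds.T):
        cols[name] = col

    frame = pd.DataFrame(cols, columns=event_cols + confound_cols)
    x = frame.to_numpy()
    deficient = np.linalg.matrix_rank(x) < x.shape[1]
    return DesignMatrix(frame=frame, event_cols=event_cols,
                        confound_cols=confound_cols, rank_deficient=deficient,
                        truncated_events=truncated)


@dataclass
class GlmFit:
    betas: pd.Series
    residuals: np.ndarray
    rss: float

    @property
    def event_betas(self) -> pd.Series:
        return self.betas[[i for i in self.betas.index if not
                           (i == "constant" or str(i).startswith("cosine_"))]]


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    # name columns that add no rank on top of their predecessors
    bad = []
    rank = 0
    for j in range(x.shape[1]):
        r = np.linalg.matrix_rank(x[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def estimate_amplitude(tc, design: DesignMatrix) -> GlmFit:
    """OLS fit of a design to one ROI time course.

    ``tc`` may be a RoiTimeCourse or a plain 1-D array. Raises on a
    rank-deficient design, naming the offending columns.
    """
    y = np.asarray(getattr(tc, "values", tc), dtype=float)
    x = design.matrix
    if len(y) != x.shape[0]:
        raise ValueError("time course length does not match design rows")
    if design.rank_deficient:
        bad = _collinear_columns(x, list(design.frame.columns))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return GlmFit(betas=pd.Series(beta, index=design.frame.columns),
                  residuals=resid, rss=float(resid @ resid))


def exclude_close_boundaries(boundaries: pd.DataFrame, min_gap: float = 6.0,
                             time_col: str = "time_s") -> pd.DataFrame:
    """Drop every boundary involved in a pair closer than ``min_gap`` seconds.

    Both members of a close pair are removed (their responses cannot be
    dissociated in a single-trial GLM). Applied per run when a ``run_id``
    column is present.
    """
    if boundaries.empty:
        return boundaries.copy()

    def _keep(group: pd.DataFrame) -> pd.DataFrame:
        t = group[time_col].to_numpy()
        order = np.argsort(t)
        ts = t[order]
        close = np.zeros(len(ts), dtype=bool)
        gaps = np.diff(ts)
        close[:-1] |= gaps < min_gap
        close[1:] |= gaps < min_gap
        keep = np.empty(len(ts), dtype=bool)
        keep[order] = ~close
        return group[keep]

    if "run_id" in boundaries.columns:
        parts = [_keep(g) for _, g in boundaries.groupby("run_id", sort=False)]
        return pd.concat(parts).sort_index()
    return _keep(boundaries)


def single_trial_betas(tcs, boundaries: pd.DataFrame, tr: float,
                       spec: HrfSpec | None = None, min_gap: float = 6.0,
                       highpass_cutoff: float = 256.0) -> pd.DataFrame:
    """Per-participant, per-boundary amplitude estimates (long format).

    Fits one least-squares-all GLM per participant and run, with a separate
    HRF-convolved stick per boundary, after removing boundaries closer than
    ``min_gap`` seconds to one another. ``tcs`` is an iterable of
    RoiTimeCourse objects carrying ``participant_id`` and ``run_id``.
    Boundary metadata columns (n_observers, salience_bin, ...) are carried
    through to the output.
    """
    spec = spec or HrfSpec()
    kept = exclude_close_boundaries(boundaries, min_gap=min_gap)
    rows = []
    meta_cols = [c for c in kept.columns if c not in ("time_s",)]
    for tc in tcs:
        run_b = kept[kept["run_id"] == tc.run_id] if "run_id" in kept.columns else kept
        if run_b.empty:
            continue
        times = run_b["time_s"].to_numpy()
        design = build_design(times, n_tr=len(tc.values), tr=tr, spec=spec,
                              scheme="per-boundary",
                              highpass_cutoff=highpass_cutoff)
        fit = estimate_amplitude(tc, design)
        betas = fit.event_betas.to_numpy()
        order = np.argsort(times)
        for j, idx in enumerate(order):
            row = {"participant_id": tc.participant_id,
                   "boundary_time_s": times[idx], "beta": betas[j]}
            for c in meta_cols:
                row[c] = run_b.iloc[idx][c]
            rows.append(row)
    return pd.DataFrame(rows)


def fir_timecourse(tcs, boundaries: pd.DataFrame, tr: float,
                   window: tuple[float, float] = (-2.0, 12.0),
                   condition_col: str = "salience_bin") -> pd.DataFrame:
    """FIR deconvolution of the peri-boundary response per condition.

    Each participant's time course is linearly interpolated to a 1-s grid;
    a GLM with one indicator per (condition, peri-boundary second) in
    ``window`` (inclusive) estimates the unconstrained response shape.
    Returns a tidy frame with mean and SEM across participants.
    """
    lags = np.arange(int(window[0]), int(window[1]) + 1)
    conds = list(pd.unique(boundaries[condition_col]))
    per_participant = {}
    for tc in tcs:
        run_b = boundaries[boundaries["run_id"] == tc.run_id] \
            if "run_id" in boundaries.columns else boundaries
        n_sec = int(np.floor((len(tc.values) - 1) * tr)) + 1
        t_grid = np.arange(n_sec, dtype=float)
        y = np.interp(t_grid, np.arange(len(tc.values)) * tr, tc.values)
        cols = [np.ones(n_sec)]
        names = [("constant", 0)]
        for cond in conds:
            times = run_b.loc[run_b[condition_col] == cond, "time_s"].to_numpy()
            for lag in lags:
                col = np.zeros(n_sec)
                idx = np.round(times + lag).astype(int)
                idx = idx[(idx >= 0) & (idx < n_sec)]
                col[idx] = 1.0
                cols.append(col)
                names.append((cond, lag))
        x = np.column_stack(cols)
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        est = {}
        for b, (cond, lag) in zip(beta, names):
            if cond != "constant":
                est[(cond, lag)] = b
        per_participant.setdefault(tc.participant_id, {}).update(est)

    rows = []
    for cond in conds:
        for lag in lags:
            vals = np.array([d[(cond, lag)] for d in per_participant.values()
                             if (cond, lag) in d])
            rows.append({condition_col: cond, "time_s": float(lag),
                         "mean": vals.mean(),
                         "sem": vals.std(ddof=1) / np.sqrt(len(vals))
                         if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)
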