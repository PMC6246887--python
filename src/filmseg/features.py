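"""Per-boundary perceptual-change covariates.

Quantifies how much the film changes across each boundary: spatially
weighted image distance (IMED) and correlation (IMNCC), colour-histogram
distance, global luminance difference, layered feature-map correlations from
a pluggable extractor (a deep network adapter or the bundled mean-pool
pyramid), audio power-spectral-density correlation/distance, and volume
change. Frame measures are evaluated over all cross pairs between the 1 s
windows before and after a boundary (max for distances, min for
correlations — the most-changed pair); audio measures use short epochs
flanking the boundary.

IMED/IMNCC weight pixel interactions by a Gaussian proximity matrix
G_ij = exp(-|P_i - P_j|^2 / 2 sigma^2) / (2 pi sigma^2), truncated to a
9 x 9 pixel neighbourhood (weights outside are negligible); the quadratic
form is evaluated as a 2-D convolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.stats import pearsonr

__all__ = [
    "imed", "imncc", "hist_distance", "luminance_diff", "window_change",
    "psd_measures", "volume_diff", "layered_feature_corr", "svd_compact",
    "shot_flags", "ToyPyramidExtractor", "boundary_covariates",
]


def _gauss_kernel(sigma: float, neighborhood: int) -> np.ndarray:
    if neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd")
    r = neighborhood // 2
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    return np.exp(-(dx ** 2 + dy ** 2) / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames differ in shape")
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    elif a.ndim != 3:
        raise ValueError("frames must be 2-D grayscale or 3-D RGB")
    return a, b


def _gquad(x: np.ndarray, y: np.ndarray, kernel: np.ndarray) -> float:
    """x' G y per channel, summed over channels, via truncated convolution."""
    total = 0.0
    for c in range(x.shape[-1]):
        gy = ndimage.convolve(y[..., c], kernel, mode="constant", cval=0.0)
        total += float(np.sum(x[..., c] * gy))
    return total


def imed(frame_a, frame_b, sigma: float = 1.0, neighborhood: int = 9) -> float:
    """IMage Euclidean Distance between two frames (RGB: channels summed)."""
    a, b = _check_pair(frame_a, frame_b)
    kernel = _gauss_kernel(sigma, neighborhood)
    d = a - b
    return float(np.sqrt(max(_gquad(d, d, kernel), 0.0)))


def imncc(frame_a, frame_b, sigma: float = 1.0, neighborhood: int = 9) -> float:
    """IMage Normalized Cross-Correlation (G-weighted, mean-centred).

    Returns 1 for identical frames, -1 for a frame against its mean-centred
    negative.
    """
    a, b = _check_pair(frame_a, frame_b)
    kernel = _gauss_kernel(sigma, neighborhood)
    a = a - a.mean()
    b = b - b.mean()
    num = _gquad(a, b, kernel)
    den = np.sqrt(max(_gquad(a, a, kernel), 0.0) * max(_gquad(b, b, kernel), 0.0))
    if den == 0:  # at least one flat frame: identical -> 1, else undefined -> 0
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def hist_distance(frame_a, frame_b, n_bins: int = 256) -> float:
    """Euclidean distance between intensity histograms (per RGB channel,
    concatenated). Invariant to any spatial rearrangement of pixels."""
    a, b = _check_pair(frame_a, frame_b)
    ha, hb = [], []
    for c in range(a.shape[-1]):
        ha.append(np.histogram(a[..., c], bins=n_bins, range=(0.0, 1.0))[0])
        hb.append(np.histogram(b[..., c], bins=n_bins, range=(0.0, 1.0))[0])
    ha = np.concatenate(ha).astype(float)
    hb = np.concatenate(hb).astype(float)
    return float(np.linalg.norm(ha - hb))


def luminance_diff(frame_a, frame_b, luma: str = "mean") -> float:
    """Absolute difference in mean luminance (mean over pixels/channels, or
    ITU BT.601 luma for RGB with ``luma='itu'``)."""
    a, b = _check_pair(frame_a, frame_b)
    if luma == "itu" and a.shape[-1] == 3:
        w = np.array([0.299, 0.587, 0.114])
        return float(abs((a @ w).mean() - (b @ w).mean()))
    return float(abs(a.mean() - b.mean()))


def _window_frames(frames, frame_times, t0: float, t1: float) -> np.ndarray:
    frame_times = np.asarray(frame_times, dtype=float)
    idx = np.nonzero((frame_times >= t0) & (frame_times < t1))[0]
    if idx.size == 0:  # window truncated past the run edge: nearest frame
        idx = np.array([np.argmin(np.abs(frame_times - (t0 + t1) / 2))])
    return idx


def window_change(frames, frame_times, boundary_time: float, measure,
                  window: float = 1.0, mode: str = "max-dist") -> float:
    """Extreme of a pairwise frame measure across a boundary.

    All cross pairs between the window [t-window, t) before and [t, t+window)
    after the boundary are evaluated; distances take the max, correlations
    the min (``mode='min-corr'``) — the most-changed pair either way.
    Windows running past the run edges are truncated.
    """
    pre = _window_frames(frames, frame_times, boundary_time - window,
                         boundary_time)
    post = _window_frames(frames, frame_times, boundary_time,
                          boundary_time + window)
    vals = [measure(frames[i], frames[j]) for i in pre for j in post]
    if mode == "max-dist":
        return float(np.max(vals))
    if mode == "min-corr":
        return float(np.min(vals))
    raise ValueError("mode must be 'max-dist' or 'min-corr'")


def psd_measures(audio, rate: int, boundary_time: float, epoch: float = 0.5,
                 f_cutoff: float = 5000.0) -> tuple[float, float]:
    """(correlation, Euclidean distance) of the PSDs in the epochs flanking
    a boundary, periodogram with a Hann window, truncated at ``f_cutoff``."""
    audio = np.asarray(audio, dtype=float)
    n = int(round(epoch * rate))
    c = int(round(boundary_time * rate))
    pre = audio[max(c - n, 0):c]
    post = audio[c:c + n]
    if len(pre) < 8 or len(post) < 8:
        raise ValueError("boundary too close to the audio edge for the epoch")
    m = min(len(pre), len(post))
    f, p_pre = signal.periodogram(pre[-m:], fs=rate, window="hann")
    _, p_post = signal.periodogram(post[:m], fs=rate, window="hann")
    keep = f <= f_cutoff
    p_pre, p_post = p_pre[keep], p_post[keep]
    if p_pre.std() == 0 or p_post.std() == 0:
        corr = 1.0 if np.allclose(p_pre, p_post) else 0.0
    else:
        corr = float(pearsonr(p_pre, p_post)[0])
    return corr, float(np.linalg.norm(p_pre - p_post))


def volume_diff(audio, rate: int, boundary_time: float, window: float = 0.1,
                kind: str = "rms") -> float:
    """Absolute difference in volume (RMS amplitude by default,
    ``kind='mean-abs'`` for mean absolute) across a boundary."""
    audio = np.asarray(audio, dtype=float)
    n = int(round(window * rate))
    c = int(round(boundary_time * rate))
    pre = audio[max(c - n, 0):c]
    post = audio[c:c + n]
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("boundary too close to the audio edge for the window")
    if kind == "rms":
        vol = lambda x: float(np.sqrt(np.mean(x ** 2)))
    elif kind == "mean-abs":
        vol = lambda x: float(np.mean(np.abs(x)))
    else:
        raise ValueError("kind must be 'rms' or 'mean-abs'")
    return abs(vol(pre) - vol(post))


class ToyPyramidExtractor:
    """Deterministic stand-in feature extractor: a mean-pool pyramid.

    Layer l is the frame (converted to grayscale) mean-pooled by a factor
    2**l. Any object with ``n_layers`` and ``layer_maps(frame) -> list`` can
    be plugged in instead (e.g. an adapter around a pretrained network).
    """

    def __init__(self, n_layers: int = 3):
        self.n_layers = n_layers

    def layer_maps(self, frame) -> list[np.ndarray]:
        f = np.asarray(frame, dtype=float)
        if f.ndim == 3:
            f = f.mean(axis=-1)
        maps = []
        for l in range(self.n_layers):
            k = min(2 ** l, f.shape[0], f.shape[1])
            h, w = (f.shape[0] // k) * k, (f.shape[1] // k) * k
            pooled = f[:h, :w].reshape(h // k, k, w // k, k).mean(axis=(1, 3))
            maps.append(pooled)
        return maps


def layered_feature_corr(frames, frame_times, boundary_time: float,
                         extractor, window: float = 1.0) -> np.ndarray:
    """Per-layer feature-map correlation across a boundary (length =
    extractor.n_layers), minimum over all window cross pairs."""
    pre = _window_frames(frames, frame_times, boundary_time - window,
                         boundary_time)
    post = _window_frames(frames, frame_times, boundary_time,
                          boundary_time + window)
    out = np.full(extractor.n_layers, np.inf)
    maps_pre = {i: extractor.layer_maps(frames[i]) for i in pre}
    maps_post = {j: extractor.layer_maps(frames[j]) for j in post}
    for i in pre:
        for j in post:
            for l in range(extractor.n_layers):
                a = maps_pre[i][l].ravel()
                b = maps_post[j][l].ravel()
                if a.std() == 0 or b.std() == 0:
                    r = 1.0 if np.allclose(a, b) else 0.0
                else:
                    r = float(pearsonr(a, b)[0])
                out[l] = min(out[l], r)
    return out


def svd_compact(feature_matrix, variance_target: float = 0.90,
                k_components: int | None = None):
    """Compact correlated covariate columns into leading SVD components.

    Columns are standardised; returns ``(scores, explained_ratio)`` where
    scores holds the smallest set of leading components reaching
    ``variance_target`` (or exactly ``k_components``).
    """
    x = np.asarray(feature_matrix, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    if k_components is None:
        k_components = int(np.searchsorted(np.cumsum(ratio),
                                           variance_target - 1e-12) + 1)
    k_components = min(k_components, len(s))
    return u[:, :k_components] * s[:k_components], ratio[:k_components]


def shot_flags(boundaries: pd.DataFrame, shot_table: pd.DataFrame,
               tr: float) -> pd.DataFrame:
    """Objective location/time-shift flags inherited from shot annotations.

    ``shot_table`` has one row per film shot: ``onset_s``, ``location_id``
    and ``temporal_progression`` (1 if the shot jumps forward in story
    time). A boundary inherits the flags of the nearest shot onset within
    1 TR (isLoc = that shot changes location vs the previous shot); with no
    shot transition nearby both flags are 0. When isLoc and isTemp coincide
    on every boundary they are additionally emitted as the single combined
    predictor isLocTemp and flagged in ``attrs``.
    """
    shots = shot_table.sort_values("onset_s").reset_index(drop=True)
    loc_change = np.zeros(len(shots), dtype=int)
    if len(shots) > 1:
        loc_change[1:] = (shots["location_id"].to_numpy()[1:]
                          != shots["location_id"].to_numpy()[:-1]).astype(int)
    temp_change = shots["temporal_progression"].to_numpy().astype(int)

    out = boundaries.copy()
    is_loc = np.zeros(len(out), dtype=int)
    is_temp = np.zeros(len(out), dtype=int)
    onsets = shots["onset_s"].to_numpy(dtype=float)
    for i, t in enumerate(out["time_s"].to_numpy(dtype=float)):
        d = np.abs(onsets - t)
        j = int(np.argmin(d))
        if d[j] <= tr:
            is_loc[i] = loc_change[j]
            is_temp[i] = temp_change[j]
    out["isLoc"] = is_loc
    out["isTemp"] = is_temp
    combined = bool(len(out)) and bool(np.all(is_loc == is_temp))
    out.attrs["isLocTemp_combined"] = combined
    if combined:
        out["isLocTemp"] = (is_loc | is_temp).astype(int)
    return out


def boundary_covariates(boundaries: pd.DataFrame, frames=None,
                        frame_times=None, audio=None, audio_rate=None,
                        extractor=None, shot_table=None, tr: float = 2.0,
                        sigma: float = 1.0, window: float = 1.0,
                        epoch: float = 0.5, vol_window: float = 0.1,
                        f_cutoff: float = 5000.0) -> pd.DataFrame:
    """Assemble the full per-boundary covariate table from available media.

    Stages with missing inputs (no frames, no audio, no shot table) are
    skipped; the returned frame always keys on the boundary rows given.
    """
    out = boundaries.copy()
    times = out["time_s"].to_numpy(dtype=float)
    if frames is not None:
        out["visDist"] = [window_change(frames, frame_times, t,
                                        lambda a, b: imed(a, b, sigma),
                                        window, "max-dist") for t in times]
        out["visCorr"] = [window_change(frames, frame_times, t,
                                        lambda a, b: imncc(a, b, sigma),
                                        window, "min-corr") for t in times]
        out["visHistDist"] = [window_change(frames, frame_times, t,
                                            hist_distance, window,
                                            "max-dist") for t in times]
        out["lumDist"] = [window_change(frames, frame_times, t,
                                        luminance_diff, window, "max-dist")
                          for t in times]
        if extractor is not None:
            corr = np.stack([layered_feature_corr(frames, frame_times, t,
                                                  extractor, window)
                             for t in times])
            for l in range(corr.shape[1]):
                out[f"dcnn_layer_{l}"] = corr[:, l]
    if audio is not None:
        psd = [psd_measures(audio, audio_rate, t, epoch, f_cutoff)
               for t in times]
        out["psdCorr"] = [p[0] for p in psd]
        out["psdDist"] = [p[1] for p in psd]
        out["absVolDiff"] = [volume_diff(audio, audio_rate, t, vol_window)
                             for t in times]
    if shot_table is not None:
        flagged = shot_flags(out, shot_table, tr)
        for c in ("isLoc", "isTemp", "isLocTemp"):
            if c in flagged.columns:
                out[c] = flagged[c]
        out.attrs["isLocTemp_combined"] = flagged.attrs.get(
            "isLocTemp_combined", False)
    return out
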