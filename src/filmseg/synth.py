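"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the statistical structure of the real inputs: observer keypress
logs with controllable per-boundary detection probability ("salience"), ROI
BOLD as HRF-convolved sticks at ground-truth boundaries plus low-frequency
drift and AR(1) noise, multi-voxel patterns with piecewise-constant event
structure, and toy film media (frame sequences with scene cuts, audio with
spectral shifts). All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import HrfSpec, build_design, cosine_basis
from .roi import RoiTimeCourse

__all__ = [
    "GroundTruth",
    "simulate_observers",
    "simulate_bold",
    "simulate_patterns",
    "simulate_media",
    "write_media",
]


@dataclass
class GroundTruth:
    """The true generative state of a simulated run.

    ``salience_prob`` is the chance each observer independently detects each
    boundary; ``amplitudes`` scale the BOLD response per boundary.
    """

    boundary_times: np.ndarray
    salience_prob: np.ndarray
    amplitudes: np.ndarray
    run_length: float = 480.0
    tr: float = 2.0
    n_participants: int = 20
    n_observers: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        self.boundary_times = np.asarray(self.boundary_times, dtype=float)
        nb = len(self.boundary_times)
        self.salience_prob = np.broadcast_to(
            np.asarray(self.salience_prob, dtype=float), (nb,)).copy()
        self.amplitudes = np.broadcast_to(
            np.asarray(self.amplitudes, dtype=float), (nb,)).copy()
        if np.any(np.diff(self.boundary_times) <= 0):
            raise ValueError("boundary_times must be strictly increasing")
        if nb and (self.boundary_times[0] < 0
                   or self.boundary_times[-1] >= self.run_length):
            raise ValueError("boundary_times must lie in [0, run_length)")
        if np.any((self.salience_prob < 0) | (self.salience_prob > 1)):
            raise ValueError("salience_prob must lie in [0, 1]")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_tr(self) -> int:
        return int(round(self.run_length / self.tr))

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(d, indent=1))


def simulate_observers(gt: GroundTruth, rt_mean: float = 0.9,
                       rt_jitter: float = 0.3, spurious_rate: float = 0.0,
                       run_id: str = "run-1", rng=None) -> pd.DataFrame:
    """Simulated keypress log: observer x press-time table.

    Each observer detects each boundary independently with its
    ``salience_prob``; a detected press lands at boundary time + ``rt_mean``
    + Gaussian(0, ``rt_jitter``) jitter. Spurious presses arrive as a
    homogeneous Poisson process at ``spurious_rate`` per second (default 0).
    """
    if rt_mean < 0:
        raise ValueError("rt_mean must be nonnegative")
    if rt_jitter < 0:
        raise ValueError("rt_jitter must be nonnegative")
    rng = np.random.default_rng(gt.seed if rng is None else rng)
    rows = []
    for o in range(gt.n_observers):
        oid = f"obs-{o:02d}"
        detected = rng.random(len(gt.boundary_times)) < gt.salience_prob
        times = gt.boundary_times[detected] + rt_mean
        if rt_jitter > 0:
            times = times + rng.normal(0.0, rt_jitter, size=times.size)
        if spurious_rate > 0:
            n_spur = rng.poisson(spurious_rate * gt.run_length)
            times = np.concatenate([times,
                                    rng.uniform(0, gt.run_length, n_spur)])
        times = np.sort(np.clip(times, 0.0, gt.run_length))
        for t in times:
            rows.append({"observer_id": oid, "run_id": run_id,
                         "press_time_s": float(t)})
    return pd.DataFrame(rows, columns=["observer_id", "run_id", "press_time_s"])


def simulate_bold(gt: GroundTruth, noise_sd: float = 1.0, ar1: float = 0.3,
                  drift_amp: float = 0.0, spec: HrfSpec | None = None,
                  run_id: str = "run-1", rng=None):
    """Per-participant ROI BOLD: HRF-convolved sticks + drift + AR(1) noise.

    The signal is the per-boundary design (amplitude-weighted), identical
    across participants; drift is a random combination of the cosine
    confound set below the high-pass cutoff (so filtering removes it by
    construction); noise is stationary AR(1) with marginal SD ``noise_sd``.
    Returns ``(time courses, design)`` where the design is the ground-truth
    per-boundary DesignMatrix.
    """
    if not (0 <= ar1 < 1):
        raise ValueError("ar1 must lie in [0, 1)")
    spec = spec or HrfSpec()
    rng = np.random.default_rng(gt.seed + 1 if rng is None else rng)
    n_tr = gt.n_tr
    design = build_design(gt.boundary_times, n_tr=n_tr, tr=gt.tr, spec=spec,
                          scheme="per-boundary")
    event_mat = design.frame[design.event_cols].to_numpy()
    # columns are in sorted-time order, as are gt.amplitudes
    signal = event_mat @ gt.amplitudes
    drift_basis = cosine_basis(n_tr, gt.tr)[:, 1:]

    tcs = []
    for p in range(gt.n_participants):
        drift = np.zeros(n_tr)
        if drift_amp > 0 and drift_basis.shape[1]:
            w = rng.normal(0.0, drift_amp, size=drift_basis.shape[1])
            drift = drift_basis @ w
        noise = np.zeros(n_tr)
        if noise_sd > 0:
            w = rng.normal(0.0, noise_sd * np.sqrt(1 - ar1 ** 2), size=n_tr)
            e = np.empty(n_tr)
            e[0] = rng.normal(0.0, noise_sd)
            for t in range(1, n_tr):
                e[t] = ar1 * e[t - 1] + w[t]
            noise = e
        tcs.append(RoiTimeCourse(values=signal + drift + noise, tr=gt.tr,
                                 run_id=run_id,
                                 participant_id=f"sub-{p:03d}"))
    return tcs, design


def simulate_patterns(n_voxels: int, event_boundaries, n_tr: int,
                      noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """Voxel x TR pattern matrix with piecewise-constant event structure.

    ``event_boundaries`` are the TR indices where a new event begins (the
    first event implicitly starts at TR 0). Each event has an iid standard
    normal mean pattern; iid Gaussian noise with SD ``noise_sd`` is added.
    """
    rng = np.random.default_rng(rng)
    starts = [0] + sorted(int(b) for b in event_boundaries) + [n_tr]
    if any(s <= p for p, s in zip(starts[:-2], starts[1:-1])) or \
            (len(starts) > 2 and starts[-2] >= n_tr):
        raise ValueError("event boundaries must be increasing TRs in (0, n_tr)")
    x = np.empty((n_voxels, n_tr))
    for a, b in zip(starts[:-1], starts[1:]):
        x[:, a:b] = rng.standard_normal((n_voxels, 1))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return x


def simulate_media(run_length: float, cut_times, frame_rate: float = 5.0,
                   audio_rate: int = 16000, frame_shape=(48, 64),
                   rgb: bool = True, luminances=None, tones=None, rng=None):
    """Toy film media: frames constant within a scene, tones per scene.

    Scenes are the intervals between consecutive ``cut_times``. Each scene
    gets a random (or caller-supplied mean ``luminances``) texture, constant
    for all its frames, and a mixture of pure ``tones`` (Hz) in the audio.
    Returns ``(frames, frame_times, audio, audio_rate)`` with frames in
    [0, 1] of shape (T, H, W, 3) if ``rgb`` else (T, H, W).
    """
    rng = np.random.default_rng(rng)
    cut_times = sorted(float(c) for c in cut_times)
    edges = [0.0] + cut_times + [run_length]
    n_scenes = len(edges) - 1
    if luminances is None:
        luminances = rng.uniform(0.2, 0.8, size=n_scenes)
    if tones is None:
        tones = rng.uniform(200.0, 4000.0, size=n_scenes)

    h, w = frame_shape
    scene_frames = []
    for s in range(n_scenes):
        tex = np.clip(luminances[s] + rng.uniform(-0.1, 0.1, size=(h, w)), 0, 1)
        if rgb:
            tex = np.stack([np.clip(tex + rng.uniform(-0.05, 0.05, (h, w)), 0, 1)
                            for _ in range(3)], axis=-1)
        scene_frames.append(tex)

    frame_times = np.arange(0.0, run_length, 1.0 / frame_rate)
    scene_of = np.searchsorted(np.asarray(cut_times), frame_times, side="right")
    frames = np.stack([scene_frames[s] for s in scene_of])

    t_audio = np.arange(int(round(run_length * audio_rate))) / audio_rate
    scene_of_sample = np.searchsorted(np.asarray(cut_times), t_audio, side="right")
    audio = np.zeros_like(t_audio)
    for s in range(n_scenes):
        m = scene_of_sample == s
        audio[m] = 0.5 * np.sin(2 * np.pi * np.atleast_1d(tones)[s] * t_audio[m])
    return frames, frame_times, audio, audio_rate


def write_media(out_dir, frames, audio, audio_rate: int,
                frame_rate: float) -> None:
    """Write frames as PNGs plus a 16-bit PCM WAV and a frame-rate sidecar."""
    import imageio.v3 as iio
    from scipy.io import wavfile

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        iio.imwrite(out / "frames" / f"frame_{i:05d}.png",
                    (np.clip(f, 0, 1) * 255).astype(np.uint8))
    wavfile.write(out / "audio.wav", audio_rate,
                  (np.clip(audio, -1, 1) * 32767).astype(np.int16))
    (out / "media.json").write_text(json.dumps({"frame_rate": frame_rate,
                                                "audio_rate": audio_rate}))
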