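"""ROI time-course extraction and normalisation.

Reads 4-D NIfTI volumes and mask images via nibabel, extracts the mean
signal over mask voxels per TR, z-scores full-run time courses, and averages
across participants (and bilateral homolog ROIs) on the normalised scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiTimeCourse", "extract_roi", "zscore", "zscore_and_average"]


@dataclass
class RoiTimeCourse:
    """One run's ROI signal for one participant."""

    values: np.ndarray
    tr: float
    run_id: str = "run-1"
    participant_id: str = "sub-1"
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("time course must be 1-D with length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time course contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_tr(self) -> int:
        return len(self.values)


def _as_array(img):
    try:  # nibabel image
        return np.asarray(img.get_fdata())
    except AttributeError:
        return np.asarray(img, dtype=float)


def extract_roi(volume_4d, mask, tr: float, run_id: str = "run-1",
                participant_id: str = "sub-1") -> RoiTimeCourse:
    """Mean signal over mask voxels at each TR.

    ``volume_4d`` and ``mask`` may be nibabel images or plain arrays; the
    mask must be nonempty and share the volume's spatial grid.
    """
    data = _as_array(volume_4d)
    m = _as_array(mask).astype(bool)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    if m.shape != data.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    if not m.any():
        raise ValueError("mask is empty")
    values = data[m].mean(axis=0)
    return RoiTimeCourse(values=values, tr=tr, run_id=run_id,
                         participant_id=participant_id)


def zscore(tc: RoiTimeCourse) -> RoiTimeCourse:
    """z-score the full run time course (error on constant input)."""
    sd = tc.values.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant time course")
    return RoiTimeCourse(values=(tc.values - tc.values.mean()) / sd, tr=tc.tr,
                         run_id=tc.run_id, participant_id=tc.participant_id,
                         zscored=True)


def zscore_and_average(tcs, run_id: str | None = None) -> RoiTimeCourse:
    """z-score each time course over its full length, then average elementwise.

    Used both for averaging across participants and for averaging bilateral
    (left/right) ROI pairs: normalisation happens before averaging so each
    series contributes on a common scale.
    """
    tcs = list(tcs)
    if not tcs:
        raise ValueError("no time courses given")
    n = {tc.n_tr for tc in tcs}
    if len(n) != 1:
        raise ValueError("time courses differ in length")
    trs = {tc.tr for tc in tcs}
    if len(trs) != 1:
        raise ValueError("time courses differ in TR")
    z = np.stack([zscore(tc).values for tc in tcs])
    return RoiTimeCourse(values=z.mean(axis=0), tr=tcs[0].tr,
                         run_id=run_id or tcs[0].run_id,
                         participant_id="group", zscored=False)
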