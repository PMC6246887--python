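"""Cortical pattern-shift segmentation with the ordered-event HMM.

Multi-voxel patterns in high-level cortex are piecewise-stable within
events. A left-to-right HMM with K events segments the pattern time series;
the recovered shifts are classified by whether they follow an annotated
boundary (within 2 TRs), and the ROI response is averaged around matched
vs non-matched shifts.
"""

import numpy as np

from filmseg import (RoiTimeCourse, classify_shifts, fit_event_hmm,
                     peri_shift_response)
from filmseg.synth import simulate_patterns

tr = 2.0
boundary_trs = [18, 47, 76, 118, 139, 171]
boundary_times = [b * tr + 0.7 for b in boundary_trs]
patterns = simulate_patterns(50, boundary_trs, 200, noise_sd=0.6, rng=4)

fit = fit_event_hmm(patterns, k_events=len(boundary_trs) + 1)
print(f"recovered shifts (TRs): {fit.shift_times.tolist()} "
      f"(truth {boundary_trs})")

shifts = classify_shifts(fit.shift_times, boundary_times, tr=tr, window_tr=2)
print(shifts.to_string(index=False))

# ROI signal bumps only after true boundaries
rng = np.random.default_rng(5)
y = rng.normal(0, 0.2, 200)
for b in boundary_trs:
    y[b + 1:b + 4] += 1.0
out = peri_shift_response(RoiTimeCourse(values=y, tr=tr), shifts,
                          n_perm=500, seed=6)
for label in ("match", "non-match"):
    d = out[label]
    p = d["permutation"].p if d["permutation"] else float("nan")
    print(f"{label}: n={d['n_shifts']}, amplitude (TRs 0-2) = "
          f"{d['amplitude']:.3f}, permutation p = {p:.3g}")
print("""
Matched shifts carry the boundary-locked ROI response; non-matched shifts
(if any) should show none.""")
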