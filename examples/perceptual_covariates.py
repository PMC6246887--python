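"""Perceptual-change covariates at boundaries from toy film media.

Builds a short synthetic film (frames + audio with scene cuts), computes
every perceptual covariate at three boundaries — two on cuts, one inside a
scene — and shows that the change measures separate them.
"""

import numpy as np
import pandas as pd

from filmseg import features
from filmseg.synth import simulate_media

cuts = [10.0, 20.0]
frames, frame_times, audio, rate = simulate_media(
    30.0, cuts, frame_rate=4.0, audio_rate=8000, frame_shape=(24, 32),
    rng=0)
boundaries = pd.DataFrame({"time_s": [10.0, 20.0, 15.0]})  # 15 s: no cut

cov = features.boundary_covariates(
    boundaries, frames=frames, frame_times=frame_times, audio=audio,
    audio_rate=rate, extractor=features.ToyPyramidExtractor(2))
cols = ["time_s", "visDist", "visCorr", "visHistDist", "lumDist",
        "psdCorr", "psdDist", "absVolDiff"]
print(cov[cols].round(3).to_string(index=False))
print("""
Rows 1-2 sit on scene cuts: large image distances (visDist, visHistDist),
low audio-spectrum correlation (psdCorr). Row 3 falls inside a scene: zero
visual change and psdCorr = 1. These covariates enter the mixed model to
test whether salience effects survive adjustment for perceptual change.""")
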