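import numpy as np
import pandas as pd
import pytest

from filmseg.glm import HrfSpec
from filmseg.synth import GroundTruth


@pytest.fixture
def hrf_spec():
    return HrfSpec()


@pytest.fixture
def small_gt():
    """Four well-separated boundaries in a 240 s run, full agreement."""
    return GroundTruth(boundary_times=[30.0, 70.0, 120.0, 180.0],
                       salience_prob=1.0, amplitudes=1.0, run_length=240.0,
                       tr=2.0, n_participants=5, n_observers=6, seed=7)


def make_annotations(press_times_by_observer, run_id="run-1",
                     rt_corrected=True):
    """Tidy press-log frame from {observer: [times]}."""
    rows = [{"observer_id": o, "run_id": run_id, "press_time_s": t}
            for o, times in press_times_by_observer.items() for t in times]
    df = pd.DataFrame(rows, columns=["observer_id", "run_id", "press_time_s"])
    df.attrs["rt_corrected"] = rt_corrected
    return df


def simulate_beta_table(seed, n_participants=200, n_boundaries=60, slope=0.5,
                        sd_participant=0.3, sd_boundary=0.2, sd_noise=1.0):
    """Single-trial beta table with a linear salience effect and crossed
    participant/boundary random intercepts — the generative model the mixed
    models assume."""
    rng = np.random.default_rng(seed)
    part = np.repeat(np.arange(n_participants), n_boundaries)
    item = np.tile(np.arange(n_boundaries), n_participants)
    salience = np.tile(rng.integers(1, 4, n_boundaries).astype(float),
                       n_participants)
    y = (slope * salience
         + rng.normal(0, sd_participant, n_participants)[part]
         + rng.normal(0, sd_boundary, n_boundaries)[item]
         + rng.normal(0, sd_noise, len(part)))
    return pd.DataFrame({"beta": y, "salience_score": salience,
                         "n_observers": salience * 4 + 2,
                         "participant_id": part, "boundary_id": item})
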