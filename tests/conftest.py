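import numpy as np
import pandas as pd
import pytest

import gazecourse as gc


@pytest.fixture(scope="session")
def small_session():
    """A small but full-design synthetic cohort (5 infants, 8 trials)."""
    cfg = gc.SimConfig(n_subjects=5, seed=11)
    samples, truth = gc.simulate_session(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def processed(small_session):
    cfg, samples, truth = small_session
    fixations, labeled = gc.process_samples(samples, truth.aoi_trajectories)
    return cfg, fixations, labeled, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_fixation_df(rows):
    """Build a minimal fixation table from (subject, trial, aoi, duration)."""
    out = []
    for k, (subj, trial, aoi, dur) in enumerate(rows):
        out.append(
            dict(
                subject_id=subj,
                trial_number=trial,
                stimulus_id="aa1_infant_directed",
                face_race="asian_american",
                speech_type="infant_directed",
                fixation_index=k + 1,
                start_ms=0.0,
                end_ms=dur,
                duration_ms=dur,
                centroid_x=0.0,
                centroid_y=0.0,
                aoi=aoi,
            )
        )
    return pd.DataFrame(out)
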