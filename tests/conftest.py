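import numpy as np
import pandas as pd
import pytest

import valphys as v
from valphys.synthetic import temperature_annotations
from valphys.temperature import clean_outliers, segment_temperature, trials_table


@pytest.fixture(scope="session")
def default_dataset():
    """The default 24-subject cohort (ground-truth intervals, no ECG trace)."""
    return v.generate_dataset(effects=v.EffectModel(seed=11), include_ecg=False)


@pytest.fixture(scope="session")
def small_design():
    """A reduced cohort for fast end-to-end checks."""
    return v.StudyDesign(n_subjects=6, n_men=4, trials_per_subject=6,
                         trial_duration_s=(43.0, 50.0))


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return v.generate_dataset(small_design, v.EffectModel(seed=5), include_ecg=False)


def build_fused(dataset):
    """Run extraction + fusion for a dataset (helper shared by tests)."""
    hrv = pd.concat(
        [v.hrv_for_trials(dataset, s, source="ibi") for s in dataset.subject_ids],
        ignore_index=True,
    )
    eeg = v.extract_feature_vectors(dataset)
    trials = []
    for s in dataset.subjects:
        segs = segment_temperature(
            s.temp, s.temp_fs, temperature_annotations(s), s.subject_id, s.gender
        )
        trials += [clean_outliers(t) for t in segs]
    return v.fuse_modalities(eeg, hrv, trials_table(trials))


@pytest.fixture(scope="session")
def fused_default(default_dataset):
    return build_fused(default_dataset)
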