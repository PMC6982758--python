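"""Simulate the multimodal cohort and look at its structure.

Generates 24 subjects (16 men, 8 women) with 14 video trials each
(7 positive / 7 negative valence), carrying ECG-derived interval series,
wrist skin temperature and EEG band-power features with planted effects.
"""

import valphys as v

dataset = v.generate_dataset(v.StudyDesign(), v.EffectModel(seed=1))
trials = dataset.trials_table()

print(f"subjects: {len(dataset.subjects)} "
      f"({sum(s.gender == 'M' for s in dataset.subjects)} men)")
print(f"trials per subject: {dataset.design.trials_per_subject}")
pos = trials[trials.label == "positive"]
neg = trials[trials.label == "negative"]
print(f"valence ratings: positive {pos.valence_rating.mean():.2f} "
      f"(s.d. {pos.valence_rating.std():.2f}), "
      f"negative {neg.valence_rating.mean():.2f} "
      f"(s.d. {neg.valence_rating.std():.2f})")
s = dataset.subjects[0]
print(f"subject {s.subject_id}: ECG {s.ecg.duration_s:.0f} s at {s.ecg.fs:.0f} Hz, "
      f"temperature {len(s.temp)} samples, "
      f"EEG features {s.eeg_features.shape[0]} windows x "
      f"{s.eeg_features.shape[1] - 2} powers")
# The rating means mirror how positive clips are rated high (~7.5/9) and
# negative clips low (~2.9/9) on the subjective valence scale.
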