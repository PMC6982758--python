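"""Skin-temperature segmentation, MAD cleaning and condition statistics.

Cuts 28 s segments per video trial and baseline, removes spike artifacts
(> 3 scaled MADs from the segment median) and compares conditions with
Mann-Whitney tests, overall and per gender.
"""

import valphys as v
from valphys.synthetic import temperature_annotations
from valphys.temperature import (clean_outliers, segment_temperature,
                                 temperature_statistics)

dataset = v.generate_dataset(effects=v.EffectModel(seed=4), include_ecg=False)
trials = []
for s in dataset.subjects:
    segs = segment_temperature(s.temp, s.temp_fs, temperature_annotations(s),
                               s.subject_id, s.gender)
    trials += [clean_outliers(t) for t in segs]

for group, gender in (("all", None), ("women", "F"), ("men", "M")):
    st = temperature_statistics(trials, mode="SI", gender=gender)
    row = st[st.comparison == "positive_vs_negative"].iloc[0]
    print(f"{group:>5}: positive {row.mean_a:.3f} degC vs negative "
          f"{row.mean_b:.3f} degC, p = {row.p:.3g}")
base = temperature_statistics(trials, mode="SI")
row = base[base.comparison == "positive_vs_baseline"].iloc[0]
print(f"stimulus vs baseline: {row.mean_a:.3f} vs {row.mean_b:.3f} degC, "
      f"p = {row.p:.3g}")
# Stimulation warms the wrist relative to baseline; negative clips run
# slightly warmer than positive ones, and that valence difference is
# carried by the women in the cohort.
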