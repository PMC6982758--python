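"""Generator contracts: determinism, round-trips and planted effects."""

import numpy as np
import pytest
from scipy import stats as sps

import valphys as v
from valphys.design import ConfigurationError
from valphys.synthetic import nn50_per_run, nominal_sd2


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_subjects": 0}, "n_subjects"),
            ({"n_men": 30}, "n_men"),
            ({"trials_per_subject": 7}, "trials_per_subject"),
            ({"trial_duration_s": (50.0, 40.0)}, "trial_duration_s"),
            ({"baseline_duration_s": -1.0}, "baseline_duration_s"),
            ({"ecg_fs": 0.0}, "ecg_fs"),
        ],
    )
    def test_invalid_design_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            v.StudyDesign(**kwargs)

    def test_negative_shift_rejected(self):
        with pytest.raises(ConfigurationError, match="temp_neg_shift"):
            v.EffectModel(temp_neg_shift=-0.1)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_design):
        a = v.generate_dataset(small_design, v.EffectModel(seed=7))
        b = v.generate_dataset(small_design, v.EffectModel(seed=7))
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.trials.equals(sb.trials)
            assert np.array_equal(sa.temp, sb.temp)
            assert np.array_equal(sa.ecg.samples, sb.ecg.samples)
            assert sa.eeg_features.equals(sb.eeg_features)
            for tid in sa.ibi:
                assert np.array_equal(
                    sa.ibi[tid].intervals_ms, sb.ibi[tid].intervals_ms
                )

    def test_different_seed_differs(self, small_design):
        a = v.generate_dataset(small_design, v.EffectModel(seed=7), include_ecg=False)
        b = v.generate_dataset(small_design, v.EffectModel(seed=8), include_ecg=False)
        assert not np.array_equal(a.subjects[0].temp, b.subjects[0].temp)


class TestECGSynthesis:
    def test_constant_rhythm_peak_spacing(self):
        trace = v.synthesize_ecg(np.full(15, 1000.0), 256.0)
        peaks = v.detect_r_peaks(v.highpass_ecg(trace))
        assert np.all(np.diff(peaks) == 256)

    def test_round_trip_within_one_sample(self):
        rng = np.random.default_rng(3)
        fs = 256.0
        for _ in range(10):
            rr = rng.uniform(600, 1100, size=30)
            trace = v.synthesize_ecg(rr, fs)
            peaks = v.detect_r_peaks(v.highpass_ecg(trace))
            assert len(peaks) == len(rr) + 1
            got = np.diff(peaks) / fs * 1000.0
            assert np.max(np.abs(got - rr)) <= 1000.0 / fs + 1e-9

    def test_empty_and_out_of_range(self):
        with pytest.raises(ConfigurationError):
            v.synthesize_ecg([], 256.0)
        with pytest.raises(ConfigurationError):
            v.synthesize_ecg([100.0, 900.0], 256.0)


class TestIBISynthesis:
    def test_minimum_length(self):
        with pytest.raises(ConfigurationError):
            v.synthesize_ibi(1, seed=0)

    def test_mean_heart_rate(self):
        s = v.synthesize_ibi(500, base_rr=857.0, seed=0)
        hr = 60000.0 / s.intervals_ms.mean()
        assert hr == pytest.approx(70.0, abs=2.0)

    def test_null_seeds_same_distribution(self):
        a = v.synthesize_ibi(1000, seed=1).intervals_ms
        b = v.synthesize_ibi(1000, seed=2).intervals_ms
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_sd2_shift_raises_sd2(self):
        eff = v.EffectModel(seed=0)
        rng = np.random.default_rng(10)
        shifted, plain = [], []
        for _ in range(40):
            s1 = v.synthesize_ibi(80, effects=eff, gender="F", condition="negative",
                                  rng=rng)
            s0 = v.synthesize_ibi(80, effects=eff, gender="F", condition="positive",
                                  rng=rng)
            shifted.append(v.poincare_measures(s1)["sd2"])
            plain.append(v.poincare_measures(s0)["sd2"])
        assert np.mean(shifted) > np.mean(plain) + 10.0

    def test_nn50_shift_realized_in_expectation(self):
        eff = v.EffectModel(nn50_male_shift=10.0, seed=0)
        rng = np.random.default_rng(11)
        pos, neg = [], []
        for _ in range(150):
            sp = v.synthesize_ibi(80, effects=eff, gender="M", condition="positive",
                                  rng=rng)
            sn = v.synthesize_ibi(80, effects=eff, gender="M", condition="negative",
                                  rng=rng)
            pos.append(v.time_domain_measures(sp)["nn50"])
            neg.append(v.time_domain_measures(sn)["nn50"])
        diff = np.mean(pos) - np.mean(neg)
        se = np.sqrt(np.var(pos) / len(pos) + np.var(neg) / len(neg))
        assert abs(diff - 10.0) <= 2 * se + 0.5

    def test_rate_calibration_constants(self):
        # the Poisson rate calibration must predict > 1 count per run
        assert nn50_per_run() > 1.0
        assert nominal_sd2() > 0.0


class TestDatasetStructure:
    def test_counts_and_balance(self, default_dataset):
        ds = default_dataset
        assert len(ds.subjects) == 24
        assert sum(s.gender == "M" for s in ds.subjects) == 16
        for s in ds.subjects:
            counts = s.trials["label"].value_counts()
            assert counts["positive"] == counts["negative"] == 7
            assert s.trials["duration_s"].between(43, 78).all()
            assert s.trials["valence_rating"].between(1, 9).all()
            assert s.trials["arousal_rating"].between(1, 9).all()

    def test_rating_class_means(self, default_dataset):
        trials = default_dataset.trials_table()
        pos = trials.loc[trials.label == "positive", "valence_rating"]
        neg = trials.loc[trials.label == "negative", "valence_rating"]
        assert pos.mean() == pytest.approx(7.51, abs=0.5)
        assert neg.mean() == pytest.approx(2.91, abs=0.5)
        assert neg.mean() < pos.mean()

    def test_modality_drop_flags(self, small_design):
        ds = v.generate_dataset(
            small_design, v.EffectModel(seed=1), include_ecg=True,
            drop_ecg_subjects=("S02",), drop_temp_subjects=("S03",),
        )
        assert ds.subject("S02").ecg is None
        assert ds.subject("S01").ecg is not None
        assert ds.subject("S03").temp is None

    def test_null_effects_no_class_difference(self, small_design):
        # all shifts zero: positive and negative pooled features indistinguishable
        ds = v.generate_dataset(small_design, v.EffectModel.null(seed=4),
                                include_ecg=False)
        import pandas as pd

        hrv = pd.concat(
            [v.hrv_for_trials(ds, s, source="ibi") for s in ds.subject_ids],
            ignore_index=True,
        )
        res = v.mann_whitney(
            hrv.loc[hrv.label == "positive", "nn50"],
            hrv.loc[hrv.label == "negative", "nn50"],
        )
        assert res.p > 0.01
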