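"""HRV measures against independent direct-definition oracles."""

import numpy as np
import pytest

import valphys as v
from valphys.design import ConfigurationError, QualityError
from valphys.hrv import ECGTrace, IBISeries


def series_from(intervals):
    iv = np.asarray(intervals, dtype=float)
    return IBISeries(iv, np.cumsum(iv) / 1000.0)


def oracle_time_domain(iv):
    """Brute-force re-statement of the time-domain definitions."""
    iv = list(map(float, iv))
    n = len(iv)
    mean = sum(iv) / n
    sdnn = (sum((x - mean) ** 2 for x in iv) / n) ** 0.5
    diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    srt = sorted(iv)
    median = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    return mean, median, sdnn, rmssd, nn50, nn50 / (n - 1)


def oracle_poincare(iv):
    iv = list(map(float, iv))
    diffs = [iv[i + 1] - iv[i] for i in range(len(iv) - 1)]
    dm = sum(diffs) / len(diffs)
    var_d = sum((d - dm) ** 2 for d in diffs) / len(diffs)
    m = sum(iv) / len(iv)
    var = sum((x - m) ** 2 for x in iv) / len(iv)
    sd1 = (0.5 * var_d) ** 0.5
    sd2 = max(2 * var - 0.5 * var_d, 0.0) ** 0.5
    return sd1, sd2


class TestTimeDomain:
    def test_hand_example_nn50(self):
        res = v.time_domain_measures(series_from([550, 610, 615, 700]))
        # successive differences 60, 5, 85 -> two exceed 50 ms
        assert res["nn50"] == 2
        assert res["pnn50"] == pytest.approx(2 / 3)

    def test_hand_example_rmssd(self):
        res = v.time_domain_measures(series_from([500, 550, 540]))
        assert res["rmssd"] == pytest.approx(np.sqrt((50**2 + 10**2) / 2), abs=1e-9)

    def test_constant_series_zero_variability(self):
        res = v.time_domain_measures(series_from([800.0] * 10))
        assert res["sdnn"] == res["rmssd"] == res["nn50"] == 0

    def test_requires_two_intervals(self):
        with pytest.raises(ConfigurationError):
            v.time_domain_measures(series_from([800.0]))

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            iv = rng.uniform(400, 1500, size=rng.integers(5, 120))
            s = series_from(iv)
            got = v.time_domain_measures(s)
            exp = oracle_time_domain(iv)
            for g, e in zip(
                [got[k] for k in ("mean_rr", "median_rr", "sdnn", "rmssd",
                                  "nn50", "pnn50")],
                exp,
            ):
                assert g == pytest.approx(e, rel=1e-9)


class TestPoincare:
    def test_alternating_series(self):
        s = series_from([800, 600] * 4)
        res = v.poincare_measures(s)
        # diffs are +/-200 with mean ~+-28.6 -> population var of diffs
        sd1, sd2 = oracle_poincare([800, 600] * 4)
        assert res["sd1"] == pytest.approx(sd1, rel=1e-9)
        assert res["sd1"] == pytest.approx(np.sqrt(0.5) * np.std(np.diff([800, 600] * 4)))

    def test_constant_series(self):
        res = v.poincare_measures(series_from([700.0] * 6))
        assert res["sd1"] == res["sd2"] == 0
        assert np.isnan(res["sd1_sd2_ratio"])

    def test_identity_and_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            iv = rng.uniform(400, 1500, size=rng.integers(5, 120))
            res = v.poincare_measures(series_from(iv))
            sdnn = v.time_domain_measures(series_from(iv))["sdnn"]
            if res["sd2"] > 0:  # identity is exact whenever SD2 is real
                assert res["sd1"] ** 2 + res["sd2"] ** 2 == pytest.approx(
                    2 * sdnn**2, rel=1e-9
                )
            sd1, sd2 = oracle_poincare(iv)
            assert res["sd1"] == pytest.approx(sd1, rel=1e-9)
            assert res["sd2"] == pytest.approx(sd2, rel=1e-9)


class TestFrequencyDomain:
    def test_pure_hf_tachogram(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.7, 0.9, size=120))
        iv = 800 + 40 * np.sin(2 * np.pi * 0.25 * t)
        res = v.frequency_domain_measures(IBISeries(iv, t))
        assert res["hf_pct"] >= 95.0

    def test_normalized_units_identity(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            s = v.synthesize_ibi(90, rng=rng)
            res = v.frequency_domain_measures(s)
            assert res["lf_nu"] + res["hf_nu"] == pytest.approx(100.0, abs=1e-9)
            assert res["vlf_pct"] + res["lf_pct"] + res["hf_pct"] <= 100.0 + 1e-9

    def test_equal_lf_hf_sinusoids(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.uniform(0.75, 0.85, size=400))
        iv = (
            800
            + 30 * np.sin(2 * np.pi * 0.1 * t)
            + 30 * np.sin(2 * np.pi * 0.25 * t)
        )
        res = v.frequency_domain_measures(IBISeries(iv, t))
        assert res["lf_hf_ratio"] == pytest.approx(1.0, abs=0.1)

    def test_bad_bands_rejected(self):
        s = v.synthesize_ibi(60, seed=0)
        with pytest.raises(ConfigurationError):
            v.frequency_domain_measures(
                s, bands={"vlf": (0.003, 0.05), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
            )


class TestPreprocessing:
    def test_highpass_removes_dc(self):
        trace = ECGTrace(np.ones(1024), 256.0)
        out = v.highpass_ecg(trace)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_highpass_passband_flat(self):
        fs = 256.0
        t = np.arange(0, 8, 1 / fs)
        trace = ECGTrace(np.sin(2 * np.pi * 20 * t), fs)
        out = v.highpass_ecg(trace)
        mid = slice(256, -256)  # ignore filter edges
        assert np.max(np.abs(out.samples[mid])) == pytest.approx(1.0, rel=0.05)

    def test_cutoff_above_nyquist(self):
        with pytest.raises(ConfigurationError):
            v.highpass_ecg(ECGTrace(np.zeros(1024), 256.0), cutoff=200.0)

    def test_flat_trace_yields_no_peaks(self):
        with pytest.warns(UserWarning):
            peaks = v.detect_r_peaks(ECGTrace(np.zeros(2048), 256.0))
        assert peaks.size == 0

    def test_refractory_suppresses_close_beat(self):
        fs = 256.0
        trace = np.zeros(int(4 * fs))
        from valphys.synthetic import _qrs_template

        tpl = _qrs_template(fs)
        half = len(tpl) // 2
        for t_s in (1.0, 1.15, 2.2):  # second deflection 150 ms after the first
            c = int(t_s * fs)
            trace[c - half : c - half + len(tpl)] += tpl
        peaks = v.detect_r_peaks(ECGTrace(trace, fs))
        assert len(peaks) == 2


class TestArtifactCorrection:
    def test_clean_series_untouched(self):
        s = series_from([800, 805, 795, 802, 799, 801])
        out = v.correct_ibi_artifacts(s)
        assert np.array_equal(out.intervals_ms, s.intervals_ms)
        assert not out.corrected_mask.any()

    def test_ectopic_drop_replaced_by_spline(self):
        s = series_from([800, 810, 400, 805, 795])
        out = v.correct_ibi_artifacts(s)
        assert list(np.flatnonzero(out.corrected_mask)) == [2]
        assert 795 < out.intervals_ms[2] < 810
        # independently fitted shape-preserving cubic through the 4 clean beats
        from scipy.interpolate import PchipInterpolator

        ref = PchipInterpolator([0, 1, 3, 4], [800, 810, 805, 795])(2)
        assert out.intervals_ms[2] == pytest.approx(float(ref), abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        iv = rng.normal(850, 30, 50)
        iv[10] = 400
        once = v.correct_ibi_artifacts(series_from(iv))
        twice = v.correct_ibi_artifacts(once)
        assert np.array_equal(once.intervals_ms, twice.intervals_ms)

    def test_too_few_intervals(self):
        with pytest.raises(ConfigurationError):
            v.correct_ibi_artifacts(series_from([800, 810, 790]))

    def test_quality_rejection(self):
        iv = [800, 810] + [400, 800] * 5  # ~half the beats artifactual
        with pytest.raises(QualityError):
            v.correct_ibi_artifacts(series_from(iv))


class TestTrialTable:
    def test_shape_and_keys(self, small_dataset):
        df = v.hrv_for_trials(small_dataset, "S01", source="ibi")
        assert len(df) == small_dataset.design.trials_per_subject
        from valphys.hrv import HRV_MEASURE_COLUMNS

        assert len(HRV_MEASURE_COLUMNS) == 19
        assert all(c in df.columns for c in HRV_MEASURE_COLUMNS)

    def test_missing_ecg_names_subject(self, small_dataset):
        with pytest.raises(QualityError, match="S01"):
            v.hrv_for_trials(small_dataset, "S01", source="ecg")
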