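"""Synthetic multimodal cohort generator.

Emulates the statistical structure of a video-stimulation valence study so
the whole analysis chain is testable without any recorded data:

* interval series — AR(1) beat-to-beat dynamics plus a respiratory-band
  (0.25 Hz) oscillation and slow LF/VLF drifts, so every HRV measure is
  nondegenerate;
* ECG — a Gaussian-derivative QRS-like wavelet rendered at each beat time,
  the simplest shape a threshold detector must handle;
* skin temperature — a mean-reverting 1 Hz walk around a subject baseline
  of 27-29 degC with occasional spike artifacts to exercise the MAD rule;
* EEG — per-window log-normal band powers with planted lateralization;
* ratings — truncated normals on [1, 9] with class means 7.51 (s.d. 1.6)
  for positive and 2.91 (s.d. 0.98) for negative stimuli, arousal 3.76
  (1.62) / 5.47 (1.35).

Planted effects (see :class:`~valphys.design.EffectModel`): extra NN50
counts on positive trials for men, extra long-term (SD2) variability on
negative trials for women, higher temperature under stimulation and on
negative trials (carried by women), and prefrontal-left / occipital-right
lateralization for positive valence with per-subject heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .design import ConfigurationError, EffectModel, StudyDesign
from .eeg import ALL_FEATURE_NAMES, ASYMMETRY_PAIRS, feature_name
from .hrv import ECGTrace, IBISeries

# --- interval-series model constants -------------------------------------
AR_COEF = 0.8
AR_SIGMA_MS = 8.0
HF_AMP_MS, HF_FREQ = 20.0, 0.25
LF_AMP_MS, LF_FREQ = 15.0, 0.08
VLF_AMP_MS, VLF_FREQ = 10.0, 0.02
SD2_SHIFT_FREQ = 0.015  # Hz, the added slow component carrying the SD2 shift
# NN50 plant: alternating +/-NN50_RUN_AMP runs of NN50_RUN_LEN intervals.
# An alternating run of any length adds only amp^2/n to SD2^2 (its variance
# lives almost entirely in the successive differences), so the planted
# short-term effect barely leaks into the long-term measure.
NN50_RUN_AMP = 30.0
NN50_RUN_LEN = 8

# --- EEG log-power model constants ---------------------------------------
BAND_BASE_LOG = {"Alpha": 2.0, "Beta1": 1.5, "Beta2": 1.0, "Gamma": 0.5}
SUBJECT_LOG_SD = 0.6
WINDOW_LOG_SD = 0.3

# --- temperature model constants ------------------------------------------
TEMP_AR = 0.995  # mean-reversion of the 1 Hz walk
TEMP_STEP_SD = 0.02  # degC per step
TEMP_SPIKE_P = 0.002
TEMP_BASE_RANGE = (27.0, 29.0)

RATING_PARAMS = {
    "positive": {"valence": (7.51, 1.6), "arousal": (3.76, 1.62)},
    "negative": {"valence": (2.91, 0.98), "arousal": (5.47, 1.35)},
}


def nominal_diff_sd(base_rr_ms: float = 857.0) -> float:
    """Closed-form s.d. of successive interval differences of the base model."""
    t = base_rr_ms / 1000.0
    var_diff = 2 * (AR_SIGMA_MS**2 / (1 - AR_COEF**2)) * (1 - AR_COEF)
    for amp, freq in ((HF_AMP_MS, HF_FREQ), (LF_AMP_MS, LF_FREQ), (VLF_AMP_MS, VLF_FREQ)):
        var_diff += amp**2 * (1 - np.cos(2 * np.pi * freq * t))
    return float(np.sqrt(var_diff))


def nn50_per_run(base_rr_ms: float = 857.0) -> float:
    """Expected NN50 counts added by one alternating run, used to set the
    Poisson rate so the planted shift is realized in expectation."""
    sd = nominal_diff_sd(base_rr_ms)
    a = NN50_RUN_AMP

    def p_exceed(offset: float) -> float:
        return float(
            sps.norm.sf((50.0 - offset) / sd) + sps.norm.cdf((-50.0 - offset) / sd)
        )

    base = p_exceed(0.0)
    interior = (NN50_RUN_LEN - 1) * (p_exceed(2 * a) - base)
    edges = 2 * (p_exceed(a) - base)
    return interior + edges


def nominal_sd2(base_rr_ms: float = 857.0) -> float:
    """Closed-form long-term Poincare spread of the base interval model.

    Used to convert a requested SD2 shift (ms) into the amplitude of the
    added slow component.
    """
    t = base_rr_ms / 1000.0
    var_ar = AR_SIGMA_MS**2 / (1 - AR_COEF**2)
    var_components = var_ar + HF_AMP_MS**2 / 2 + LF_AMP_MS**2 / 2 + VLF_AMP_MS**2 / 2
    var_diff = 2 * var_ar * (1 - AR_COEF)
    for amp, freq in ((HF_AMP_MS, HF_FREQ), (LF_AMP_MS, LF_FREQ), (VLF_AMP_MS, VLF_FREQ)):
        var_diff += amp**2 * (1 - np.cos(2 * np.pi * freq * t))
    return float(np.sqrt(2 * var_components - 0.5 * var_diff))


def synthesize_ibi(
    n: int,
    base_rr: float = 857.0,
    effects: EffectModel | None = None,
    gender: str = "M",
    condition: str = "baseline",
    multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> IBISeries:
    """Autocorrelated inter-beat interval series with planted shifts.

    The base model is AR(1) (coefficient 0.8, innovation s.d. 8 ms) plus
    sinusoids in the HF (0.25 Hz), LF (0.08 Hz) and VLF (0.02 Hz) bands with
    random phases.  Group flags select the planted effects: men's positive
    trials receive Poisson-distributed alternating +/-30 ms runs that raise
    the expected NN50 count by ``nn50_male_shift`` while barely touching
    SD2; women's negative trials receive a slow 0.015 Hz component raising
    SD2 by ``sd2_female_shift`` ms in expectation.  ``multiplier`` scales
    both (per-subject heterogeneity).
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = EffectModel.null() if effects is None else effects
    t = np.arange(n) * base_rr / 1000.0
    ar = np.empty(n)
    ar[0] = rng.normal(0, AR_SIGMA_MS / np.sqrt(1 - AR_COEF**2))
    innov = rng.normal(0, AR_SIGMA_MS, size=n)
    for k in range(1, n):
        ar[k] = AR_COEF * ar[k - 1] + innov[k]
    iv = base_rr + ar
    for amp, freq in ((HF_AMP_MS, HF_FREQ), (LF_AMP_MS, LF_FREQ), (VLF_AMP_MS, VLF_FREQ)):
        iv = iv + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    scale = max(multiplier, 0.0)
    if gender == "M" and condition == "positive" and effects.nn50_male_shift > 0:
        run = min(NN50_RUN_LEN, max(n - 2, 2))
        k = rng.poisson(scale * effects.nn50_male_shift / nn50_per_run(base_rr))
        if k > 0 and n > run + 2:
            # non-overlapping run start positions
            slots = np.arange(1, n - run - 1, run + 2)
            starts = rng.choice(slots, size=min(k, len(slots)), replace=False)
            for s in starts:
                signs = np.resize([1.0, -1.0], run) * rng.choice([-1.0, 1.0])
                iv[s : s + run] += signs * NN50_RUN_AMP
    if gender == "F" and condition == "negative" and effects.sd2_female_shift > 0:
        s0 = nominal_sd2(base_rr)
        target = s0 + scale * effects.sd2_female_shift
        amp = np.sqrt(max(target**2 - s0**2, 0.0))
        iv = iv + amp * np.sin(2 * np.pi * SD2_SHIFT_FREQ * t + rng.uniform(0, 2 * np.pi))
    iv = np.clip(iv, 310.0, 1990.0)
    onsets = np.cumsum(iv) / 1000.0
    return IBISeries(iv, onsets)


def _qrs_template(fs: float, width_s: float = 0.08) -> np.ndarray:
    """Gaussian-derivative QRS-like wavelet of ~80 ms total width."""
    sigma = width_s / 6.0
    t = np.arange(-width_s / 2, width_s / 2, 1.0 / fs)
    w = -t / sigma * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.max(np.abs(w))


def render_ecg(beat_times_s: np.ndarray, fs: float, duration_s: float) -> np.ndarray:
    """Render a QRS wavelet at each beat time (snapped to the sample grid)."""
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    template = _qrs_template(fs)
    half = len(template) // 2
    for t_b in beat_times_s:
        center = int(round(t_b * fs))
        lo, hi = center - half, center - half + len(template)
        if lo < 0 or hi > n:
            continue
        trace[lo:hi] += template
    return trace


def synthesize_ecg(rr_intervals_ms, fs: float) -> ECGTrace:
    """An ECG trace with one QRS-like deflection per interval.

    Beats sit at the cumulative interval times (plus a 0.5 s lead-in);
    applying the R-peak detector to the output recovers the intervals to
    within one sample.
    """
    rr = np.asarray(rr_intervals_ms, dtype=float)
    if rr.size == 0:
        raise ConfigurationError("interval list must not be empty")
    if np.any((rr < 300.0) | (rr > 2000.0)):
        raise ConfigurationError("intervals must lie in [300, 2000] ms")
    beat_times = 0.5 + np.concatenate([[0.0], np.cumsum(rr)]) / 1000.0
    duration = beat_times[-1] + 0.5
    return ECGTrace(render_ecg(beat_times, fs, duration), fs)


# ---------------------------------------------------------------------------
# cohort containers


@dataclass(frozen=True)
class SubjectRecord:
    """All modalities and annotations of one simulated subject."""

    subject_id: str
    gender: str  # 'M' | 'F'
    trials: pd.DataFrame  # trial_id, label, onset_s, duration_s, offset_s, ratings
    baselines: pd.DataFrame  # baseline_id, onset_s, duration_s
    ecg: ECGTrace | None
    temp: np.ndarray | None
    temp_fs: float
    ibi: dict[int, IBISeries] | None
    eeg_features: pd.DataFrame | None
    eeg_raw: tuple | None = None  # (array, fs, channel names) for tiny fixtures
    effect_multiplier: float = 1.0
    eeg_sign: int = 1

    @property
    def session_duration_s(self) -> float:
        return float(self.trials["offset_s"].max() + 2.0)


@dataclass(frozen=True)
class MultimodalDataset:
    """The hand-off object between every analysis stage."""

    design: StudyDesign
    effects: EffectModel
    subjects: tuple[SubjectRecord, ...]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"unknown subject {subject_id!r}")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def trials_table(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = s.trials.copy()
            df.insert(0, "subject", s.subject_id)
            df.insert(1, "gender", s.gender)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@lru_cache(maxsize=None)
def _truncnorm_loc(mean: float, sd: float, lo: float = 1.0, hi: float = 9.0) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Rating scales clip at their endpoints, so the reported class mean is the
    mean *after* truncation; the underlying location is solved for.
    """

    def truncated_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return sps.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return float(brentq(truncated_mean, lo, hi + 5 * sd))


def _truncnorm(rng, mean, sd, lo=1.0, hi=9.0, size=None):
    loc = _truncnorm_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _eeg_shift(pair_region: str, band: str, label: str) -> float:
    """Signed unit shift of the (left - right) log-power difference.

    Positive valence lateralizes prefrontally to the left (left power up,
    right power down) and occipitally to the right; negative valence
    reverses both.  Central and parietal pairs carry no planted effect.
    """
    valence = 1.0 if label == "positive" else -1.0
    if pair_region == "PF":
        return valence  # +1: left > right on positive trials
    if pair_region == "O":
        return -valence
    return 0.0


def generate_dataset(
    design: StudyDesign | None = None,
    effects: EffectModel | None = None,
    include_ecg: bool = True,
    drop_ecg_subjects: tuple[str, ...] = (),
    drop_temp_subjects: tuple[str, ...] = (),
) -> MultimodalDataset:
    """Generate the full multi-subject multimodal dataset.

    Deterministic: identical design + effects (including the seed) give a
    bit-identical dataset.  ``include_ecg=False`` skips rendering the ECG
    traces (the ground-truth interval series are still attached), which is
    useful for statistical simulations that start from intervals.
    ``drop_*_subjects`` deliberately removes a modality from named subjects
    to emulate recording failures.
    """
    design = StudyDesign() if design is None else design
    effects = EffectModel() if effects is None else effects
    master = np.random.SeedSequence(effects.seed)
    subject_seeds = master.spawn(design.n_subjects)
    base_rr = 857.0
    subjects = []
    for j in range(design.n_subjects):
        rng = np.random.default_rng(subject_seeds[j])
        subject_id = f"S{j + 1:02d}"
        gender = "M" if j < design.n_men else "F"
        mult = 1.0 + effects.subject_heterogeneity * rng.standard_normal()
        sign = int(rng.choice([-1, 1])) if effects.eeg_random_signs else 1

        labels = np.array(["positive"] * (design.trials_per_subject // 2)
                          + ["negative"] * (design.trials_per_subject // 2))
        rng.shuffle(labels)
        durations = rng.uniform(*design.trial_duration_s, size=design.trials_per_subject)

        # timeline: [baseline, trial] x n_trials
        trial_rows, baseline_rows = [], []
        t_cursor = 0.0
        for i, (label, dur) in enumerate(zip(labels, durations), start=1):
            baseline_rows.append(
                {"baseline_id": i, "onset_s": t_cursor,
                 "duration_s": design.baseline_duration_s}
            )
            t_cursor += design.baseline_duration_s
            vm, vs = RATING_PARAMS[label]["valence"]
            am, asd = RATING_PARAMS[label]["arousal"]
            trial_rows.append(
                {
                    "trial_id": i,
                    "label": label,
                    "onset_s": t_cursor,
                    "duration_s": dur,
                    "offset_s": t_cursor + dur,
                    "valence_rating": float(_truncnorm(rng, vm, vs)),
                    "arousal_rating": float(_truncnorm(rng, am, asd)),
                }
            )
            t_cursor += dur
        trials = pd.DataFrame(trial_rows)
        baselines = pd.DataFrame(baseline_rows)
        session_end = t_cursor + design.baseline_duration_s

        # --- intervals + ECG ---
        ibi: dict[int, IBISeries] = {}
        beat_times = []
        for row in trials.itertuples():
            n_beats = int(np.ceil(row.duration_s * 1000.0 / base_rr)) + 2
            series = synthesize_ibi(
                n_beats, base_rr, effects, gender, row.label, mult, rng=rng
            )
            ibi[row.trial_id] = series
            times = row.onset_s + 0.2 + np.concatenate(
                [[0.0], series.onset_times_s]
            )
            beat_times.append(times[times < row.offset_s - 0.05])
        for row in baselines.itertuples():
            n_beats = int(np.ceil(row.duration_s * 1000.0 / base_rr)) + 2
            series = synthesize_ibi(n_beats, base_rr, rng=rng)
            times = row.onset_s + 0.2 + np.concatenate([[0.0], series.onset_times_s])
            end = row.onset_s + row.duration_s - 0.05
            beat_times.append(times[times < end])
        ecg = None
        if include_ecg and subject_id not in drop_ecg_subjects:
            trace = render_ecg(
                np.concatenate(beat_times), design.ecg_fs, session_end
            )
            ecg = ECGTrace(trace, design.ecg_fs)

        # --- temperature ---
        temp = None
        if subject_id not in drop_temp_subjects:
            n_temp = int(round(session_end * design.temp_fs))
            base = rng.uniform(*TEMP_BASE_RANGE)
            walk = np.empty(n_temp)
            walk[0] = base
            steps = rng.normal(0, TEMP_STEP_SD, size=n_temp)
            for k in range(1, n_temp):
                walk[k] = base + TEMP_AR * (walk[k - 1] - base) + steps[k]
            shift = np.zeros(n_temp)
            tgrid = np.arange(n_temp) / design.temp_fs
            for row in trials.itertuples():
                in_trial = (tgrid >= row.onset_s) & (tgrid < row.offset_s)
                delta = effects.temp_task_shift
                if gender == "F" and row.label == "negative":
                    delta += max(mult, 0.0) * effects.temp_neg_shift
                shift[in_trial] += delta
            spikes = rng.random(n_temp) < TEMP_SPIKE_P
            spike_amp = rng.uniform(4.0, 8.0, size=n_temp) * rng.choice(
                [-1.0, 1.0], size=n_temp
            )
            temp = walk + shift + np.where(spikes, spike_amp, 0.0)

        # --- EEG band-power features ---
        subj_intercepts = {
            name: SUBJECT_LOG_SD * rng.standard_normal() for name in ALL_FEATURE_NAMES
        }
        if design.eeg_window_mode == "sliding":
            step = design.eeg_window_s / 2.0
            starts = np.arange(
                0.0, design.analysis_window_s - design.eeg_window_s + 1e-9, step
            )
        else:
            starts = np.array([0.0])
        lateral = {}  # feature name -> (pair region, hemisphere sign)
        for pair, (left_r, right_r, band) in ASYMMETRY_PAIRS.items():
            region = pair.split("-")[0]
            lateral[feature_name(left_r, band)] = (region, +1)
            lateral[feature_name(right_r, band)] = (region, -1)
        feat_rows = []
        for row in trials.itertuples():
            for w, _start in enumerate(starts):
                entry = {"trial_id": row.trial_id, "window_id": w}
                for name in ALL_FEATURE_NAMES:
                    band = name.split(":")[1]
                    logp = (
                        BAND_BASE_LOG[band]
                        + subj_intercepts[name]
                        + WINDOW_LOG_SD * rng.standard_normal()
                    )
                    if name in lateral and effects.eeg_asym_shift > 0:
                        region, hemi = lateral[name]
                        logp += (
                            0.5
                            * hemi
                            * _eeg_shift(region, band, row.label)
                            * effects.eeg_asym_shift
                            * mult
                            * sign
                        )
                    entry[name] = float(np.exp(logp))
                feat_rows.append(entry)
        eeg_features = pd.DataFrame(feat_rows)

        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                gender=gender,
                trials=trials,
                baselines=baselines,
                ecg=ecg,
                temp=temp,
                temp_fs=design.temp_fs,
                ibi=ibi,
                eeg_features=eeg_features,
                effect_multiplier=mult,
                eeg_sign=sign,
            )
        )
    return MultimodalDataset(design=design, effects=effects, subjects=tuple(subjects))


def temperature_annotations(subject: SubjectRecord) -> pd.DataFrame:
    """Segmentation table (trial_id, condition, onset_s) covering stimulus
    trials and baseline periods of one subject."""
    rows = [
        {"trial_id": r.trial_id, "condition": r.label, "onset_s": r.onset_s}
        for r in subject.trials.itertuples()
    ]
    rows += [
        {"trial_id": -r.baseline_id, "condition": "baseline", "onset_s": r.onset_s}
        for r in subject.baselines.itertuples()
    ]
    return pd.DataFrame(rows)
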