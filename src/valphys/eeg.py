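"""EEG band-power features and interhemispheric asymmetry analysis.

The feature set is the 20 frequency-location band powers used for valence
classification — Alpha/Beta1/Beta2/Gamma at prefrontal left and right,
Beta1/Gamma at frontal midline, Alpha/Beta1 at central midline, Beta1/Beta2
at parieto-occipital midline, Gamma at central left/right and parietal
right, and Beta1/Beta2/Gamma at occipital right — plus the four homologous
left-side powers needed to complete the 9 lateral pairs.

Asymmetry is quantified with the classical index
``AI = (right - left) / (right + left)`` on band spectral power over
homologous regions; midline features never enter asymmetry pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .design import ConfigurationError
from .stats import mann_whitney

#: Conventional band edges (Hz), consistent with the 45 Hz low-pass.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "Alpha": (8.0, 12.0),
    "Beta1": (12.0, 20.0),
    "Beta2": (20.0, 30.0),
    "Gamma": (30.0, 45.0),
}

#: Standard 10/10-system electrode labels (subset sufficient for validation).
TEN_TEN_LABELS = frozenset(
    """
    Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8
    F7 F5 F3 F1 Fz F2 F4 F6 F8
    FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8
    T7 C5 C3 C1 Cz C2 C4 C6 T8
    TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8
    P7 P5 P3 P1 Pz P2 P4 P6 P8
    PO7 PO3 POz PO4 PO8 O1 Oz O2
    """.split()
)

#: Region -> electrode sets in the 10/10 system.  The mapping is a package
#: default (standard neighborhoods) and fully configurable.
DEFAULT_REGION_MAP: dict[str, tuple[str, ...]] = {
    "PF-left": ("Fp1", "AF3", "AF7"),
    "PF-right": ("Fp2", "AF4", "AF8"),
    "Fm": ("Fz", "AFz"),
    "Cm": ("Cz", "FCz"),
    "C-left": ("C3", "C5"),
    "C-right": ("C4", "C6"),
    "P-left": ("P3", "P5"),
    "P-right": ("P4", "P6"),
    "POm": ("POz", "Pz"),
    "O-left": ("O1", "PO3"),
    "O-right": ("O2", "PO4"),
}

#: The 20 primary frequency-location features, as (region, band) pairs.
PRIMARY_FEATURES: tuple[tuple[str, str], ...] = (
    ("PF-left", "Alpha"),
    ("PF-left", "Beta1"),
    ("PF-left", "Beta2"),
    ("PF-left", "Gamma"),
    ("PF-right", "Alpha"),
    ("PF-right", "Beta1"),
    ("PF-right", "Beta2"),
    ("PF-right", "Gamma"),
    ("Fm", "Beta1"),
    ("Fm", "Gamma"),
    ("Cm", "Alpha"),
    ("Cm", "Beta1"),
    ("POm", "Beta1"),
    ("POm", "Beta2"),
    ("C-left", "Gamma"),
    ("C-right", "Gamma"),
    ("P-right", "Gamma"),
    ("O-right", "Beta1"),
    ("O-right", "Beta2"),
    ("O-right", "Gamma"),
)

#: Homologous left-hemisphere powers needed to complete the asymmetry pairs.
AUXILIARY_FEATURES: tuple[tuple[str, str], ...] = (
    ("P-left", "Gamma"),
    ("O-left", "Beta1"),
    ("O-left", "Beta2"),
    ("O-left", "Gamma"),
)

#: The 9 lateral frequency-location pairs evaluated for asymmetry
#: (midline regions excluded by construction).
ASYMMETRY_PAIRS: dict[str, tuple[str, str, str]] = {
    "PF-Alpha": ("PF-left", "PF-right", "Alpha"),
    "PF-Beta1": ("PF-left", "PF-right", "Beta1"),
    "PF-Beta2": ("PF-left", "PF-right", "Beta2"),
    "PF-Gamma": ("PF-left", "PF-right", "Gamma"),
    "C-Gamma": ("C-left", "C-right", "Gamma"),
    "P-Gamma": ("P-left", "P-right", "Gamma"),
    "O-Beta1": ("O-left", "O-right", "Beta1"),
    "O-Beta2": ("O-left", "O-right", "Beta2"),
    "O-Gamma": ("O-left", "O-right", "Gamma"),
}


def feature_name(region: str, band: str) -> str:
    return f"{region}:{band}"


PRIMARY_FEATURE_NAMES: list[str] = [feature_name(r, b) for r, b in PRIMARY_FEATURES]
AUXILIARY_FEATURE_NAMES: list[str] = [feature_name(r, b) for r, b in AUXILIARY_FEATURES]
ALL_FEATURE_NAMES: list[str] = PRIMARY_FEATURE_NAMES + AUXILIARY_FEATURE_NAMES


def validate_region_map(regions: dict[str, tuple[str, ...]]) -> None:
    """Check labels are valid 10/10 names and region pairs are disjoint."""
    for region, electrodes in regions.items():
        for e in electrodes:
            if e not in TEN_TEN_LABELS:
                raise ConfigurationError(
                    f"region {region!r}: {e!r} is not a 10/10 electrode label"
                )
    for left_r, right_r, _band in ASYMMETRY_PAIRS.values():
        if left_r in regions and right_r in regions:
            overlap = set(regions[left_r]) & set(regions[right_r])
            if overlap:
                raise ConfigurationError(
                    f"regions {left_r!r} and {right_r!r} share electrodes {overlap}"
                )


def preprocess_eeg(
    data: np.ndarray,
    fs: float,
    l_freq: float = 0.5,
    h_freq: float = 45.0,
    artifact_hook=None,
) -> np.ndarray:
    """Band-pass filter (0.5-45 Hz) and Common Average Reference.

    ``data`` is (n_channels, n_samples).  ``artifact_hook``, when given, is
    called with the filtered array before re-referencing and must return an
    array of the same shape — the attachment point for ICA-style artifact
    removal, intentionally left empty here.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ConfigurationError("EEG must be 2-D with at least 2 channels")
    if fs <= 2 * h_freq:
        raise ConfigurationError(f"fs must exceed {2 * h_freq} Hz")
    sos = signal.butter(4, [l_freq, h_freq], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    if artifact_hook is not None:
        filtered = np.asarray(artifact_hook(filtered), dtype=float)
        if filtered.shape != data.shape:
            raise ConfigurationError("artifact_hook must preserve the array shape")
    return filtered - filtered.mean(axis=0, keepdims=True)


def band_power(
    window: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Welch band power of an EEG window, averaged over channels.

    Returns the spectral power integrated over ``band`` (uV^2/Hz aggregated
    across the band); always non-negative.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ConfigurationError(f"band {band} must lie inside (0, {fs / 2}) Hz")
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n = window.shape[1]
    if n < 2 * fs / lo:
        raise ConfigurationError(
            f"window must span >= 2 cycles of the band lower edge ({lo} Hz)"
        )
    nperseg = min(n, int(round(2 * fs)))
    freqs, psd = signal.welch(window, fs=fs, nperseg=nperseg, axis=1)
    psd_mean = psd.mean(axis=0)
    sel = (freqs >= lo) & (freqs < hi)
    return float(np.trapezoid(psd_mean[sel], freqs[sel]))


def extract_feature_vectors(
    dataset,
    regions: dict[str, tuple[str, ...]] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """The band-power feature table: one row per subject x trial x window.

    When the dataset carries precomputed band-power features (the default
    for the synthetic cohort), they are validated and passed through.  When
    a subject instead carries raw EEG, powers are computed with
    :func:`band_power` per region and band over each trial window.
    """
    regions = DEFAULT_REGION_MAP if regions is None else regions
    bands = DEFAULT_BANDS if bands is None else bands
    validate_region_map(regions)
    for region, _band in PRIMARY_FEATURES + AUXILIARY_FEATURES:
        if region not in regions:
            raise ConfigurationError(f"region map is missing region {region!r}")
    frames = []
    for subject in dataset.subjects:
        if subject.eeg_features is not None:
            df = subject.eeg_features.copy()
            missing = [c for c in ALL_FEATURE_NAMES if c not in df.columns]
            if missing:
                raise ConfigurationError(
                    f"subject {subject.subject_id}: missing feature columns {missing}"
                )
            if (df[ALL_FEATURE_NAMES].to_numpy() < 0).any():
                raise ConfigurationError(
                    f"subject {subject.subject_id}: negative band powers"
                )
        elif subject.eeg_raw is not None:
            df = _features_from_raw(subject, dataset.design, regions, bands)
        else:
            raise ConfigurationError(f"subject {subject.subject_id} has no EEG data")
        df.insert(0, "subject", subject.subject_id)
        df.insert(1, "gender", subject.gender)
        labels = subject.trials.set_index("trial_id")
        df["label"] = df["trial_id"].map(labels["label"])
        df["valence_rating"] = df["trial_id"].map(labels["valence_rating"])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _features_from_raw(subject, design, regions, bands) -> pd.DataFrame:
    """Compute band powers from a raw multichannel recording (small inputs)."""
    raw, fs, channels = subject.eeg_raw
    processed = preprocess_eeg(raw, fs)
    ch_index = {name: i for i, name in enumerate(channels)}
    for region, electrodes in regions.items():
        missing = [e for e in electrodes if e not in ch_index]
        if missing:
            raise ConfigurationError(
                f"region {region!r}: electrodes {missing} absent from recording"
            )
    rows = []
    win = design.analysis_window_s
    for trial in subject.trials.itertuples():
        start = int(round(trial.onset_s * fs))
        stop = int(round((trial.onset_s + win) * fs))
        rows.append(
            {
                "trial_id": trial.trial_id,
                "window_id": 0,
                **{
                    feature_name(region, band): band_power(
                        processed[[ch_index[e] for e in regions[region]], start:stop],
                        fs,
                        bands[band],
                    )
                    for region, band in PRIMARY_FEATURES + AUXILIARY_FEATURES
                },
            }
        )
    return pd.DataFrame(rows)


def asymmetry_index(right, left):
    """Classical asymmetry index ``(right - left) / (right + left)``.

    Vectorized; a zero power sum yields a missing value.  The index is
    antisymmetric in its arguments, invariant to common positive scaling,
    and bounded in [-1, 1] whenever both powers are non-negative.
    """
    right = np.asarray(right, dtype=float)
    left = np.asarray(left, dtype=float)
    total = right + left
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(total > 0, (right - left) / np.where(total > 0, total, 1.0), np.nan)
    if ai.ndim == 0:
        return float(ai)
    return ai


def asymmetry_analysis(
    features: pd.DataFrame,
    mode: str = "SI",
) -> pd.DataFrame:
    """Mann-Whitney statistics for the 9 homologous frequency-location pairs.

    For each pair three comparisons are reported: the asymmetry index
    between positive and negative trials, and the raw left-vs-right powers
    within each emotional condition.  ``mode='SI'`` pools all subjects;
    ``mode='SD'`` tests each subject separately.  Lateralization direction
    is the sign of the median difference (positive = rightward).
    """
    for cond in ("positive", "negative"):
        if not (features["label"] == cond).any():
            raise ConfigurationError(f"no {cond} trials present")
    groups = (
        [("all", features)]
        if mode == "SI"
        else [(s, g) for s, g in features.groupby("subject", sort=True)]
    )
    rows = []
    for unit, df in groups:
        pos = df[df["label"] == "positive"]
        neg = df[df["label"] == "negative"]
        for pair, (left_r, right_r, band) in ASYMMETRY_PAIRS.items():
            lcol, rcol = feature_name(left_r, band), feature_name(right_r, band)
            ai_pos = asymmetry_index(pos[rcol], pos[lcol])
            ai_neg = asymmetry_index(neg[rcol], neg[lcol])
            res = mann_whitney(ai_pos, ai_neg)
            rows.append(
                {
                    "unit": unit,
                    "pair": pair,
                    "comparison": "ai_positive_vs_negative",
                    "statistic": res.statistic,
                    "p": res.p,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "direction": res.direction,
                }
            )
            for cond, sub in (("positive", pos), ("negative", neg)):
                res = mann_whitney(sub[rcol], sub[lcol])
                rows.append(
                    {
                        "unit": unit,
                        "pair": pair,
                        "comparison": f"power_right_vs_left_{cond}",
                        "statistic": res.statistic,
                        "p": res.p,
                        "n_a": res.n_a,
                        "n_b": res.n_b,
                        "direction": res.direction,
                    }
                )
    return pd.DataFrame(rows)
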