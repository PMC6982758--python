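"""Study design and planted-effect parameters for the synthetic cohort.

The defaults mirror a video-stimulation valence study: 24 subjects
(16 men, 8 women), 14 clips per subject (7 positive, 7 negative,
43-78 s each) interleaved with 30 s baselines, ECG at 256 Hz, wrist
skin temperature at 1 Hz, and EEG band-power features per trial window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a design or effect parameter is invalid; names the field."""


class QualityError(RuntimeError):
    """Raised when a trial or segment fails a data-quality rule."""


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and recording layout of a simulated session."""

    n_subjects: int = 24
    n_men: int = 16
    trials_per_subject: int = 14
    trial_duration_s: tuple[float, float] = (43.0, 78.0)
    baseline_duration_s: float = 30.0
    ecg_fs: float = 256.0
    temp_fs: float = 1.0
    eeg_fs: float = 1000.0
    #: 'trial' = one 28 s window per clip; 'sliding' = 4 s windows, 50% overlap
    eeg_window_mode: str = "sliding"
    eeg_window_s: float = 4.0
    analysis_window_s: float = 28.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (0 <= self.n_men <= self.n_subjects):
            raise ConfigurationError("n_men must satisfy 0 <= n_men <= n_subjects")
        if self.trials_per_subject < 2 or self.trials_per_subject % 2:
            raise ConfigurationError("trials_per_subject must be even and >= 2")
        lo, hi = self.trial_duration_s
        if lo <= 0 or hi < lo:
            raise ConfigurationError("trial_duration_s must be a positive (lo, hi) range")
        if self.baseline_duration_s <= 0:
            raise ConfigurationError("baseline_duration_s must be > 0")
        for name in ("ecg_fs", "temp_fs", "eeg_fs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.eeg_window_mode not in ("trial", "sliding"):
            raise ConfigurationError("eeg_window_mode must be 'trial' or 'sliding'")

    @property
    def n_women(self) -> int:
        return self.n_subjects - self.n_men

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EffectModel:
    """Magnitudes of the valence effects planted in the synthetic signals.

    nn50_male_shift
        Expected extra count of >50 ms successive-interval differences per
        positive trial, men only.
    sd2_female_shift
        Milliseconds added to the long-term Poincare spread (SD2) on
        negative trials, women only.
    temp_neg_shift
        Degrees C added to skin temperature on negative trials, carried by
        women.
    temp_task_shift
        Degrees C added to skin temperature during any stimulus relative to
        baseline, both genders.
    eeg_asym_shift
        Log-power asymmetry magnitude: prefrontal left-lateralization for
        positive valence (right for negative), reversed occipitally.
    subject_heterogeneity
        Standard deviation of the per-subject multiplier Normal(1, h)
        applied to every planted effect.
    eeg_random_signs
        When True, each subject's EEG effect direction gets an independent
        random sign, emulating strong inter-subject brain variability.
    """

    nn50_male_shift: float = 10.0
    sd2_female_shift: float = 20.0
    temp_neg_shift: float = 0.4
    temp_task_shift: float = 1.7
    eeg_asym_shift: float = 0.6
    subject_heterogeneity: float = 0.3
    eeg_random_signs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nn50_male_shift",
            "sd2_female_shift",
            "temp_neg_shift",
            "temp_task_shift",
            "eeg_asym_shift",
            "subject_heterogeneity",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def null(cls, seed: int = 0) -> "EffectModel":
        """All planted shifts zero: the no-effect control condition."""
        return cls(
            nn50_male_shift=0.0,
            sd2_female_shift=0.0,
            temp_neg_shift=0.0,
            temp_task_shift=0.0,
            eeg_asym_shift=0.0,
            subject_heterogeneity=0.0,
            eeg_random_signs=False,
            seed=seed,
        )
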