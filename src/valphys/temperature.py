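"""Wrist skin-temperature segmentation, outlier cleaning and statistics.

Temperature is segmented into 28 s trials aligned to each video clip (the
first 28 s after onset) and to each baseline period.  Within a segment,
samples more than three scaled median absolute deviations (1.4826 * MAD)
from the segment median are treated as sensor artifacts and replaced by
the mean of the retained samples.  Group comparisons use per-trial mean
temperature as the observation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ConfigurationError, QualityError
from .stats import mann_whitney

#: consistency constant making MAD estimate the s.d. under normality
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class TempTrial:
    """One 28 s temperature segment with its condition and subject keys."""

    samples: np.ndarray
    condition: str  # positive | negative | baseline
    subject_id: str
    gender: str
    trial_id: int
    cleaned: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.condition not in ("positive", "negative", "baseline"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))


def segment_temperature(
    trace: np.ndarray,
    fs: float,
    annotations: pd.DataFrame,
    subject_id: str,
    gender: str,
    segment_s: float = 28.0,
    offset_s: float = 0.0,
) -> list[TempTrial]:
    """Cut one ``segment_s`` window per annotated trial and baseline.

    ``annotations`` needs columns trial_id, condition and onset_s; windows
    are half-open ``[onset + offset, onset + offset + segment_s)``.  A
    window extending past the end of the trace is an error naming the
    trial.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    out = []
    for row in annotations.itertuples():
        start = int(round((row.onset_s + offset_s) * fs))
        stop = start + int(round(segment_s * fs))
        if start < 0 or stop > n:
            raise ConfigurationError(
                f"trial {row.trial_id}: window [{start}, {stop}) outside trace "
                f"of {n} samples"
            )
        out.append(
            TempTrial(
                samples=trace[start:stop],
                condition=row.condition,
                subject_id=subject_id,
                gender=gender,
                trial_id=row.trial_id,
            )
        )
    return out


def clean_outliers(trial: TempTrial, n_mads: float = 3.0) -> TempTrial:
    """Replace samples beyond ``n_mads`` scaled MADs from the median.

    Replacement value is the mean of the non-outlier samples of the same
    segment (using the all-sample mean would reinject the artifact).  When
    the MAD is zero (more than half the samples equal the median) the
    threshold degenerates to zero and any sample strictly different from
    the median is flagged — a constant segment is therefore untouched.  A
    segment where every sample would be flagged is rejected as degenerate.
    The operation is idempotent.
    """
    if trial.cleaned:  # cleaning is applied once per segment; the flag records it
        return trial
    x = trial.samples
    if len(x) < 3:
        raise ConfigurationError("outlier cleaning requires >= 3 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    outlier = np.abs(x - med) > n_mads * MAD_SCALE * mad
    if outlier.all():
        raise QualityError("degenerate segment: every sample flagged as outlier")
    if not outlier.any():
        return replace(trial, cleaned=True)
    cleaned = x.copy()
    cleaned[outlier] = x[~outlier].mean()
    return replace(trial, samples=cleaned, cleaned=True)


def trials_table(trials: list[TempTrial]) -> pd.DataFrame:
    """Tidy per-segment table with the mean temperature of each segment."""
    return pd.DataFrame(
        {
            "subject": t.subject_id,
            "gender": t.gender,
            "trial_id": t.trial_id,
            "condition": t.condition,
            "mean_temp": t.mean,
            "cleaned": t.cleaned,
        }
        for t in trials
    )


_COMPARISONS = [
    ("positive", "negative"),
    ("positive", "baseline"),
    ("negative", "baseline"),
]


def temperature_statistics(
    trials: list[TempTrial],
    mode: str = "SI",
    gender: str | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparisons of condition means plus group summaries.

    Tests positive-vs-negative, positive-vs-baseline and negative-vs-
    baseline on per-segment mean temperatures, pooled over subjects
    (``mode='SI'``) or within each subject (``mode='SD'``); ``gender``
    restricts the sample to one gender.  Each row carries the two group
    means and standard deviations alongside the test result.
    """
    df = trials_table(trials)
    if gender is not None:
        df = df[df["gender"] == gender]
    groups = (
        [("all", df)]
        if mode == "SI"
        else [(s, g) for s, g in df.groupby("subject", sort=True)]
    )
    rows = []
    for unit, sub in groups:
        by_cond = {c: g["mean_temp"].to_numpy() for c, g in sub.groupby("condition")}
        for cond_a, cond_b in _COMPARISONS:
            a = by_cond.get(cond_a, np.array([]))
            b = by_cond.get(cond_b, np.array([]))
            if len(a) == 0 or len(b) == 0:
                raise ConfigurationError(
                    f"empty group for comparison {cond_a} vs {cond_b} (unit {unit})"
                )
            res = mann_whitney(a, b)
            rows.append(
                {
                    "unit": unit,
                    "comparison": f"{cond_a}_vs_{cond_b}",
                    "statistic": res.statistic,
                    "p": res.p,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "direction": res.direction,
                    f"mean_a": float(a.mean()),
                    f"sd_a": float(a.std(ddof=1)) if len(a) > 1 else np.nan,
                    f"mean_b": float(b.mean()),
                    f"sd_b": float(b.std(ddof=1)) if len(b) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
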