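"""Nonparametric statistics shared by all modalities.

Rank-based tests throughout: physiological features on short emotional
trials are not normally distributed (checked with a one-sample KS test),
so group comparisons use the Mann-Whitney U test and feature-rating
association uses Spearman rank correlation.  p-values are reported raw;
a Benjamini-Hochberg adjustment helper is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ConfigurationError


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p: float
    n_a: int
    n_b: int
    #: sign of median(a) - median(b); 0 when medians tie
    direction: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ConfigurationError("p must lie in [0, 1]")


def mann_whitney(a, b, alternative: str = "two-sided") -> StatResult:
    """Mann-Whitney U test of two independent samples.

    Uses the exact null distribution when both groups have at most 8
    observations and the pooled sample is tie-free, and the tie-corrected
    normal approximation (with continuity correction) otherwise.  The
    reported U is the statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    direction = float(np.median(a) - np.median(b))
    return StatResult(
        test=f"mann-whitney-{method}",
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
        direction=int(np.sign(direction)),
    )


def ks_normality(sample) -> StatResult:
    """One-sample Kolmogorov-Smirnov test against a normal reference.

    The sample is standardized with its own mean and standard deviation and
    compared with the standard normal CDF.
    """
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ConfigurationError("KS normality test requires n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("sample is constant; normality test undefined")
    z = (x - x.mean()) / sd
    res = sps.kstest(z, "norm")
    return StatResult(
        test="ks-normality",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n_a=len(x),
        n_b=len(x),
        direction=0,
    )


def zscore_features(
    table: pd.DataFrame,
    columns: list[str],
    grouping: str = "global",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """z-score feature columns to mean 0, s.d. 1 (population convention).

    ``grouping='global'`` standardizes each column over the whole table;
    ``grouping='per-subject'`` standardizes within every subject.  A
    zero-variance column (within its grouping) is an error naming the
    column, not a silent NaN fill.
    """
    if grouping not in ("global", "per-subject"):
        raise ConfigurationError("grouping must be 'global' or 'per-subject'")
    out = table.copy()

    def _transform(df: pd.DataFrame, context: str) -> pd.DataFrame:
        vals = df[columns].to_numpy(dtype=float)
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ConfigurationError(
                f"zero-variance column(s) {[columns[i] for i in dead]} {context}"
            )
        df = df.copy()
        df[columns] = (vals - mean) / sd
        return df

    if grouping == "global":
        return _transform(out, "in table")
    parts = [
        _transform(g, f"for subject {s}") for s, g in out.groupby(subject_col, sort=False)
    ]
    return pd.concat(parts).loc[out.index]


def feature_valence_correlation(
    table: pd.DataFrame,
    feature_cols: list[str],
    rating_col: str = "valence_rating",
    mode: str = "SI",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Spearman correlation of each feature with the subjective valence rating.

    ``mode='SD'`` correlates within every subject (one row per
    subject x feature); ``mode='SI'`` pools all subjects.  Constant features
    yield a missing coefficient.
    """
    if table[rating_col].isna().any():
        raise ConfigurationError("ratings must be present for all trials")
    groups = (
        [("all", table)]
        if mode == "SI"
        else [(s, g) for s, g in table.groupby(subject_col, sort=True)]
    )
    rows = []
    for unit, df in groups:
        ratings = df[rating_col].to_numpy(dtype=float)
        for col in feature_cols:
            x = df[col].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(ratings == ratings[0]):
                rho, p = np.nan, np.nan
            else:
                rho, p = sps.spearmanr(x, ratings)
            rows.append(
                {"unit": unit, "feature": col, "rho": rho, "p": p, "n": len(df)}
            )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default
    reporting convention here)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
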