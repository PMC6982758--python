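"""Valence classification: subject-dependent and subject-independent.

Two evaluation schemes mirror how affective models are deployed:

* SD (subject-dependent) — a model per subject, evaluated by stratified
  k-fold CV over that subject's trials; analysis windows of one trial are
  never split across folds (grouped folds), which would otherwise leak
  within-trial autocorrelation into the test fold and inflate scores.
* SI (subject-independent) — leave-one-subject-out: train on all other
  subjects, test on the held-out one.

Classifiers are KNN with 5 neighbors and QDA (with light covariance
shrinkage so small folds with near-singular class covariances regularize
instead of failing).  Features are z-scored inside each training fold
only.  The primary metric is positive-class f1; macro-f1 is reported
alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .design import ConfigurationError
from .eeg import PRIMARY_FEATURE_NAMES

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "positive"

#: modality name -> feature columns of the fused table
MODALITY_COLUMNS: dict[str, list[str]] = {
    "eeg": list(PRIMARY_FEATURE_NAMES),
    "ecg": ["nn50"],
    "temp": ["mean_temp"],
}

#: the five modality combinations of the comparison grid
MODALITY_SETS: dict[str, tuple[str, ...]] = {
    "EEG": ("eeg",),
    "T+ECG": ("temp", "ecg"),
    "EEG+T": ("eeg", "temp"),
    "EEG+ECG": ("eeg", "ecg"),
    "EEG+T+ECG": ("eeg", "temp", "ecg"),
}


def make_classifier(name: str):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    raise ConfigurationError(f"unknown classifier {name!r}; use 'knn' or 'qda'")


def modality_feature_columns(modalities) -> list[str]:
    cols: list[str] = []
    for m in modalities:
        if m not in MODALITY_COLUMNS:
            raise ConfigurationError(
                f"unknown modality {m!r}; known: {sorted(MODALITY_COLUMNS)}"
            )
        cols.extend(MODALITY_COLUMNS[m])
    return cols


@dataclass(frozen=True)
class ClassificationOutcome:
    scheme: str  # 'SD' | 'SI'
    classifier: str
    modalities: tuple[str, ...]
    per_unit_f1: dict[str, float]  # per subject (SD) / per held-out subject (SI)
    per_unit_macro_f1: dict[str, float]
    seed: int

    @property
    def mean_f1(self) -> float:
        return float(np.mean(list(self.per_unit_f1.values())))

    @property
    def sd_f1(self) -> float:
        vals = list(self.per_unit_f1.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean(list(self.per_unit_macro_f1.values())))

    def summary_row(self) -> dict:
        return {
            "scheme": self.scheme,
            "classifier": self.classifier,
            "modalities": "+".join(self.modalities),
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "mean_macro_f1": self.mean_macro_f1,
            "n_units": len(self.per_unit_f1),
            "seed": self.seed,
        }


def fuse_modalities(
    eeg: pd.DataFrame, hrv: pd.DataFrame, temp: pd.DataFrame
) -> pd.DataFrame:
    """Join the per-window EEG features with the per-trial NN50 and mean
    cleaned temperature on (subject, trial) keys.

    The per-trial scalars broadcast to every EEG window of the trial — a
    feature-level alignment that replaces signal-level resampling of the
    raw modalities.  Subjects missing any modality (or with unusable rows)
    are dropped with a logged list, mirroring how incomplete recordings are
    excluded from a multimodal model.
    """
    hrv_part = hrv[["subject", "trial_id", "nn50"]].dropna()
    temp_part = temp.loc[
        temp["condition"].isin(["positive", "negative"]),
        ["subject", "trial_id", "mean_temp"],
    ].dropna()
    fused = eeg.merge(hrv_part, on=["subject", "trial_id"], how="inner").merge(
        temp_part, on=["subject", "trial_id"], how="inner"
    )
    kept = set(fused["subject"])
    dropped = sorted(
        (set(eeg["subject"]) | set(hrv["subject"]) | set(temp["subject"])) - kept
    )
    if dropped:
        logger.warning("subjects dropped from fusion (incomplete modalities): %s",
                       dropped)
    if not kept:
        raise ConfigurationError("no subjects with all modalities present")
    ordered = (
        ["subject", "gender", "trial_id", "window_id", "label", "valence_rating"]
        + [c for c in eeg.columns if c in set(sum(MODALITY_COLUMNS.values(), []))]
        + ["nn50", "mean_temp"]
    )
    ordered = [c for c in ordered if c in fused.columns]
    extra = [c for c in fused.columns if c not in ordered]
    return fused[ordered + extra].sort_values(
        ["subject", "trial_id", "window_id"], kind="mergesort"
    ).reset_index(drop=True)


def _fold_f1(model, X, y, folds) -> tuple[float, float]:
    """Pooled-prediction f1 over CV folds (positive-class, macro)."""
    pred = np.empty(len(y), dtype=object)
    for train, test in folds:
        from sklearn.base import clone

        m = clone(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[train], y[train])
            pred[test] = m.predict(X[test])
    pred = pred.astype(str)
    return (
        float(f1_score(y, pred, pos_label=POSITIVE_LABEL, zero_division=0)),
        float(f1_score(y, pred, average="macro", zero_division=0)),
    )


def classify(
    table: pd.DataFrame,
    scheme: str = "SD",
    classifier: str = "knn",
    modalities: tuple[str, ...] = ("eeg", "temp", "ecg"),
    gender: str | None = None,
    n_splits: int = 10,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> ClassificationOutcome:
    """Run one scheme x classifier x modality-set classification.

    Returns per-unit f1 (one entry per subject) plus summary statistics.
    ``gender`` restricts the population.  Fold assignment and therefore the
    whole outcome are deterministic under ``seed``.
    """
    cols = (
        modality_feature_columns(modalities)
        if feature_columns is None
        else list(feature_columns)
    )
    df = table if gender is None else table[table["gender"] == gender]
    if df.empty:
        raise ConfigurationError("no rows after gender filtering")
    y_all = df["label"].to_numpy(dtype=str)
    if len(np.unique(y_all)) < 2:
        raise ConfigurationError("labels are degenerate (single class)")
    model = make_pipeline(StandardScaler(), make_classifier(classifier))
    per_f1: dict[str, float] = {}
    per_macro: dict[str, float] = {}
    if scheme == "SD":
        for subject, sub in df.groupby("subject", sort=True):
            X = sub[cols].to_numpy(dtype=float)
            y = sub["label"].to_numpy(dtype=str)
            groups = sub["trial_id"].to_numpy()
            n_class_groups = (
                pd.DataFrame({"y": y, "g": groups}).groupby("y")["g"].nunique().min()
            )
            k = int(min(n_splits, n_class_groups))
            if k < 2:
                raise ConfigurationError(
                    f"subject {subject}: not enough trials per class for CV"
                )
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(splitter.split(X, y, groups))
            per_f1[subject], per_macro[subject] = _fold_f1(model, X, y, folds)
    elif scheme == "SI":
        subjects = df["subject"].to_numpy()
        X = df[cols].to_numpy(dtype=float)
        for subject in sorted(set(subjects)):
            test = subjects == subject
            train = ~test
            if len(np.unique(y_all[train])) < 2:
                raise ConfigurationError("training fold lost a class")
            from sklearn.base import clone

            m = clone(model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[train], y_all[train])
                pred = m.predict(X[test])
            per_f1[subject] = float(
                f1_score(y_all[test], pred, pos_label=POSITIVE_LABEL, zero_division=0)
            )
            per_macro[subject] = float(
                f1_score(y_all[test], pred, average="macro", zero_division=0)
            )
    else:
        raise ConfigurationError("scheme must be 'SD' or 'SI'")
    return ClassificationOutcome(
        scheme=scheme,
        classifier=classifier,
        modalities=tuple(modalities),
        per_unit_f1=per_f1,
        per_unit_macro_f1=per_macro,
        seed=seed,
    )


def compare_modalities(
    table: pd.DataFrame,
    schemes: tuple[str, ...] = ("SD", "SI"),
    classifiers: tuple[str, ...] = ("knn", "qda"),
    modality_sets: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ClassificationOutcome]]:
    """The modality-comparison grid: EEG, T+ECG, EEG+T, EEG+ECG, EEG+T+ECG
    crossed with both classifiers and both schemes.

    Returns a summary table (one row per cell, including a chance-level
    reference column from the label balance) and the full outcomes with
    per-unit scores retained for paired comparisons.
    """
    modality_sets = MODALITY_SETS if modality_sets is None else modality_sets
    outcomes = []
    rows = []
    chance = float((table["label"] == POSITIVE_LABEL).mean())
    for name, mods in modality_sets.items():
        for clf in classifiers:
            for scheme in schemes:
                out = classify(
                    table, scheme=scheme, classifier=clf, modalities=mods, seed=seed
                )
                outcomes.append(out)
                row = out.summary_row()
                row["modality_set"] = name
                row["chance_positive_rate"] = chance
                rows.append(row)
    return pd.DataFrame(rows), outcomes


def gender_split_classification(
    table: pd.DataFrame,
    classifier: str = "knn",
    modalities: tuple[str, ...] = ("eeg", "temp", "ecg"),
    seed: int = 0,
    min_reliable_subjects: int = 15,
) -> dict[str, ClassificationOutcome]:
    """Subject-independent classification for all / women / men.

    Groups with fewer than ``min_reliable_subjects`` subjects get a warning
    (below the sample size generally considered sufficient for SI
    evaluation); fewer than 2 subjects is an error.
    """
    results = {}
    for name, gender in (("all", None), ("women", "F"), ("men", "M")):
        sub = table if gender is None else table[table["gender"] == gender]
        n_subj = sub["subject"].nunique()
        if n_subj < 2:
            raise ConfigurationError(
                f"group {name!r} has {n_subj} subject(s); need >= 2 for SI"
            )
        if n_subj < min_reliable_subjects:
            warnings.warn(
                f"group {name!r} has only {n_subj} subjects (< "
                f"{min_reliable_subjects}); SI scores are unreliable",
                stacklevel=2,
            )
        results[name] = classify(
            table,
            scheme="SI",
            classifier=classifier,
            modalities=modalities,
            gender=gender,
            seed=seed,
        )
    return results
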