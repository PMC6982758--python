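"""Wrapper feature selection by simulated annealing.

The search state is a bit mask over candidate features; the objective is
the cross-validated f1 of a KNN(5) or QDA classifier on the selected
subset.  Standard Metropolis acceptance: better states are always
accepted, worse ones with probability exp(-delta / T) under a geometric
temperature schedule.  The same CV folds are reused for every evaluated
subset within a run so that subset comparisons are not confounded by fold
noise, and the best-ever state is returned, with ties broken toward the
smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .design import ConfigurationError
from .classification import make_classifier, POSITIVE_LABEL


@dataclass(frozen=True)
class SAConfig:
    initial_temperature: float = 0.1  # in f1 units
    cooling_rate: float = 0.95
    steps: int = 500
    min_size: int = 1
    max_size: int | None = None
    classifier: str = "knn"
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cooling_rate < 1):
            raise ConfigurationError("cooling_rate must lie in (0, 1)")
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")
        if self.min_size < 1:
            raise ConfigurationError("min_size must be >= 1")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ConfigurationError("max_size must be >= min_size")


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    best_score: float
    #: (step, proposal score, current score after the step, best so far)
    trace: tuple[tuple[int, float, float, float], ...]
    seed: int
    config: SAConfig


def _cv_folds(y: np.ndarray, n_splits: int, seed: int):
    """Fixed stratified folds shared by all subset evaluations of a run."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigurationError("labels must contain both classes")
    k = min(n_splits, counts.min())
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def evaluate_subset(
    subset: list[str],
    features: pd.DataFrame,
    labels: np.ndarray,
    classifier: str = "knn",
    folds=None,
    n_splits: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated positive-class f1 of one feature subset.

    An empty subset scores 0 by convention.  Features are z-scored on the
    training fold only (pipeline with a scaler), so the objective is
    leakage-free.
    """
    if len(subset) == 0:
        return 0.0
    y = np.asarray(labels)
    if folds is None:
        folds = _cv_folds(y, n_splits, seed)
    X = features[list(subset)].to_numpy(dtype=float)
    scores = []
    for train, test in folds:
        model = make_pipeline(StandardScaler(), make_classifier(classifier))
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        scores.append(
            f1_score(y[test], pred, pos_label=POSITIVE_LABEL, zero_division=0)
        )
    return float(np.mean(scores))


def anneal_select(
    features: pd.DataFrame,
    labels,
    config: SAConfig | None = None,
    candidate_columns: list[str] | None = None,
) -> SelectionResult:
    """Metropolis simulated-annealing search over feature subsets.

    Neighbor move: flip one randomly chosen feature bit (rejected
    immediately when it would violate the subset-size bounds).  Fully
    reproducible under the config seed.
    """
    config = SAConfig() if config is None else config
    cols = list(features.columns if candidate_columns is None else candidate_columns)
    if len(cols) < 2:
        raise ConfigurationError("need >= 2 candidate features")
    y = np.asarray(labels)
    folds = _cv_folds(y, config.n_splits, config.seed)
    rng = np.random.default_rng(config.seed)
    max_size = len(cols) if config.max_size is None else config.max_size

    def score_of(mask: np.ndarray) -> float:
        subset = [c for c, m in zip(cols, mask) if m]
        return evaluate_subset(subset, features, y, config.classifier, folds=folds)

    # initial state: a random subset of half the features
    mask = np.zeros(len(cols), dtype=bool)
    init = rng.choice(len(cols), size=max(config.min_size, len(cols) // 2), replace=False)
    mask[init] = True
    current = score_of(mask)
    best_mask, best = mask.copy(), current
    temperature = config.initial_temperature
    trace = [(0, current, current, best)]
    for step in range(1, config.steps):
        flip = int(rng.integers(len(cols)))
        proposal = mask.copy()
        proposal[flip] = ~proposal[flip]
        size = int(proposal.sum())
        if size < config.min_size or size > max_size:
            trace.append((step, current, current, best))
            temperature *= config.cooling_rate
            continue
        cand = score_of(proposal)
        delta = cand - current
        if delta >= 0 or rng.random() < np.exp(delta / max(temperature, 1e-12)):
            mask, current = proposal, cand
        if current > best or (
            current == best and mask.sum() < best_mask.sum()
        ):
            best_mask, best = mask.copy(), current
        trace.append((step, cand, current, best))
        temperature *= config.cooling_rate
    selected = tuple(c for c, m in zip(cols, best_mask) if m)
    return SelectionResult(
        selected=selected,
        best_score=best,
        trace=tuple(trace),
        seed=config.seed,
        config=config,
    )
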