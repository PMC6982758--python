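"""End-to-end orchestration: simulate -> extract -> test -> select ->
fuse -> classify -> correlate, with a reproducible report bundle.

A single top-level seed deterministically derives per-stage seeds, so one
knob reproduces every number; re-running with the same config writes
byte-identical outputs.  Stage tables are written as TSV, the manifest as
JSON, and a short plain-text summary closes the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    MODALITY_COLUMNS,
    compare_modalities,
    fuse_modalities,
    gender_split_classification,
)
from .design import ConfigurationError, EffectModel, StudyDesign
from .eeg import PRIMARY_FEATURE_NAMES, asymmetry_analysis, extract_feature_vectors
from .hrv import HRV_MEASURE_COLUMNS, hrv_for_trials
from .io import read_dataset
from .selection import SAConfig, anneal_select
from .stats import feature_valence_correlation, ks_normality, mann_whitney
from .synthetic import generate_dataset, temperature_annotations
from .temperature import clean_outliers, segment_temperature, temperature_statistics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectModel | None = None  # None -> defaults with derived seed
    input_dir: str | None = None  # read a written dataset instead of simulating
    out_dir: str = "valphys_run"
    seed: int = 0
    hrv_source: str = "ibi"  # 'ecg' runs the full R-peak chain
    sa_steps: int = 300
    sa_classifiers: tuple[str, ...] = ("knn", "qda")
    schemes: tuple[str, ...] = ("SD", "SI")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = StudyDesign(**raw.get("design", {}))
        effects = EffectModel(**raw["effects"]) if "effects" in raw else None
        keys = {
            k: raw[k]
            for k in ("input_dir", "out_dir", "seed", "hrv_source", "sa_steps")
            if k in raw
        }
        return cls(design=design, effects=effects, **keys)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "selection", "classification", "gender")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the stage tables and outcome objects.  Any stage
    failure propagates with its stage named; tables already written are
    retained for inspection.
    """
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data -----------------------------------------------------
    if config.input_dir is not None:
        if not Path(config.input_dir).exists():
            raise ConfigurationError(f"input directory {config.input_dir} not found")
        dataset = read_dataset(config.input_dir)
    else:
        effects = (
            config.effects
            if config.effects is not None
            else EffectModel(seed=seeds["simulate"])
        )
        dataset = generate_dataset(
            config.design, effects, include_ecg=(config.hrv_source == "ecg")
        )

    stage = "hrv"
    try:
        hrv_frames = [
            hrv_for_trials(dataset, sid, source=config.hrv_source)
            for sid in dataset.subject_ids
        ]
        hrv_table = pd.concat(hrv_frames, ignore_index=True)
        _write(hrv_table, out / "hrv.tsv")

        stage = "eeg"
        eeg_table = extract_feature_vectors(dataset)
        _write(eeg_table, out / "eeg_features.tsv")
        asym = asymmetry_analysis(eeg_table, mode="SI")
        asym_sd = asymmetry_analysis(eeg_table, mode="SD")
        _write(asym, out / "asymmetry_si.tsv")
        _write(asym_sd, out / "asymmetry_sd.tsv")

        stage = "temperature"
        temp_trials = []
        for s in dataset.subjects:
            if s.temp is None:
                logger.warning("subject %s lacks temperature; excluded", s.subject_id)
                continue
            segs = segment_temperature(
                s.temp, s.temp_fs, temperature_annotations(s), s.subject_id, s.gender
            )
            temp_trials.extend(clean_outliers(t) for t in segs)
        temp_table = pd.DataFrame(
            {
                "subject": t.subject_id,
                "gender": t.gender,
                "trial_id": t.trial_id,
                "condition": t.condition,
                "mean_temp": t.mean,
            }
            for t in temp_trials
        )
        _write(temp_table, out / "temperature.tsv")
        temp_stats = pd.concat(
            [
                temperature_statistics(temp_trials, mode="SI").assign(group="all"),
                temperature_statistics(temp_trials, mode="SI", gender="F").assign(
                    group="women"
                ),
                temperature_statistics(temp_trials, mode="SI", gender="M").assign(
                    group="men"
                ),
            ],
            ignore_index=True,
        )
        _write(temp_stats, out / "temperature_stats.tsv")

        stage = "hrv-statistics"
        hrv_ok = hrv_table.dropna(subset=HRV_MEASURE_COLUMNS)
        stat_rows = []
        for measure in HRV_MEASURE_COLUMNS:
            col = hrv_ok[["gender", "label", measure]].dropna()
            ks = ks_normality(col[measure])
            for group, sub in (
                ("all", col),
                ("men", col[col["gender"] == "M"]),
                ("women", col[col["gender"] == "F"]),
            ):
                pos = sub.loc[sub["label"] == "positive", measure]
                neg = sub.loc[sub["label"] == "negative", measure]
                if len(pos) == 0 or len(neg) == 0 or pos.nunique() + neg.nunique() < 3:
                    continue
                res = mann_whitney(pos, neg)
                stat_rows.append(
                    {
                        "measure": measure,
                        "group": group,
                        "test": res.test,
                        "U": res.statistic,
                        "p": res.p,
                        "n_pos": res.n_a,
                        "n_neg": res.n_b,
                        "direction": res.direction,
                        "ks_normality_p": ks.p,
                    }
                )
        hrv_stats = pd.DataFrame(stat_rows)
        _write(hrv_stats, out / "hrv_stats.tsv")

        stage = "selection"
        labels = hrv_ok["label"].to_numpy()
        selections = {}
        for clf in config.sa_classifiers:
            sa = SAConfig(
                steps=config.sa_steps, classifier=clf, seed=seeds["selection"]
            )
            selections[clf] = anneal_select(
                hrv_ok[HRV_MEASURE_COLUMNS].reset_index(drop=True), labels, sa
            )
        (out / "selection.json").write_text(
            json.dumps(
                {
                    clf: {
                        "selected": list(r.selected),
                        "best_score": r.best_score,
                        "seed": r.seed,
                        "steps": r.config.steps,
                    }
                    for clf, r in selections.items()
                },
                indent=2,
                sort_keys=True,
            )
        )

        stage = "fusion"
        fused = fuse_modalities(eeg_table, hrv_table, temp_table)
        _write(fused, out / "fused_features.tsv")

        stage = "classification"
        grid, outcomes = compare_modalities(
            fused, schemes=config.schemes, seed=seeds["classification"]
        )
        _write(grid, out / "classification_grid.tsv")
        gender_out = gender_split_classification(fused, seed=seeds["gender"])
        gender_df = pd.DataFrame(
            [dict(out_.summary_row(), group=name) for name, out_ in gender_out.items()]
        )
        _write(gender_df, out / "classification_gender.tsv")

        stage = "correlation"
        feature_cols = PRIMARY_FEATURE_NAMES + ["nn50", "mean_temp"]
        corr_sd = feature_valence_correlation(fused, feature_cols, mode="SD")
        corr_si = feature_valence_correlation(fused, feature_cols, mode="SI")
        _write(corr_sd, out / "correlation_sd.tsv")
        _write(corr_si, out / "correlation_si.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "design": dataset.design.to_dict(),
        "effects": dataset.effects.to_dict(),
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".tsv"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    summary = [
        f"valphys {__version__} full analysis (seed {config.seed})",
        f"subjects: {len(dataset.subjects)}  trials/subject: "
        f"{dataset.design.trials_per_subject}",
        f"HRV rows: {len(hrv_table)} ({hrv_table[HRV_MEASURE_COLUMNS[0]].isna().sum()}"
        " rejected)",
        f"asymmetry pairs tested: {asym['pair'].nunique()}",
        "temperature SI p (pos vs neg, all): "
        f"{temp_stats.loc[(temp_stats['group'] == 'all') & (temp_stats['comparison'] == 'positive_vs_negative'), 'p'].iloc[0]:.3g}",
        f"fused features: {len([c for cols in MODALITY_COLUMNS.values() for c in cols])}",
        "classification grid cells: " f"{len(grid)}",
    ]
    for clf, r in selections.items():
        summary.append(
            f"SA selection ({clf}): {len(r.selected)} features, best f1 "
            f"{r.best_score:.3f}"
        )
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    return {
        "dataset": dataset,
        "hrv": hrv_table,
        "hrv_stats": hrv_stats,
        "eeg": eeg_table,
        "asymmetry_si": asym,
        "asymmetry_sd": asym_sd,
        "temperature": temp_table,
        "temperature_stats": temp_stats,
        "selections": selections,
        "fused": fused,
        "grid": grid,
        "outcomes": outcomes,
        "gender": gender_out,
        "correlation_sd": corr_sd,
        "correlation_si": corr_si,
        "out_dir": out,
    }
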