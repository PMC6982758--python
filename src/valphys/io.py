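"""Plain-text persistence of a multimodal dataset.

One delimited (TSV) table per modality per subject plus a JSON manifest
recording the design, effect parameters, seed and file inventory; the
reader reconstructs the dataset losslessly (floats are written with
full precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ConfigurationError, EffectModel, StudyDesign
from .hrv import ECGTrace, IBISeries
from .synthetic import MultimodalDataset, SubjectRecord

_FLOAT_FMT = "%.17g"


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_tsv(path: Path) -> pd.DataFrame:
    # round_trip parsing: the default pandas float parser is not
    # correctly rounded and would break bit-level reproducibility
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_dataset(dataset: MultimodalDataset, out_dir: str | Path) -> Path:
    """Write every subject's tables plus ``manifest.json``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, dict[str, str]] = {}
    for s in dataset.subjects:
        files: dict[str, str] = {}
        prefix = s.subject_id
        _write_tsv(out / f"{prefix}_trials.tsv", s.trials)
        files["trials"] = f"{prefix}_trials.tsv"
        _write_tsv(out / f"{prefix}_baselines.tsv", s.baselines)
        files["baselines"] = f"{prefix}_baselines.tsv"
        if s.ecg is not None:
            n = len(s.ecg.samples)
            df = pd.DataFrame(
                {"time_s": np.arange(n) / s.ecg.fs, "mv": s.ecg.samples}
            )
            _write_tsv(out / f"{prefix}_ecg.tsv", df)
            files["ecg"] = f"{prefix}_ecg.tsv"
        if s.temp is not None:
            n = len(s.temp)
            df = pd.DataFrame(
                {"time_s": np.arange(n) / s.temp_fs, "celsius": s.temp}
            )
            _write_tsv(out / f"{prefix}_temp.tsv", df)
            files["temp"] = f"{prefix}_temp.tsv"
        if s.ibi is not None:
            rows = []
            for trial_id, series in s.ibi.items():
                for iv, t, m in zip(
                    series.intervals_ms, series.onset_times_s, series.corrected_mask
                ):
                    rows.append(
                        {"trial_id": trial_id, "interval_ms": iv,
                         "onset_s": t, "corrected": int(m)}
                    )
            _write_tsv(out / f"{prefix}_ibi.tsv", pd.DataFrame(rows))
            files["ibi"] = f"{prefix}_ibi.tsv"
        if s.eeg_features is not None:
            _write_tsv(out / f"{prefix}_eeg_features.tsv", s.eeg_features)
            files["eeg_features"] = f"{prefix}_eeg_features.tsv"
        inventory[s.subject_id] = {
            "gender": s.gender,
            "effect_multiplier": s.effect_multiplier,
            "eeg_sign": s.eeg_sign,
            "files": files,
        }
    manifest = {
        "design": dataset.design.to_dict(),
        "effects": dataset.effects.to_dict(),
        "seed": dataset.effects.seed,
        "subjects": inventory,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_dataset(in_dir: str | Path) -> MultimodalDataset:
    """Reconstruct a dataset written by :func:`write_dataset`."""
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    d = dict(manifest["design"])
    d["trial_duration_s"] = tuple(d["trial_duration_s"])
    design = StudyDesign(**d)
    effects = EffectModel(**manifest["effects"])
    subjects = []
    for subject_id, meta in manifest["subjects"].items():
        files = meta["files"]
        trials = _read_tsv(root / files["trials"])
        baselines = _read_tsv(root / files["baselines"])
        ecg = temp = ibi = eeg_features = None
        if "ecg" in files:
            df = _read_tsv(root / files["ecg"])
            ecg = ECGTrace(df["mv"].to_numpy(), design.ecg_fs)
        if "temp" in files:
            temp = _read_tsv(root / files["temp"])["celsius"].to_numpy()
        if "ibi" in files:
            df = _read_tsv(root / files["ibi"])
            ibi = {
                int(tid): IBISeries(
                    g["interval_ms"].to_numpy(),
                    g["onset_s"].to_numpy(),
                    g["corrected"].to_numpy(dtype=bool),
                )
                for tid, g in df.groupby("trial_id")
            }
        if "eeg_features" in files:
            eeg_features = _read_tsv(root / files["eeg_features"])
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                gender=meta["gender"],
                trials=trials,
                baselines=baselines,
                ecg=ecg,
                temp=temp,
                temp_fs=design.temp_fs,
                ibi=ibi,
                eeg_features=eeg_features,
                effect_multiplier=meta["effect_multiplier"],
                eeg_sign=meta["eeg_sign"],
            )
        )
    return MultimodalDataset(design=design, effects=effects, subjects=tuple(subjects))
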