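"""Reading and writing recordings, feature tables and reports.

Recordings are stored as a plain CSV (one row per sample, columns
``time_s, ch_ED, ch_PL, ch_FCU, ch_ECR, force_N, torque_Nm, label``)
plus a JSON sidecar holding the metadata (sampling rate, subject, protocol,
seed, maximum force/torque, sample count).  Floats are written at full
shortest-round-trip precision, so a write/read cycle reproduces sample
values exactly.  Readers validate rather than coerce: wrong columns, labels
outside 1..15 or a row count disagreeing with the sidecar all raise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .synthetic import DEFAULT_FS, MUSCLES, N_CLASSES, Recording, SubjectProfile

RECORDING_COLUMNS = ["time_s", "ch_ED", "ch_PL", "ch_FCU", "ch_ECR",
                     "force_N", "torque_Nm", "label"]
FEATURE_TABLE_COLUMNS = ["subject_id", "window_index", "label", *FEATURE_NAMES]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RecordingFileSet:
    data_path: Path
    meta_path: Path

    @classmethod
    def for_recording(cls, directory: PathLike, recording: Recording) -> "RecordingFileSet":
        stem = f"{recording.subject.subject_id}_{recording.protocol}"
        d = Path(directory)
        return cls(d / f"{stem}.csv", d / f"{stem}.json")


def write_recording(recording: Recording, paths: RecordingFileSet) -> None:
    n = recording.n_samples
    df = pd.DataFrame({
        "time_s": np.arange(n) / recording.fs,
        "ch_ED": recording.channels[0],
        "ch_PL": recording.channels[1],
        "ch_FCU": recording.channels[2],
        "ch_ECR": recording.channels[3],
        "force_N": recording.force if recording.force is not None else [""] * n,
        "torque_Nm": recording.torque if recording.torque is not None else [""] * n,
        "label": recording.labels,
    })
    paths.data_path.parent.mkdir(parents=True, exist_ok=True)
    # 17 significant digits: exact float64 round trip
    df.to_csv(paths.data_path, index=False, float_format="%.17g")
    meta = {
        "fs": recording.fs,
        "subject_id": recording.subject.subject_id,
        "group": recording.subject.group,
        "protocol": recording.protocol,
        "seed": recording.seed,
        "max_force": recording.subject.max_force,
        "max_torque": recording.subject.max_torque,
        "separability": recording.subject.separability,
        "noise_floor": recording.subject.noise_floor,
        "n_samples": n,
    }
    Path(paths.meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_recording(paths: RecordingFileSet) -> Recording:
    meta = json.loads(Path(paths.meta_path).read_text())
    df = pd.read_csv(paths.data_path, float_precision="round_trip")
    if list(df.columns) != RECORDING_COLUMNS:
        raise ValueError(f"recording CSV columns must be exactly "
                         f"{RECORDING_COLUMNS}, got {list(df.columns)}")
    if len(df) != meta["n_samples"]:
        raise ValueError(f"CSV has {len(df)} rows but sidecar records "
                         f"{meta['n_samples']} samples (truncated or corrupt file)")
    labels = df["label"].to_numpy()
    bad = np.where((labels < 1) | (labels > N_CLASSES))[0]
    if len(bad):
        raise ValueError(f"label {labels[bad[0]]} outside 1..{N_CLASSES} "
                         f"at row {bad[0]}")
    fs = int(meta["fs"])
    if fs != DEFAULT_FS:
        warnings.warn(f"non-standard sampling rate {fs} Hz (expected "
                      f"{DEFAULT_FS} Hz)", stacklevel=2)
    force = df["force_N"].to_numpy(dtype=float)
    torque = df["torque_Nm"].to_numpy(dtype=float)
    profile = SubjectProfile(
        subject_id=meta["subject_id"], group=meta["group"],
        max_force=meta["max_force"], max_torque=meta["max_torque"],
        separability=meta.get("separability", 1.0),
        noise_floor=meta.get("noise_floor", 0.05),
    )
    return Recording(
        fs=fs,
        channels=np.vstack([df[f"ch_{m}"].to_numpy(dtype=float) for m in MUSCLES]),
        labels=labels.astype(int),
        force=None if np.all(np.isnan(force)) else force,
        torque=None if np.all(np.isnan(torque)) else torque,
        subject=profile,
        protocol=meta["protocol"],
        seed=int(meta["seed"]),
    )


def _features_to_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != FEATURE_TABLE_COLUMNS:
            raise ValueError(f"feature table columns must be exactly "
                             f"{FEATURE_TABLE_COLUMNS}")
        return features
    records = []
    for fv in features:
        rec = {"subject_id": fv.subject_id, "window_index": fv.window_index,
               "label": fv.label}
        rec.update(dict(zip(FEATURE_NAMES, fv.values)))
        records.append(rec)
    return pd.DataFrame(records, columns=FEATURE_TABLE_COLUMNS)


def write_feature_table(features, path: PathLike) -> None:
    """Write feature vectors (list of FeatureVector or conforming DataFrame)."""
    df = _features_to_frame(features)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != FEATURE_TABLE_COLUMNS:
        raise ValueError(f"feature table columns must be exactly "
                         f"{FEATURE_TABLE_COLUMNS}, got {list(df.columns)}")
    return df


def read_feature_vectors(path: PathLike) -> List[FeatureVector]:
    df = read_feature_table(path)
    return [FeatureVector(values=row[FEATURE_NAMES].to_numpy(dtype=float),
                          label=None if pd.isna(row["label"]) else int(row["label"]),
                          subject_id=row["subject_id"],
                          window_index=int(row["window_index"]))
            for _, row in df.iterrows()]
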