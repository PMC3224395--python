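"""Config-driven end-to-end pipeline: simulate -> segment -> features ->
tune/train -> evaluate, per subject and per cohort.

One master seed deterministically derives every per-subject and
per-recording seed, so a full cohort study is reproducible from a single
integer.  Intermediate artifacts (recordings, feature tables, grid-search
tables, reports, the resolved config) are persisted when an output
directory is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as semg_io
from .classify import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, GridSearchResult,
                       grid_search_cv, split_train_test, train_svm)
from .evaluate import (CohortSummary, EvaluationReport, score,
                       summary_from_reports, SUMMARY_COLUMNS)
from .features import ARModelSpec, feature_names, features_dataframe
from .segmentation import segment_and_label, window_params
from .synthetic import (DEFAULT_FS, PROTOCOL_NAMES, SubjectProfile,
                        _derive_seed, draw_profiles, make_schedule)

log = logging.getLogger("semgpipe")


@dataclass
class PipelineConfig:
    """All pipeline knobs; serializable to/from YAML."""

    seed: int = 42
    out_dir: Optional[str] = None
    # simulation
    protocols: Tuple[str, ...] = PROTOCOL_NAMES
    event_duration_s: float = 5.0
    n_senior: int = 12
    n_young: int = 7
    # segmentation
    window_ms: float = 250.0
    step_ms: float = 125.0
    label_policy: str = "pure"
    #: seconds trimmed around every class transition before labelling, so
    #: training windows come from steady-state effort, not the on/off ramps
    event_margin_s: float = 0.3
    #: cap on windows kept per class per subject; balances classes (sustained
    #: grasps produce far more windows than brief pinches)
    max_windows_per_class: int = 40
    # features
    ar_order: int = 4
    ar_method: str = "burg"
    # classification
    test_fraction: float = 0.1
    cv_folds: int = 8
    c_grid: Tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    standardize: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["protocols"] = list(self.protocols)
        d["c_grid"] = list(self.c_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("protocols", "c_grid", "gamma_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def subject_features(profile: SubjectProfile, config: PipelineConfig,
                     subject_seed: int) -> pd.DataFrame:
    """Simulate all protocols for one subject and return the feature table.

    Windows are labelled with the pure policy by default and subsampled to
    at most ``max_windows_per_class`` per class (seeded, deterministic) so
    the per-subject class distribution is roughly balanced.
    """
    win, step = window_params(DEFAULT_FS, config.window_ms, config.step_ms)
    log.info("subject %s: window %d samples, step %d samples",
             profile.subject_id, win, step)
    spec = ARModelSpec(order=config.ar_order, method=config.ar_method)
    frames = []
    for j, name in enumerate(config.protocols):
        sched = make_schedule(name, event_duration_s=config.event_duration_s)
        rec = _simulate_for(profile, sched, subject_seed, j)
        segs = segment_and_label(rec, win, step, policy=config.label_policy,
                                 event_margin_s=config.event_margin_s)
        frames.append(features_dataframe(segs, spec))
    df = pd.concat(frames, ignore_index=True)
    df["window_index"] = np.arange(len(df))  # global index across protocols
    if config.max_windows_per_class:
        rng = np.random.default_rng(_derive_seed(subject_seed, 97))
        keep = []
        for label, grp in df.groupby("label"):
            idx = grp.index.to_numpy()
            if len(idx) > config.max_windows_per_class:
                idx = np.sort(rng.choice(idx, config.max_windows_per_class,
                                         replace=False))
            keep.append(idx)
        df = df.loc[np.sort(np.concatenate(keep))].reset_index(drop=True)
    return df


def _simulate_for(profile, sched, subject_seed, j):
    from .synthetic import simulate_recording
    return simulate_recording(sched, profile,
                              seed=_derive_seed(subject_seed, 11, j))


def run_subject_pipeline(profile: SubjectProfile, config: PipelineConfig,
                         subject_seed: Optional[int] = None,
                         out_dir: Optional[Path] = None):
    """Full per-subject pipeline; returns (report, grid_result, features).

    Stages: simulate each protocol, segment and label windows, extract the
    24 features, split 90/10 stratified, tune (c, γ) by cross-validated grid
    search on the training part only, train at the best pair, score the
    held-out windows.
    """
    if subject_seed is None:
        subject_seed = config.seed
    try:
        df = subject_features(profile, config, subject_seed)
    except Exception as exc:
        raise RuntimeError(f"simulation/feature stage failed for "
                           f"{profile.subject_id}: {exc}") from exc
    names = feature_names(ar_order=config.ar_order)
    X = df[names].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=int)
    split_seed = _derive_seed(subject_seed, 23)
    train_idx, test_idx = split_train_test(X, y, config.test_fraction,
                                           seed=split_seed)
    grid = grid_search_cv(X[train_idx], y[train_idx], config.c_grid,
                          config.gamma_grid, folds=config.cv_folds,
                          seed=_derive_seed(subject_seed, 29),
                          standardize_features=config.standardize)
    model = train_svm(X[train_idx], y[train_idx], grid.best,
                      standardize_features=config.standardize)
    pred = model.predict(X[test_idx])
    report = score(pred, y[test_idx], subject_id=profile.subject_id)
    log.info("subject %s: best (c=%g, gamma=%g) cv=%.2f%% test=%.2f%%",
             profile.subject_id, grid.best.c, grid.best.gamma,
             grid.best_cv_accuracy, report.accuracy)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        semg_io.write_feature_table(df, out_dir / f"{profile.subject_id}_features.csv")
        grid.table.to_csv(out_dir / f"{profile.subject_id}_grid.csv", index=False)
        (out_dir / f"{profile.subject_id}_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n")
    return report, grid, df


def run_cohort_study(config: PipelineConfig):
    """Run per-subject pipelines for both cohorts and summarize.

    Returns ``(summary, reports, profiles)``; writes a per-subject summary
    CSV (columns subject, accuracy_pct, max_force_N, max_torque_Nm) and the
    resolved config when ``config.out_dir`` is set.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    profiles: List[SubjectProfile] = []
    profiles += draw_profiles(config.n_senior, "senior", config.seed)
    profiles += draw_profiles(config.n_young, "young", config.seed)
    reports = []
    for i, prof in enumerate(profiles):
        subject_seed = _derive_seed(config.seed, 5, i)
        report, _, _ = run_subject_pipeline(prof, config, subject_seed,
                                            out_dir=out_dir)
        reports.append(report)
    summary = summary_from_reports(reports, profiles)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.per_subject[SUMMARY_COLUMNS].to_csv(
            out_dir / "cohort_summary.csv", index=False)
        config.to_yaml(out_dir / "config.yaml")
    return summary, reports, profiles
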