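"""Scoring, confusion structure and cohort-level summaries.

Beyond plain accuracy and the 15x15 confusion matrix, this module
quantifies the characteristic error mode of forearm-sEMG gesture
classification — confusion between pinches of adjacent fingers in the same
arm position (middle vs ring especially), driven by synergistic forearm
co-contraction — and aggregates per-subject results into cohort summaries:
group means of accuracy, maximum force and maximum torque, the senior-vs-
young force/torque decrease (relative percent) and accuracy decrease
(percentage points), and within-group linear fits of accuracy against
maximum force/torque.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix

from .synthetic import CLASS_IDS, N_CLASSES, PINCH_CLASSES, SubjectProfile

#: pinch pairs of adjacent fingers within one arm position
ADJACENT_PINCH_PAIRS = frozenset({
    frozenset(p) for p in ((5, 6), (6, 7), (7, 8), (12, 13), (13, 14), (14, 15))
})

SUMMARY_COLUMNS = ["subject", "accuracy_pct", "max_force_N", "max_torque_Nm"]


@dataclass
class EvaluationReport:
    """Accuracy, confusion matrix (rows true / columns predicted) and
    per-class recall for one subject's test set."""

    accuracy: float                 # percent
    confusion: np.ndarray           # (15, 15) counts
    per_class_recall: np.ndarray    # percent, NaN for absent classes
    subject_id: str = ""

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "accuracy_pct": self.accuracy,
            "n_test": self.n_test,
            "confusion": self.confusion.tolist(),
            "per_class_recall_pct": [None if np.isnan(v) else v
                                     for v in self.per_class_recall],
        }


def score(pred: Sequence[int], true: Sequence[int],
          subject_id: str = "") -> EvaluationReport:
    """Score predictions against ground truth over the 15 gesture classes."""
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if len(pred) == 0:
        raise ValueError("cannot score an empty prediction set")
    if len(pred) != len(true):
        raise ValueError("pred and true must have equal length")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.min() < 1 or arr.max() > N_CLASSES:
            raise ValueError(f"{name} labels must lie in 1..{N_CLASSES}")
    cm = confusion_matrix(true, pred, labels=list(CLASS_IDS))
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, 100.0 * np.diag(cm) / row_sums, np.nan)
    return EvaluationReport(accuracy=float(accuracy), confusion=cm,
                            per_class_recall=recall, subject_id=subject_id)


def adjacent_pinch_confusion(report: EvaluationReport) -> float:
    """Fraction of misclassified pinch windows predicted as the adjacent-
    finger pinch in the same arm position (0.0 when there are no pinch
    errors)."""
    cm = report.confusion
    total_errors = 0
    adjacent = 0
    for t in PINCH_CLASSES:
        for p in CLASS_IDS:
            if p == t:
                continue
            count = cm[t - 1, p - 1]
            total_errors += count
            if frozenset((t, p)) in ADJACENT_PINCH_PAIRS:
                adjacent += count
    return adjacent / total_errors if total_errors else 0.0


@dataclass
class GroupFit:
    """Least-squares line of accuracy (%) against a strength measure."""

    slope: float
    correlation: float


@dataclass
class CohortSummary:
    per_subject: pd.DataFrame               # subject, group, accuracy, force, torque
    group_means: pd.DataFrame               # indexed by group
    force_decrease_pct: Optional[float]     # 100*(young - senior)/young
    torque_decrease_pct: Optional[float]
    accuracy_decrease_points: Optional[float]  # young mean - senior mean
    fits: Dict[str, Dict[str, Optional[GroupFit]]] = field(default_factory=dict)


def _group_fit(x: np.ndarray, acc: np.ndarray) -> Optional[GroupFit]:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(acc) == 0:
        return None
    res = sstats.linregress(x, acc)
    return GroupFit(slope=float(res.slope), correlation=float(res.rvalue))


def cohort_summary(per_subject: pd.DataFrame) -> CohortSummary:
    """Aggregate a per-subject table with columns ``subject, group,
    accuracy_pct, max_force_N, max_torque_Nm`` into cohort statistics.

    Force/torque decreases are relative percent changes of the senior mean
    from the young mean; the accuracy decrease is the percentage-point
    difference of the group means.  Both require exactly the two groups
    'senior' and 'young' and are None otherwise.
    """
    required = {"subject", "group", "accuracy_pct", "max_force_N", "max_torque_Nm"}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValueError(f"per-subject table missing columns {sorted(missing)}")
    if len(per_subject) == 0:
        raise ValueError("per-subject table is empty")
    means = per_subject.groupby("group")[
        ["accuracy_pct", "max_force_N", "max_torque_Nm"]].mean()
    force_dec = torque_dec = acc_dec = None
    if {"senior", "young"} <= set(means.index):
        young, senior = means.loc["young"], means.loc["senior"]
        force_dec = float(100.0 * (young.max_force_N - senior.max_force_N)
                          / young.max_force_N)
        torque_dec = float(100.0 * (young.max_torque_Nm - senior.max_torque_Nm)
                           / young.max_torque_Nm)
        acc_dec = float(young.accuracy_pct - senior.accuracy_pct)
    fits: Dict[str, Dict[str, Optional[GroupFit]]] = {}
    for g, sub in per_subject.groupby("group"):
        acc = sub.accuracy_pct.to_numpy(dtype=float)
        fits[str(g)] = {
            "force": _group_fit(sub.max_force_N.to_numpy(dtype=float), acc),
            "torque": _group_fit(sub.max_torque_Nm.to_numpy(dtype=float), acc),
        }
    return CohortSummary(per_subject=per_subject.reset_index(drop=True),
                         group_means=means, force_decrease_pct=force_dec,
                         torque_decrease_pct=torque_dec,
                         accuracy_decrease_points=acc_dec, fits=fits)


def summary_from_reports(reports: Sequence[EvaluationReport],
                         profiles: Sequence[SubjectProfile]) -> CohortSummary:
    """Build the cohort summary from per-subject reports and profiles."""
    if len(reports) != len(profiles):
        raise ValueError("need one profile per report")
    rows = [{"subject": p.subject_id, "group": p.group,
             "accuracy_pct": r.accuracy, "max_force_N": p.max_force,
             "max_torque_Nm": p.max_torque}
            for r, p in zip(reports, profiles)]
    return cohort_summary(pd.DataFrame(rows))


def load_reference_cohorts() -> pd.DataFrame:
    """Reference per-subject summary tables (accuracy, maximum force and
    torque) for a 12-subject senior cohort and a 7-subject young cohort,
    shipped with the package as a worked example and regression fixture."""
    frames = []
    for group, fname in (("senior", "cohort_senior.csv"),
                         ("young", "cohort_young.csv")):
        with resources.files("semgpipe.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh)
        df.insert(1, "group", group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
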