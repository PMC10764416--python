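"""Subject-grouped evaluation: splits, cross-validation, ROC/AUC, geometric-
mean threshold selection, confusion metrics, and the sensor ablation.

All splitting operates on subjects, never on windows, so no person ever
contributes to both sides of a fold or of the 80/20 hold-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .dataio import ValidationError
from .windowing import SENSOR_CONFIGS, WindowDataset

MEAN_ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class SubjectSplit:
    train_subjects: tuple[str, ...]
    holdout_subjects: tuple[str, ...]
    bins: dict[str, int] = field(default_factory=dict)  # subject -> stratum


@dataclass
class FoldAssignment:
    """k lists of validation subjects forming a partition of the pool."""

    folds: tuple[tuple[str, ...], ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_subjects(self, fold: int) -> tuple[str, ...]:
        return tuple(
            s for i, f in enumerate(self.folds) if i != fold for s in f
        )


@dataclass
class ROCResult:
    fprs: list[np.ndarray]
    tprs: list[np.ndarray]
    aucs: np.ndarray  # per fold
    grid_fpr: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs))  # population SD across folds


@dataclass
class ThresholdChoice:
    threshold: float
    gmean: float
    sensitivity: float
    specificity: float


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auc: float


# ---------------------------------------------------------------------------
# splits


def holdout_split(
    subject_fog_pct: dict[str, float],
    fraction: float = 0.2,
    seed: int = 0,
) -> SubjectSplit:
    """Stratified 80/20 subject split.

    Subjects are binned by their per-subject FOG-time percentage: subjects
    with 0 % FOG form their own bin, the rest are cut at the quartiles of the
    nonzero percentages. The hold-out set draws ~``fraction`` from each bin
    (largest-remainder rounding to hit the overall count exactly).
    """
    subjects = list(subject_fog_pct)
    if len(subjects) < 5:
        raise ValidationError("need at least 5 subjects for a stratified split")
    pct = np.array([subject_fog_pct[s] for s in subjects])
    bins = np.zeros(len(subjects), dtype=int)
    nz = pct > 0
    if nz.sum() >= 4:
        quartiles = np.quantile(pct[nz], [0.25, 0.5, 0.75])
        bins[nz] = 1 + np.searchsorted(quartiles, pct[nz], side="left")
    else:
        bins[nz] = 1
    rng = np.random.default_rng(seed)
    n_holdout = int(round(fraction * len(subjects)))
    uniq = np.unique(bins)
    quota = {b: fraction * int((bins == b).sum()) for b in uniq}
    take = {b: int(np.floor(q)) for b, q in quota.items()}
    short = n_holdout - sum(take.values())
    for b in sorted(uniq, key=lambda b: quota[b] - take[b], reverse=True):
        if short <= 0:
            break
        if take[b] < int((bins == b).sum()):
            take[b] += 1
            short -= 1
    holdout: list[str] = []
    for b in uniq:
        members = [s for s, sb in zip(subjects, bins) if sb == b]
        picked = rng.choice(len(members), size=take[b], replace=False)
        holdout.extend(members[i] for i in sorted(picked))
    holdout_set = set(holdout)
    return SubjectSplit(
        train_subjects=tuple(s for s in subjects if s not in holdout_set),
        holdout_subjects=tuple(holdout),
        bins={s: int(b) for s, b in zip(subjects, bins)},
    )


def grouped_kfold(
    train_subjects: Sequence[str], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Partition subjects into k near-equal validation groups (seeded)."""
    subjects = list(train_subjects)
    if len(subjects) < k:
        raise ValidationError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    folds = [tuple(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), k)]
    return FoldAssignment(folds=tuple(tuple(str(s) for s in f) for f in folds))


def subject_fog_percent(dataset: WindowDataset) -> dict[str, float]:
    """Per-subject FOG-time percentage estimated from window fractions."""
    out: dict[str, float] = {}
    for s in dataset.subjects():
        sel = dataset.subject_ids == s
        out[s] = float(100.0 * dataset.fog_fraction[sel].mean())
    return out


# ---------------------------------------------------------------------------
# ROC machinery


def roc_points(
    labels: np.ndarray, probabilities: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) with a threshold at every distinct score.

    Prediction rule: positive iff probability >= threshold.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, probabilities, drop_intermediate=False)
    return fpr, tpr, thr


def roc_auc(labels: np.ndarray, probabilities: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points plus trapezoidal AUC (equals the Mann-Whitney statistic)."""
    fpr, tpr, _ = roc_points(labels, probabilities)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def mean_roc(
    fprs: Sequence[np.ndarray], tprs: Sequence[np.ndarray], aucs: Sequence[float]
) -> ROCResult:
    """Vertical averaging on a common 101-point FPR grid; mean AUC is the
    arithmetic mean of per-fold AUCs and the SD is the population SD."""
    if len(fprs) < 2:
        raise ValidationError("mean ROC needs at least two folds")
    interp = np.stack([np.interp(MEAN_ROC_GRID, f, t) for f, t in zip(fprs, tprs)])
    interp[:, 0] = 0.0
    interp[:, -1] = 1.0
    return ROCResult(
        fprs=[np.asarray(f) for f in fprs],
        tprs=[np.asarray(t) for t in tprs],
        aucs=np.asarray(aucs, dtype=float),
        grid_fpr=MEAN_ROC_GRID.copy(),
        mean_tpr=interp.mean(axis=0),
        sd_tpr=interp.std(axis=0),
    )


def gmean_threshold(labels: np.ndarray, probabilities: np.ndarray) -> ThresholdChoice:
    """Operating point maximizing sqrt(TPR * (1 - FPR)) over all ROC
    thresholds; ties break toward the larger threshold."""
    fpr, tpr, thr = roc_points(labels, probabilities)
    g = np.sqrt(tpr * (1.0 - fpr))
    best = int(np.argmax(g))  # thresholds are descending: first max = largest tau
    tau = float(min(max(thr[best], 0.0), 1.0))
    return ThresholdChoice(
        threshold=tau,
        gmean=float(g[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


def confusion_metrics(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float
) -> MetricsReport:
    """Threshold at p >= tau and report the confusion-table metrics.

    Precision and F-score are NaN when no window is predicted positive.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    y = np.asarray(labels, dtype=float)
    pred = np.asarray(probabilities) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    f = (
        2 * prec * sens / (prec + sens)
        if (tp + fp) and (prec + sens) > 0
        else float("nan")
    )
    if y.min() != y.max():
        _, _, auc = roc_auc(y, probabilities)
    else:
        auc = float("nan")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                         specificity=spec, precision=prec, f_score=f, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation and ablation


@dataclass
class CVResult:
    roc: ROCResult
    pooled_labels: np.ndarray
    pooled_probabilities: np.ndarray
    fold_assignment: FoldAssignment


def cross_validate(
    dataset: WindowDataset,
    trainer: Callable[[WindowDataset], object],
    folds: FoldAssignment,
    score_partial_as_neg: bool = False,
) -> CVResult:
    """Train/score once per fold with subjects partitioned, never windows.

    ``trainer`` maps a training WindowDataset to a fitted model exposing
    ``predict_dataset``. DISCARD windows never reach a training batch;
    validation windows follow the same exclusion unless
    ``score_partial_as_neg``.
    """
    fprs, tprs, aucs = [], [], []
    pooled_y: list[np.ndarray] = []
    pooled_p: list[np.ndarray] = []
    subject_arr = dataset.subject_ids.astype(str)
    for fold in range(folds.k):
        val_subjects = set(folds.folds[fold])
        train_subjects = set(folds.train_subjects(fold))
        if val_subjects & train_subjects:
            raise ValidationError("fold assignment is not a partition")
        tr_idx = np.flatnonzero(np.isin(subject_arr, list(train_subjects)))
        va_idx = np.flatnonzero(np.isin(subject_arr, list(val_subjects)))
        train_ds = dataset.select(tr_idx).scorable()
        val_ds = dataset.select(va_idx).scorable(include_partial_as_neg=score_partial_as_neg)
        model = trainer(train_ds)
        p = model.predict_dataset(val_ds)
        y = val_ds.y()
        fpr, tpr, auc = roc_auc(y, p)
        fprs.append(fpr)
        tprs.append(tpr)
        aucs.append(auc)
        pooled_y.append(y)
        pooled_p.append(p)
    return CVResult(
        roc=mean_roc(fprs, tprs, aucs),
        pooled_labels=np.concatenate(pooled_y),
        pooled_probabilities=np.concatenate(pooled_p),
        fold_assignment=folds,
    )


def assert_no_subject_leakage(
    train_ds: WindowDataset, eval_ds: WindowDataset
) -> None:
    overlap = set(map(str, train_ds.subject_ids)) & set(map(str, eval_ds.subject_ids))
    if overlap:
        raise ValidationError(f"subject leakage across split: {sorted(overlap)}")


def run_sensor_ablation(
    dataset_seven: WindowDataset,
    trainer_factory: Callable[[WindowDataset], object],
    folds: FoldAssignment,
    configs: Sequence[str] = ("seven", "six_legs_feet", "lower_legs", "lumbar", "right_foot"),
) -> tuple[pd.DataFrame, dict[str, CVResult]]:
    """Paired sensor-configuration comparison.

    The same fold assignment is reused for every configuration so differences
    are attributable to the channels, not the subject draw. Returns one row
    per configuration (channel count, mean AUC, SD) plus the full CV results.
    """
    rows = []
    results: dict[str, CVResult] = {}
    for name in configs:
        sensors = SENSOR_CONFIGS[name]
        missing = [
            s for s in sensors
            if f"{s}_x" not in dataset_seven.channel_names
        ]
        if missing:
            raise ValidationError(f"ablation requires sensors {missing} in the dataset")
        ds = dataset_seven.restrict_channels(sensors)
        cv = cross_validate(ds, trainer_factory, folds)
        results[name] = cv
        rows.append(
            {
                "configuration": name,
                "n_sensors": len(sensors),
                "n_channels": 3 * len(sensors),
                "mean_auc": cv.roc.mean_auc,
                "sd_auc": cv.roc.sd_auc,
            }
        )
    return pd.DataFrame(rows), results


def select_configuration(table: pd.DataFrame, tol: float = 1e-9) -> str:
    """Highest mean AUC; exact ties (within tol) break toward fewer sensors."""
    best_auc = table["mean_auc"].max()
    tied = table[table["mean_auc"] >= best_auc - tol]
    tied = tied.sort_values(["n_sensors", "configuration"], kind="stable")
    return str(tied.iloc[0]["configuration"])


__all__ = [
    "MEAN_ROC_GRID",
    "SubjectSplit",
    "FoldAssignment",
    "ROCResult",
    "ThresholdChoice",
    "MetricsReport",
    "CVResult",
    "holdout_split",
    "grouped_kfold",
    "subject_fog_percent",
    "roc_points",
    "roc_auc",
    "mean_roc",
    "gmean_threshold",
    "confusion_metrics",
    "cross_validate",
    "assert_no_subject_leakage",
    "run_sensor_ablation",
    "select_configuration",
]
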