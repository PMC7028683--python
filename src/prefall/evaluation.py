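"""Per-class metrics, subject-wise folds, cross-validation, latency.

Metrics are one-vs-rest: for a given class, TP counts its instances
correctly assigned to it, FN its instances assigned elsewhere, FP instances
of the other two classes pulled into it and TN the rest.  From those,

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

Cross-validation partitions *subjects*, not windows, so no person
contributes data to both the training and the test side of any fold.  The
canonical geometry (15 elderly + 23 young) gives five folds of exactly three
elderly subjects each, with young groups of sizes 5/5/5/4/4.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DataError,
    MeasurementError,
    SplitError,
    UndefinedMetricError,
)
from .nn.models import Model, ModelConfig, build_model
from .simulate import Cohort
from .training import EpochRecord, TrainConfig, select_best_epoch, train_model
from .windows import LABEL_NAMES, WindowSet, build_dataset

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "FoldSplit",
    "confusion_counts",
    "class_metrics",
    "make_subjectwise_folds",
    "cross_validate",
    "measure_latency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    cls: int
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, cls: int) -> ConfusionCounts:
    """One-vs-rest TP/FN/TN/FP for ``cls`` over three-class label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DataError("label vectors must be non-empty and aligned")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        bad = ~np.isin(y, (0, 1, 2))
        if bad.any():
            raise DataError(f"{name} contains labels outside {{0,1,2}}")
    if cls not in (0, 1, 2):
        raise DataError(f"class id {cls} outside {{0,1,2}}")
    pos = y_true == cls
    pred_pos = y_pred == cls
    return ConfusionCounts(
        cls=cls,
        tp=int((pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
        tn=int((~pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
    )


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """Sensitivity, specificity and accuracy from one-vs-rest counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError(
            f"metrics undefined for class {LABEL_NAMES.get(c.cls, c.cls)}: "
            f"tp+fn={c.tp + c.fn}, tn+fp={c.tn + c.fp}"
        )
    return ClassMetrics(
        sensitivity=c.tp / (c.tp + c.fn),
        specificity=c.tn / (c.tn + c.fp),
        accuracy=(c.tp + c.tn) / c.total,
    )


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    test_subjects: tuple[str, ...]
    train_subjects: tuple[str, ...]


def _split_groups(ids: list, n_folds: int, rng: np.random.Generator) -> list[list]:
    """Shuffle and split into ``n_folds`` groups with sizes differing by <= 1."""
    ids = list(ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    base, extra = divmod(len(shuffled), n_folds)
    groups, pos = [], 0
    for g in range(n_folds):
        size = base + (1 if g < extra else 0)
        groups.append(shuffled[pos:pos + size])
        pos += size
    return groups


def make_subjectwise_folds(
    elderly_ids: Sequence[str],
    young_ids: Sequence[str],
    rng: np.random.Generator | int | None = None,
    n_folds: int = 5,
) -> list[FoldSplit]:
    """Randomly pair elderly groups with young groups into test folds.

    Elderly and young subjects are independently shuffled and split into
    ``n_folds`` groups as evenly as possible; each elderly group is combined
    with a randomly chosen young group to form one test fold, and the
    training set is the complement.  With 15 elderly and 23 young this gives
    the canonical 3-elderly-per-fold, 5/5/5/4/4-young geometry (~80/20
    train/test).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    elderly = list(elderly_ids)
    young = list(young_ids)
    if len(set(elderly) & set(young)):
        raise SplitError("a subject id appears in both groups")
    if len(elderly) < n_folds:
        raise SplitError(
            f"{len(elderly)} elderly subjects cannot fill {n_folds} folds"
        )
    e_groups = _split_groups(elderly, n_folds, rng)
    y_groups = _split_groups(young, n_folds, rng)
    pairing = rng.permutation(n_folds)
    all_subjects = set(elderly) | set(young)
    folds = []
    for k in range(n_folds):
        test = tuple(sorted(e_groups[k] + y_groups[pairing[k]]))
        train = tuple(sorted(all_subjects - set(test)))
        folds.append(FoldSplit(fold=k, test_subjects=test, train_subjects=train))
    return folds


def _metrics_from_counts(counts: dict[int, tuple[int, int, int, int]]) -> dict:
    """Per-class metric dict at one epoch; undefined metrics become None."""
    out = {}
    for cls, (tp, fn, tn, fp) in counts.items():
        try:
            m = class_metrics(ConfusionCounts(cls, tp, fn, tn, fp))
            out[LABEL_NAMES[cls]] = {
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
            }
        except UndefinedMetricError:
            out[LABEL_NAMES[cls]] = {
                "sensitivity": None, "specificity": None, "accuracy": None,
            }
    return out


def cross_validate(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    window_len: int = 256,
    stride: int = 128,
    rule: str = "final_sample",
    n_folds: int = 5,
    fold_seed: int = 0,
    pooled: bool = False,
    cache_dir: "str | None" = None,
) -> dict:
    """Subject-wise k-fold cross-validation of one model family.

    Returns a JSON-serializable report: per-fold metrics at the selected
    epoch plus the across-fold mean (macro over folds by default; ``pooled``
    sums confusion counts over folds first).  Undefined per-fold metrics
    propagate as missing values and are excluded from means.

    With ``cache_dir`` set, each completed fold is written to disk and an
    interrupted run resumes from the folds already finished.
    """
    import json as _json
    from pathlib import Path as _Path
    cfg = train_config if train_config is not None else TrainConfig()
    dataset = build_dataset(cohort.trials, window_len, stride, rule)
    folds = make_subjectwise_folds(
        cohort.ids_by_group("elderly"), cohort.ids_by_group("young"),
        rng=fold_seed, n_folds=n_folds,
    )
    fold_reports = []
    pooled_counts = {c: np.zeros(4, dtype=np.int64) for c in (0, 1, 2)}
    for split in folds:
        cache_path = (
            _Path(cache_dir) / f"fold_{split.fold}.json" if cache_dir else None
        )
        if cache_path is not None and cache_path.exists():
            fold_report = _json.loads(cache_path.read_text())
            logger.info("fold %d: loaded from cache %s", split.fold, cache_path)
        else:
            train_ws = dataset.for_subjects(split.train_subjects)
            test_ws = dataset.for_subjects(split.test_subjects)
            leak = set(train_ws.provenance["subject_id"]) & set(test_ws.provenance["subject_id"])
            assert not leak, f"subject leakage across fold {split.fold}: {leak}"
            model = build_model(model_config, seed=cfg.seed + split.fold)
            records = train_model(model, train_ws, test_ws, cfg)
            best = select_best_epoch(records)
            rec = records[best]
            fold_report = {
                "fold": split.fold,
                "test_subjects": list(split.test_subjects),
                "best_epoch": best,
                "n_train_windows": len(train_ws),
                "n_test_windows": len(test_ws),
                "test_counts": {str(c): list(rec.test_counts[c]) for c in (0, 1, 2)},
                "metrics": _metrics_from_counts(rec.test_counts),
            }
            logger.info("fold %d: best epoch %d, test sens %s",
                        split.fold, best,
                        tuple(round(s, 3) for s in rec.test_sensitivity))
            if cache_path is not None:
                cache_path.parent.mkdir(parents=True, exist_ok=True)
                cache_path.write_text(_json.dumps(fold_report, indent=2, sort_keys=True))
        for c in (0, 1, 2):
            pooled_counts[c] += np.asarray(fold_report["test_counts"][str(c)])
        fold_reports.append(fold_report)
    mean: dict = {}
    for cls_name in LABEL_NAMES.values():
        mean[cls_name] = {}
        for metric in ("sensitivity", "specificity", "accuracy"):
            vals = [f["metrics"][cls_name][metric] for f in fold_reports
                    if f["metrics"][cls_name][metric] is not None]
            mean[cls_name][metric] = float(np.mean(vals)) if vals else None
    report = {
        "family": model_config.family,
        "model_config": model_config.to_dict(),
        "train_config": {
            "batch_size": cfg.batch_size, "n_epochs": cfg.n_epochs,
            "learning_rate": cfg.learning_rate, "focal_gamma": cfg.focal_gamma,
            "seed": cfg.seed, "normalize": cfg.normalize,
        },
        "window_len": window_len,
        "stride": stride,
        "rule": rule,
        "n_folds": n_folds,
        "fold_seed": fold_seed,
        "class_counts": dataset.class_counts,
        "folds": fold_reports,
        "mean": mean,
    }
    if pooled:
        report["pooled"] = _metrics_from_counts(
            {c: tuple(int(v) for v in pooled_counts[c]) for c in (0, 1, 2)}
        )
    return report


def measure_latency(
    model: Model,
    windows: WindowSet | np.ndarray,
    n_warmup: int = 10,
    max_instances: int | None = None,
) -> dict:
    """Mean wall-clock time of one single-window forward pass, in ms.

    Runs in streaming deployment style: batch size 1, warm-up passes
    excluded.  The result is hardware-dependent; only relative comparisons
    between families measured on the same machine are meaningful.
    """
    x = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
    if len(x) < 100:
        raise MeasurementError(
            f"latency measurement needs >= 100 instances, got {len(x)}"
        )
    if max_instances is not None:
        x = x[:max_instances]
    for i in range(min(n_warmup, len(x))):
        model.predict_proba(x[i:i + 1])
    times = np.empty(len(x))
    for i in range(len(x)):
        t0 = time.perf_counter()
        model.predict_proba(x[i:i + 1])
        times[i] = time.perf_counter() - t0
    return {
        "mean_ms": float(times.mean() * 1e3),
        "std_ms": float(times.std() * 1e3),
        "n_instances": int(len(x)),
    }
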