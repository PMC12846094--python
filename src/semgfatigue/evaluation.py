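"""LOSO experiment runner and evaluation metrics.

Per-class precision, recall and F1 follow the one-vs-rest count definitions;
headline accuracy is trace/total, with the summed one-vs-rest form (which
counts TN and coincides with trace/total for two classes) also reported.
ROC and precision-recall curves are built by an explicit threshold sweep,
ROC-AUC by the trapezoid rule and PR-AUC by right-step interpolation.
Macro averaging is used for the aggregate precision/recall/F1, excluding
classes whose denominators are empty in a fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .classification import (
    BaselineSpec,
    TrainSpec,
    train_baseline,
    train_image_model,
)
from .errors import ValidationError
from .features import FeatureConfig, feature_vector
from .preprocessing import preprocess_recording
from .scalogram import CwtConfig, cwt, render_image
from .segmentation import (
    HOP_MS_DEFAULT,
    WINDOW_MS_DEFAULT,
    LabeledDataset,
    Segment,
    assert_no_leakage,
    binarize,
    consensus_filter,
    label_dataset,
    loso_split,
    slide_windows,
)
from .synth import Recording

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValidationError("confusion matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(
    true_labels, predicted_labels, class_order: tuple[str, ...] | list
) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted as j."""
    class_order = tuple(class_order)
    index = {c: k for k, c in enumerate(class_order)}
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValidationError("label lists must be parallel")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValidationError(f"label outside class order: {ti!r}/{pi!r}")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1.

    Zero-denominator per-class values are NaN and excluded from the macro
    means (with a logged count).
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    c = len(cm.class_order)
    acc = float(np.trace(cm.counts) / cm.total)
    num = den = 0
    per_class: dict[str, dict[str, float]] = {}
    n_undefined = 0
    for i, name in enumerate(cm.class_order):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        num += tp + tn
        den += tp + tn + fp + fn
        pr = tp / (tp + fp) if tp + fp > 0 else float("nan")
        re = tp / (tp + fn) if tp + fn > 0 else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else float("nan")
        n_undefined += int(np.isnan(pr)) + int(np.isnan(re)) + int(np.isnan(f1))
        per_class[name] = {"precision": pr, "recall": re, "f1": f1}
    if n_undefined:
        logger.warning("%d undefined per-class metric(s) excluded from macros", n_undefined)

    def _macro(key: str) -> float:
        vals = [v[key] for v in per_class.values() if not np.isnan(v[key])]
        return float(np.mean(vals)) if vals else float("nan")

    return {
        "accuracy": acc,
        "accuracy_ovr": float(num / den),   # one-vs-rest summed form; == acc for C=2
        "precision": _macro("precision"),
        "recall": _macro("recall"),
        "f1": _macro("f1"),
        "per_class": per_class,
    }


def _binary_curves(scores: np.ndarray, truth: np.ndarray) -> dict:
    """ROC and PR points for one positive class via a threshold sweep."""
    order = np.argsort(-scores, kind="stable")
    truth = truth[order].astype(bool)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC/PR undefined: truth contains a single class")
    tp = np.cumsum(truth)
    fp = np.cumsum(~truth)
    # collapse tied scores to the last point of each tie group
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(truth) - 1]
    tp, fp = tp[distinct], fp[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision = tp / (tp + fp)
    recall = tp / n_pos
    rec = np.r_[0.0, recall]
    prec = np.r_[1.0, precision]
    pr_auc = float(np.sum(np.diff(rec) * prec[1:]))   # right-step interpolation
    return {
        "fpr": fpr, "tpr": tpr, "roc_auc": roc_auc,
        "precision": prec, "recall": rec, "pr_auc": pr_auc,
    }


def roc_pr(scores: np.ndarray, true_labels: np.ndarray,
           class_order: tuple[str, ...]) -> dict:
    """Per-class one-vs-rest ROC and PR curves with AUCs.

    ``scores`` is (n, C) class probabilities; ``true_labels`` indices into
    ``class_order``.
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    if scores.ndim != 2 or scores.shape[1] != len(class_order):
        raise ValidationError("scores must be (n, n_classes)")
    out = {}
    for i, name in enumerate(class_order):
        out[name] = _binary_curves(scores[:, i], (true_labels == i).astype(int))
    return out


@dataclass
class PipelineConfig:
    """Everything run_loso needs besides the cohort and the model spec."""

    task: str = "binary"                      # {"binary", "threeclass"}
    representation: str = "features"          # {"features", "scalogram"}
    window_ms: int = WINDOW_MS_DEFAULT
    hop_ms: int = HOP_MS_DEFAULT
    consensus_only: bool = False
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    cwt_config: CwtConfig = field(default_factory=CwtConfig)
    image_size: int = 224
    seed: int = 0


@dataclass
class EvalReport:
    folds: list[dict]
    aggregate: dict
    confusion_total: ConfusionMatrix
    class_names: tuple[str, ...]
    averaging: str = "macro"
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "class_names": list(self.class_names),
            "averaging": self.averaging,
            "folds": self.folds,
            "aggregate": self.aggregate,
            "confusion_total": self.confusion_total.counts.tolist(),
            "extras": {k: v for k, v in self.extras.items()
                       if isinstance(v, (int, float, str, list, dict))},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _group_windows(segments: list[Segment]) -> dict[tuple[str, int], list[Segment]]:
    """Group per-channel segments by (subject, start) — one window each."""
    groups: dict[tuple[str, int], list[Segment]] = {}
    for seg in segments:
        groups.setdefault((seg.subject_id, seg.start_ms), []).append(seg)
    return groups


def prepare_dataset(
    cohort: list[Recording], config: PipelineConfig
) -> LabeledDataset:
    """Preprocess and window every recording; label with the compound rule."""
    segments: list[Segment] = []
    for rec in cohort:
        proc = preprocess_recording(rec)
        segments.extend(slide_windows(proc, config.window_ms, config.hop_ms))
    ds = label_dataset(segments)
    if config.task == "binary":
        ds = binarize(ds)
    return ds


def _featurize(ds: LabeledDataset, config: PipelineConfig):
    """One row per window: 32 features, label, subject. Channel-major order."""
    groups = _group_windows(ds.segments)
    label_of = {}
    for seg, lab in zip(ds.segments, ds.labels):
        label_of[(seg.subject_id, seg.start_ms)] = int(lab)
    keys = sorted(groups)
    X = np.empty((len(keys), 0))
    rows, labels, subjects = [], [], []
    for key in keys:
        segs = sorted(groups[key], key=lambda s: s.channel_name)
        # restore the recording's channel order (channel-major vector)
        order = {c: k for k, c in enumerate(("BB", "BRA", "TRI", "DEL"))}
        segs = sorted(segs, key=lambda s: order.get(s.channel_name, 99))
        fv = feature_vector(segs, config.feature_config)
        rows.append(fv.values)
        labels.append(label_of[key])
        subjects.append(key[0])
    X = np.vstack(rows) if rows else np.empty((0, 32))
    return X, np.array(labels, dtype=int), np.array(subjects)


def _imageize(ds: LabeledDataset, config: PipelineConfig):
    """One image per (window, channel); all channels of a window share its label."""
    images, labels, subjects = [], [], []
    for seg, lab in zip(ds.segments, ds.labels):
        sc = cwt(seg, config.cwt_config)
        img = render_image(sc, config.image_size, config.image_size)
        images.append(img.pixels)
        labels.append(int(lab))
        subjects.append(seg.subject_id)
    return np.stack(images), np.array(labels, dtype=int), np.array(subjects)


def _aggregate_folds(folds: list[dict]) -> dict:
    keys = ("accuracy", "accuracy_ovr", "precision", "recall", "f1")
    agg = {}
    for k in keys:
        vals = np.array([f["metrics"][k] for f in folds], dtype=float)
        vals = vals[~np.isnan(vals)]
        agg[k] = {"mean": float(vals.mean()) if len(vals) else float("nan"),
                  "std": float(vals.std()) if len(vals) else float("nan")}
    return agg


def run_loso(
    cohort: list[Recording],
    config: PipelineConfig,
    model_spec: BaselineSpec | TrainSpec,
) -> EvalReport:
    """Leakage-safe leave-one-subject-out evaluation of one model.

    Preprocessing, windowing and representation building are strictly
    per-subject operations, so they are computed once per subject and folds
    assemble disjoint subject groups; a segment-provenance disjointness
    assertion runs in every fold and a violation is a hard error.
    """
    if len(cohort) < 2:
        raise ValidationError("LOSO needs a cohort of at least 2 subjects")
    ds = prepare_dataset(cohort, config)
    if config.consensus_only:
        ds = consensus_filter(ds)
        if len(ds) == 0:
            raise ValidationError("consensus subset is empty")
    class_names = ds.class_names

    if config.representation == "features":
        X, y, subjects = _featurize(ds, config)
        seg_subjects_per_row = subjects
    elif config.representation == "scalogram":
        X, y, subjects = _imageize(ds, config)
        seg_subjects_per_row = subjects
    else:
        raise ValidationError(f"unknown representation {config.representation!r}")

    split = loso_split([rec.subject_id for rec in cohort])
    folds_out = []
    cm_sum = np.zeros((len(class_names), len(class_names)), dtype=int)
    pooled_scores, pooled_truth = [], []
    for train_ids, test_id in split.folds:
        train_mask = np.isin(seg_subjects_per_row, train_ids)
        test_mask = seg_subjects_per_row == test_id
        # provenance check on the actual training segments, not the split table
        train_segments = [s for s in ds.segments if s.subject_id in train_ids]
        assert_no_leakage(train_segments, test_id)
        if not test_mask.any():
            logger.warning("fold %s: held-out subject produced no segments", test_id)
            continue
        if isinstance(model_spec, BaselineSpec):
            model = train_baseline(X[train_mask], y[train_mask], model_spec,
                                   seed=config.seed)
            X_test = X[test_mask]
            keep = ~np.any(np.isnan(X_test), axis=1)
            X_test, y_test = X_test[keep], y[test_mask][keep]
        else:
            model = train_image_model(X[train_mask], y[train_mask], model_spec)
            X_test, y_test = X[test_mask], y[test_mask]
        proba = model.predict_proba(X_test)
        pred = model.classes_[np.argmax(proba, axis=1)]
        # expand probabilities to the full class set if a class was missing in train
        full = np.zeros((len(proba), len(class_names)))
        for col, c in enumerate(model.classes_):
            full[:, int(c)] = proba[:, col]
        cm = confusion(
            [class_names[t] for t in y_test],
            [class_names[p] for p in pred],
            class_names,
        )
        cm_sum += cm.counts
        fold_metrics = metrics(cm)
        folds_out.append({
            "test_subject": test_id,
            "n_test": int(len(y_test)),
            "metrics": fold_metrics,
            "confusion": cm.counts.tolist(),
        })
        pooled_scores.append(full)
        pooled_truth.append(y_test)

    aggregate = _aggregate_folds(folds_out)
    extras: dict = {"n_windows": int(len(y)), "task": config.task,
                    "representation": config.representation,
                    "consensus_only": config.consensus_only}
    try:
        curves = roc_pr(np.vstack(pooled_scores), np.concatenate(pooled_truth),
                        class_names)
        extras["roc_auc"] = {k: v["roc_auc"] for k, v in curves.items()}
        extras["pr_auc"] = {k: v["pr_auc"] for k, v in curves.items()}
    except ValidationError:
        logger.warning("pooled ROC/PR undefined (single-class truth)")
    return EvalReport(
        folds=folds_out,
        aggregate=aggregate,
        confusion_total=ConfusionMatrix(cm_sum, class_names),
        class_names=class_names,
        extras=extras,
    )


def compare_full_vs_consensus(
    cohort: list[Recording],
    config: PipelineConfig,
    model_spec: BaselineSpec | TrainSpec,
) -> tuple[EvalReport, EvalReport]:
    """Identical folds and seeds; only the consensus filtering differs."""
    from dataclasses import replace

    full = run_loso(cohort, replace(config, consensus_only=False), model_spec)
    consensus = run_loso(cohort, replace(config, consensus_only=True), model_spec)
    n_full = full.extras["n_windows"]
    n_cons = consensus.extras["n_windows"]
    logger.info("consensus subset keeps %d of %d windows", n_cons, n_full)
    full.extras["counterpart_windows"] = n_cons
    consensus.extras["counterpart_windows"] = n_full
    return full, consensus
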