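"""Classifiers: classical baselines on 32-dim features and the image network.

Baselines are scikit-learn estimators configured verbatim from the published
per-task hyperparameter tables.  The image route is a pluggable convolutional
backbone followed by the dense head (GAP -> 256 -> dropout 0.4 -> 128 ->
dropout 0.4 -> softmax).  The default backbone is a small CNN trained from
scratch in NumPy (three conv-pool blocks ending at feature width 64) so the
pipeline runs on one CPU; the named ImageNet backbones raise an explicit
unavailable-backbone error unless an implementation is registered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import _nn
from .errors import UnavailableBackboneError, ValidationError

logger = logging.getLogger(__name__)

BASELINE_FAMILIES = (
    "logistic_regression", "random_forest", "decision_tree", "svm", "knn",
)

# Published grid-search results, per task.
BASELINE_PARAMS: dict[str, dict[str, dict]] = {
    "binary": {
        "logistic_regression": dict(solver="newton-cg", max_iter=60, multi_class="ovr", C=0.002),
        "random_forest": dict(max_depth=15, n_estimators=12, criterion="gini"),
        "decision_tree": dict(criterion="gini", max_depth=13),
        "svm": dict(decision_function_shape="ovo", max_iter=80, kernel="linear", C=0.3),
        "knn": dict(n_neighbors=7, metric="minkowski", algorithm="auto", weights="distance"),
    },
    "threeclass": {
        "logistic_regression": dict(solver="newton-cg", max_iter=65, multi_class="ovr", C=0.003),
        "random_forest": dict(max_depth=14, n_estimators=14, criterion="gini"),
        "decision_tree": dict(criterion="gini", max_depth=16),
        "svm": dict(decision_function_shape="ovo", max_iter=75, kernel="linear", C=0.4),
        "knn": dict(n_neighbors=8, metric="minkowski", algorithm="auto", weights="distance"),
    },
}


@dataclass(frozen=True)
class BaselineSpec:
    family: str
    task: str = "binary"                      # {"binary", "threeclass"}
    params: dict = field(default_factory=dict)

    @classmethod
    def published(cls, family: str, task: str) -> "BaselineSpec":
        if task not in BASELINE_PARAMS:
            raise ValidationError(f"unknown task {task!r}")
        if family not in BASELINE_PARAMS[task]:
            raise ValidationError(f"unknown baseline family {family!r}")
        return cls(family=family, task=task, params=dict(BASELINE_PARAMS[task][family]))


@dataclass(frozen=True)
class HeadSpec:
    dense1_units: int = 256
    dropout1: float = 0.4
    dense2_units: int = 128
    dropout2: float = 0.4

    def validate(self) -> None:
        if self.dense1_units < 1 or self.dense2_units < 1:
            raise ValidationError("dense units must be positive")
        for r in (self.dropout1, self.dropout2):
            if not 0.0 <= r < 1.0:
                raise ValidationError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 0.002
    batch_size: int = 128
    optimizer: str = "adam"
    epochs: int = 70
    seed: int = 0
    backbone_id: str = "scratch_small_cnn"
    fine_tune_all: bool = True
    val_fraction: float = 0.1
    input_size: int = 32                      # scratch backbone input side

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")


def build_head(num_classes: int, head: HeadSpec = HeadSpec()) -> list[tuple]:
    """Layer-sequence description of the dense classification head."""
    head.validate()
    if num_classes not in (2, 3):
        raise ValidationError("num_classes must be 2 or 3")
    return [
        ("global_average_pool",),
        ("dense", head.dense1_units),
        ("dropout", head.dropout1),
        ("dense", head.dense2_units),
        ("dropout", head.dropout2),
        ("dense", num_classes),
        ("softmax",),
    ]


def head_param_count(feature_width: int, num_classes: int,
                     head: HeadSpec = HeadSpec()) -> int:
    """Closed-form parameter count of the dense head given backbone width F."""
    f, d1, d2, c = feature_width, head.dense1_units, head.dense2_units, num_classes
    return f * d1 + d1 + d1 * d2 + d2 + d2 * c + c


SCRATCH_FEATURE_WIDTH = 64
_SCRATCH_CHANNELS = (8, 16, SCRATCH_FEATURE_WIDTH)


def _build_scratch_network(
    num_classes: int, head: HeadSpec, rng: np.random.Generator
) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    c_in = 3
    for c_out in _SCRATCH_CHANNELS:
        layers += [_nn.Conv2D(c_in, c_out, rng), _nn.ReLU(), _nn.MaxPool2()]
        c_in = c_out
    layers += [
        _nn.GlobalAveragePool(),
        _nn.Dense(SCRATCH_FEATURE_WIDTH, head.dense1_units, rng),
        _nn.ReLU(),
        _nn.Dropout(head.dropout1, rng),
        _nn.Dense(head.dense1_units, head.dense2_units, rng),
        _nn.ReLU(),
        _nn.Dropout(head.dropout2, rng),
        _nn.Dense(head.dense2_units, num_classes, rng),
    ]
    return _nn.Sequential(layers)


# Registry of backbone builders; pre-trained ImageNet models can be plugged in
# by registering a builder with the same signature.
BackboneBuilder = Callable[[int, HeadSpec, np.random.Generator], _nn.Sequential]
_BACKBONES: dict[str, BackboneBuilder | None] = {
    "scratch_small_cnn": _build_scratch_network,
    "inception_resnet_v2": None,
    "densenet121": None,
    "resnet50": None,
    "inception_v3": None,
}


def register_backbone(backbone_id: str, builder: BackboneBuilder) -> None:
    _BACKBONES[backbone_id] = builder


def _resize_images(images: np.ndarray, side: int) -> np.ndarray:
    """Downsample (N, H, W, 3) images to (N, side, side, 3) floats in [0, 1]."""
    x = np.asarray(images, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    n, h, w, c = x.shape
    if h == side and w == side:
        return x
    if h % side == 0 and w % side == 0:
        fh, fw = h // side, w // side
        return x.reshape(n, side, fh, side, fw, c).mean(axis=(2, 4))
    from skimage.transform import resize

    out = np.empty((n, side, side, c), dtype=np.float32)
    for i in range(n):
        out[i] = resize(x[i], (side, side, c), order=1, anti_aliasing=True)
    return out


class TrainedImageModel:
    """Fitted scratch/pluggable CNN with its training history."""

    def __init__(self, network: _nn.Sequential, classes: np.ndarray,
                 spec: TrainSpec, history: dict[str, list[float]]):
        self.network = network
        self.classes_ = classes
        self.spec = spec
        self.history = history

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _resize_images(images, self.spec.input_size)
        probs = []
        for start in range(0, len(x), 256):
            logits = self.network.forward(x[start : start + 256], train=False)
            probs.append(_nn.softmax(logits))
        return np.vstack(probs)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(images), axis=1)]


def train_image_model(
    images: np.ndarray,
    labels: np.ndarray,
    spec: TrainSpec = TrainSpec(),
    head: HeadSpec = HeadSpec(),
) -> TrainedImageModel:
    """Fit the image classifier; returns the model with per-epoch curves.

    ``images`` is (N, H, W, 3) uint8 or float; ``labels`` integer classes.
    A stratified ``val_fraction`` of the training windows is held out for the
    loss/accuracy curves.
    """
    spec.validate()
    head.validate()
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    builder = _BACKBONES.get(spec.backbone_id)
    if builder is None:
        raise UnavailableBackboneError(
            f"backbone {spec.backbone_id!r} has no local implementation; "
            "register one or use 'scratch_small_cnn'"
        )
    rng = np.random.default_rng(spec.seed)
    network = builder(len(classes), head, rng)

    x = _resize_images(images, spec.input_size)
    y = np.searchsorted(classes, labels)

    # stratified validation split
    val_idx: list[int] = []
    if spec.val_fraction > 0:
        for c in range(len(classes)):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_val = int(round(spec.val_fraction * len(idx)))
            val_idx.extend(idx[:n_val].tolist())
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    x_tr, y_tr = x[~val_mask], y[~val_mask]
    x_val, y_val = x[val_mask], y[val_mask]

    opt = _nn.Adam(network.params(), lr=spec.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }

    def _evaluate(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
        if len(ys) == 0:
            return float("nan"), float("nan")
        losses, correct = [], 0
        for start in range(0, len(xs), 256):
            logits = network.forward(xs[start : start + 256], train=False)
            loss, _ = _nn.softmax_xent(logits, ys[start : start + 256])
            losses.append(loss * len(ys[start : start + 256]))
            correct += int(np.sum(np.argmax(logits, axis=1) == ys[start : start + 256]))
        return float(np.sum(losses) / len(ys)), correct / len(ys)

    n_tr = len(y_tr)
    for _epoch in range(spec.epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, spec.batch_size):
            batch = order[start : start + spec.batch_size]
            logits = network.forward(x_tr[batch], train=True)
            _, g = _nn.softmax_xent(logits, y_tr[batch])
            network.backward(g)
            opt.step(network.grads())
        tr_loss, tr_acc = _evaluate(x_tr, y_tr)
        va_loss, va_acc = _evaluate(x_val, y_val)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)

    return TrainedImageModel(network, classes, spec, history)


class TrainedBaseline:
    """Fitted scikit-learn baseline honouring the published parameters."""

    def __init__(self, estimator, classes: np.ndarray, spec: BaselineSpec,
                 n_dropped: int = 0):
        self.estimator = estimator
        self.classes_ = classes
        self.spec = spec
        self.n_dropped = n_dropped

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self.estimator.predict_proba(X)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax of probabilities; ties break toward the lower-ordered class
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_estimator(spec: BaselineSpec, seed: int):
    p = dict(spec.params)
    if spec.family == "logistic_regression":
        multi = p.pop("multi_class", None)
        est = LogisticRegression(random_state=seed, **p)
        if multi == "ovr":
            est = OneVsRestClassifier(est)
        return est
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.family == "svm":
        return SVC(probability=True, random_state=seed, **p)
    if spec.family == "knn":
        return KNeighborsClassifier(**p)
    raise ValidationError(f"unknown baseline family {spec.family!r}")


def extract_params(model: TrainedBaseline) -> dict:
    """Read the spec'd hyperparameters back from the fitted estimator."""
    est = model.estimator
    if isinstance(est, OneVsRestClassifier):
        got = est.estimator.get_params()
        got["multi_class"] = "ovr"
    else:
        got = est.get_params()
    return {k: got[k] for k in model.spec.params}


def train_baseline(
    X: np.ndarray, labels: np.ndarray, spec: BaselineSpec, seed: int = 0
) -> TrainedBaseline:
    """Fit one classical baseline; rows with NaN features are dropped (logged)."""
    try:
        _make_estimator(spec, seed)
    except TypeError as exc:
        raise ValidationError(f"invalid parameter for {spec.family}: {exc}") from exc
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = ~np.any(np.isnan(X), axis=1)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropping %d row(s) with undefined features", n_dropped)
    X, labels = X[keep], labels[keep]
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    est = _make_estimator(spec, seed)
    with warnings.catch_warnings():
        # the published SVM max_iter values may stop before convergence
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        warnings.filterwarnings("ignore", category=UserWarning)
        est.fit(X, labels)
    return TrainedBaseline(est, classes, spec, n_dropped=n_dropped)
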