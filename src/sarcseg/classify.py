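"""Shallow neural classifier for object/noise localization labels.

A single-hidden-layer perceptron (32 ReLU units, one sigmoid output neuron,
binary cross-entropy loss, Adam, 10 epochs, batch size 32) maps each
feature vector to the probability that its localization belongs to a
double-line object.  Training runs as an explicit per-epoch loop so the
per-epoch train/validation loss history is available; everything is seeded
for reproducibility.

Feature-set ablations (distances-only, directions-only, combined) are
supported by training on column slices of the full feature matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelBinarizer

__all__ = [
    "ClassifierSpec",
    "Metrics",
    "TrainedClassifier",
    "train",
    "predict",
    "evaluate",
    "run_ablation",
    "save_model",
    "load_model",
]

_CLASSES = np.array([0, 1])  # 0 = noise, 1 = object


@dataclass
class ClassifierSpec:
    hidden_units: int = 32
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3  # Adam default
    threshold: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class Metrics:
    """Confusion-matrix summary. Rates follow the usual convention:
    tp_rate = TP/(TP+FN) over true objects, tn_rate = TN/(TN+FP) over true
    noise; a rate is NaN when its denominator class is absent."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def tp_rate(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def tn_rate(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")


@dataclass
class TrainedClassifier:
    model: MLPClassifier
    input_width: int
    spec: ClassifierSpec
    history: dict = field(default_factory=dict)


def _check_features(X, width=None):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    if width is not None and X.shape[1] != width:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model width {width}"
        )
    return X


def train(
    X,
    y,
    spec: ClassifierSpec | None = None,
    X_val=None,
    y_val=None,
) -> TrainedClassifier:
    """Fit the MLP for ``spec.epochs`` passes over the data.

    Returns the fitted classifier together with per-epoch ``loss`` (and
    ``val_loss`` when a validation set is supplied, used for monitoring
    only — there is no early stopping).
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    X = _check_features(X)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0 = noise, 1 = object)")
    if X_val is not None:
        X_val = _check_features(X_val, X.shape[1])
        y_val = np.asarray(y_val).astype(int)

    model = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation="relu",
        solver="adam",
        batch_size=spec.batch_size,
        learning_rate_init=spec.learning_rate,
        max_iter=1,
        shuffle=True,
        random_state=spec.rng_seed,
    )
    history = {"loss": [], "val_loss": []}
    for _ in range(spec.epochs):
        model.partial_fit(X, y, classes=_CLASSES)
        history["loss"].append(log_loss(y, model.predict_proba(X), labels=_CLASSES))
        if X_val is not None and len(X_val):
            history["val_loss"].append(
                log_loss(y_val, model.predict_proba(X_val), labels=_CLASSES)
            )
    return TrainedClassifier(model=model, input_width=X.shape[1], spec=spec, history=history)


def predict(clf: TrainedClassifier, X, threshold: float | None = None):
    """Per-localization object probability and binary label
    (``label = probability >= threshold``)."""
    X = _check_features(X, clf.input_width)
    if threshold is None:
        threshold = clf.spec.threshold
    proba = clf.model.predict_proba(X)[:, 1]
    return proba, proba >= threshold


def evaluate(pred_labels, true_labels) -> Metrics:
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if set(np.unique(true)) - {0, 1} or set(np.unique(pred)) - {0, 1}:
        raise ValueError("labels must be binary")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    return Metrics(tp=tp, fn=fn, tn=tn, fp=fp)


ABLATIONS = ("distances", "directions", "combined")


@dataclass
class AblationRun:
    """One feature-set variant: fitted model, test predictions, metrics."""

    metrics: Metrics
    test_labels: np.ndarray
    model: TrainedClassifier


def _slice(X, which, n_dist):
    if which == "distances":
        return X[:, :n_dist]
    if which == "directions":
        return X[:, n_dist:]
    if which == "combined":
        return X
    raise ValueError(f"unknown feature set {which!r}")


def run_ablation(
    X,
    y,
    train_idx,
    val_idx,
    test_idx,
    spec: ClassifierSpec | None = None,
    n_dist: int = 350,
    feature_sets=ABLATIONS,
) -> dict[str, AblationRun]:
    """Train and evaluate the three feature-set variants on fixed splits.

    ``X`` is the full distance+direction matrix; the distances-only and
    directions-only models are trained on its column slices so all three
    variants see identical data and splits.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    results: dict[str, AblationRun] = {}
    for which in feature_sets:
        Xs = _slice(X, which, n_dist)
        clf = train(Xs[train_idx], y[train_idx], spec, Xs[val_idx], y[val_idx])
        _, labels = predict(clf, Xs[test_idx])
        results[which] = AblationRun(
            metrics=evaluate(labels, y[test_idx]), test_labels=labels, model=clf
        )
    return results


def save_model(clf: TrainedClassifier, path) -> None:
    """Portable serialization: weights in an .npz plus a JSON sidecar with
    the training spec and input width."""
    path = Path(path)
    arrays = {}
    for i, (c, b) in enumerate(zip(clf.model.coefs_, clf.model.intercepts_)):
        arrays[f"coef_{i}"] = c
        arrays[f"intercept_{i}"] = b
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "input_width": clf.input_width,
        "n_layers": len(clf.model.coefs_),
        "spec": asdict(clf.spec),
        "history": clf.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    n_layers = sidecar["n_layers"]
    coefs = [data[f"coef_{i}"] for i in range(n_layers)]
    intercepts = [data[f"intercept_{i}"] for i in range(n_layers)]
    spec = ClassifierSpec(**sidecar["spec"])
    model = MLPClassifier(
        hidden_layer_sizes=tuple(c.shape[1] for c in coefs[:-1]),
        activation="relu",
    )
    model.coefs_ = coefs
    model.intercepts_ = intercepts
    model.n_layers_ = n_layers + 1
    model.n_outputs_ = 1
    model.out_activation_ = "logistic"
    model.classes_ = _CLASSES
    model.n_features_in_ = sidecar["input_width"]
    lb = LabelBinarizer()
    lb.fit(_CLASSES)
    model._label_binarizer = lb
    return TrainedClassifier(
        model=model,
        input_width=sidecar["input_width"],
        spec=spec,
        history=sidecar.get("history", {}),
    )
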