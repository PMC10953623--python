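"""Linear support-vector classification of ventricular feature vectors.

The classifier maps the six-element feature vector

    (apr_log, total_vv_norm, lr_frontal_log, lr_temporal_log, age, sex)

to a binary "compatible with bvFTD" / "not compatible" call.  Features
are z-scored with training statistics, a soft-margin linear SVM is fit
(optionally with inverse-frequency class weights for the heavily
imbalanced validation setting), and the signed decision value
w·z(x) + b is thresholded at zero, ties counting as positive.
Prediction is computed directly from the serialised weights, so a
saved and reloaded model reproduces its decisions bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .io_model import SchemaError

FEATURE_ORDER = ("apr_log", "total_vv_norm", "lr_frontal_log",
                 "lr_temporal_log", "age", "sex_code")

LABEL_POSITIVE = "bvFTD_compatible"
LABEL_NEGATIVE = "not_compatible"

_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


@dataclass
class SVMModel:
    """A trained linear SVM with its feature scaling and metadata."""

    feature_names: tuple[str, ...]
    mean: np.ndarray            # per-feature training mean
    std: np.ndarray             # per-feature training standard deviation
    weights: np.ndarray         # linear decision weights (z-scored space)
    bias: float
    C: float = 1.0
    class_weight: str = "balanced"   # "balanced" | "none"
    n_per_class: dict = field(default_factory=dict)
    seed: int = 0
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.std <= 0):
            raise ValueError("feature scaling standard deviations must be > 0")
        if not (len(self.feature_names) == self.mean.size
                == self.std.size == self.weights.size):
            raise ValueError("inconsistent model dimensions")

    def decision_value(self, x: np.ndarray) -> float:
        z = (np.asarray(x, dtype=np.float64) - self.mean) / self.std
        return float(self.weights @ z + self.bias)


def _validate_X_y(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_ORDER):
        raise SchemaError(
            f"feature matrix must be (n, {len(FEATURE_ORDER)}) in the order "
            + ", ".join(FEATURE_ORDER))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    if y.shape != (X.shape[0],):
        raise SchemaError("labels must match the number of feature rows")
    yb = np.asarray(y, dtype=np.int64)
    if not np.isin(yb, (0, 1)).all():
        raise ValueError("labels must be binary (1 = bvFTD, 0 = other)")
    return X, yb


def train(X, y, C: float = 1.0, class_weight: str = "balanced",
          seed: int = 0) -> SVMModel:
    """Fit the linear SVM on feature vectors X with binary labels y.

    ``class_weight`` "balanced" applies inverse-frequency class weights
    (the validation cohorts are heavily imbalanced); "none" weights all
    samples equally.  The solver is deterministic for fixed inputs.
    """
    X, yb = _validate_X_y(X, y)
    n = X.shape[0]
    if n < 4:
        raise TrainingError(f"need at least 4 samples, got {n}")
    classes, counts = np.unique(yb, return_counts=True)
    if classes.size < 2:
        raise TrainingError("training data contains a single class")
    if class_weight not in ("balanced", "none"):
        raise ValueError("class_weight must be 'balanced' or 'none'")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std

    # the penalty is applied per sample (C/n) so the fitted boundary is
    # invariant under uniform duplication of the dataset
    svc = LinearSVC(
        C=C / n,
        class_weight="balanced" if class_weight == "balanced" else None,
        loss="squared_hinge", dual=False, tol=1e-8, max_iter=50000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svc.fit(Z, yb)
    model = SVMModel(
        feature_names=tuple(FEATURE_ORDER),
        mean=mean, std=std,
        weights=svc.coef_.ravel().copy(), bias=float(svc.intercept_[0]),
        C=C, class_weight=class_weight,
        n_per_class={int(c): int(k) for c, k in zip(classes, counts)},
        seed=seed,
    )
    preds = predict_many(model, X)[0]
    model.training_accuracy = float((preds == yb).mean())
    return model


def predict(model: SVMModel, x) -> tuple[str, float]:
    """Classify one feature vector; returns (label, signed margin)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (len(model.feature_names),):
        raise SchemaError(
            f"expected {len(model.feature_names)} features in the order "
            + ", ".join(model.feature_names))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    score = model.decision_value(x)
    label = LABEL_POSITIVE if score >= 0 else LABEL_NEGATIVE
    return label, score


def predict_many(model: SVMModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised prediction; returns (binary labels, scores)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise SchemaError("feature matrix does not match the model schema")
    Z = (X - model.mean) / model.std
    scores = Z @ model.weights + model.bias
    return (scores >= 0).astype(np.int64), scores


def save_model(model: SVMModel, path) -> None:
    """Serialise a model to a human-readable key-value text file."""
    with open(path, "w") as fh:
        fh.write("# ventra linear SVM model\n")
        fh.write(f"format_version: {_FORMAT_VERSION}\n")
        fh.write("features: " + ",".join(model.feature_names) + "\n")
        fh.write("mean: " + " ".join(f"{v:.17g}" for v in model.mean) + "\n")
        fh.write("std: " + " ".join(f"{v:.17g}" for v in model.std) + "\n")
        fh.write("weights: " + " ".join(f"{v:.17g}" for v in model.weights)
                 + "\n")
        fh.write(f"bias: {model.bias:.17g}\n")
        fh.write(f"C: {model.C:.17g}\n")
        fh.write(f"class_weight: {model.class_weight}\n")
        fh.write("n_per_class: " + " ".join(
            f"{k}={v}" for k, v in sorted(model.n_per_class.items())) + "\n")
        fh.write(f"seed: {model.seed}\n")
        fh.write(f"training_accuracy: {model.training_accuracy:.17g}\n")


class ModelFormatError(ValueError):
    pass


def load_reference_model() -> "SVMModel":
    """The packaged reference model.

    Trained (seed-pinned) on ground-truth feature vectors of a synthetic
    cohort at the default group effect sizes; regenerate with
    ``ventra train``.  Numerical parity with any externally trained
    ventricular-feature classifier is out of scope — the reference model
    documents the expected file format and gives ``run`` a working
    default.
    """
    from importlib import resources
    ref = resources.files("ventra").joinpath("data/reference_model.txt")
    with resources.as_file(ref) as path:
        return load_model(path)


_REQUIRED_KEYS = ("format_version", "features", "mean", "std", "weights",
                  "bias")


def load_model(path) -> SVMModel:
    """Load a model file; unknown extra keys warn, truncation errors."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ModelFormatError(f"unparseable model line: {line!r}")
            key, val = line.split(":", 1)
            entries[key.strip()] = val.strip()
    missing = [k for k in _REQUIRED_KEYS if k not in entries]
    if missing:
        raise ModelFormatError(
            f"model file {path} is truncated or invalid; missing "
            + ", ".join(missing))
    version = int(entries["format_version"])
    if version != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version} "
            f"(this build reads version {_FORMAT_VERSION})")
    known = set(_REQUIRED_KEYS) | {"C", "class_weight", "n_per_class",
                                   "seed", "training_accuracy"}
    extra = sorted(set(entries) - known)
    if extra:
        warnings.warn(f"model file has unknown keys (ignored): "
                      + ", ".join(extra))
    n_per_class = {}
    for tok in entries.get("n_per_class", "").split():
        k, v = tok.split("=")
        n_per_class[int(k)] = int(v)
    return SVMModel(
        feature_names=tuple(entries["features"].split(",")),
        mean=np.array([float(v) for v in entries["mean"].split()]),
        std=np.array([float(v) for v in entries["std"].split()]),
        weights=np.array([float(v) for v in entries["weights"].split()]),
        bias=float(entries["bias"]),
        C=float(entries.get("C", 1.0)),
        class_weight=entries.get("class_weight", "balanced"),
        n_per_class=n_per_class,
        seed=int(entries.get("seed", 0)),
        training_accuracy=float(entries.get("training_accuracy", "nan")),
    )
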