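"""L2-regularized logistic regression over the 11 features.

The classifier is an ordinary logistic model: coding probability

    p = 1 / (1 + exp(-(w . x + b)))

with the inverse regularization strength C chosen by stratified k-fold
cross-validation (accuracy metric) over a logarithmic grid, ties broken
toward the smaller C (stronger regularization), then refit on all data.
Coding is the positive class.  Features are not standardized by default;
when standardization is requested the train-set means/sds are stored in
the model and applied at prediction time.

Models serialize to a human-readable JSON file carrying the weights,
intercept, chosen C, decision cutoff, feature ordering, the digest of the
hexamer table used for feature extraction, and training provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1

#: default logarithmic C grid, 10 points from 1e-4 to 1e4
DEFAULT_C_GRID = tuple(np.logspace(-4, 4, 10))

#: packaged operating cutoffs (probability thresholds) per species
SPECIES_CUTOFFS = {"human": 0.5654, "mouse": 0.4567}
DEFAULT_CUTOFF = 0.5


@dataclass
class TrainedModel:
    weights: np.ndarray
    intercept: float
    C: float
    cutoff: float = DEFAULT_CUTOFF
    feature_names: tuple[str, ...] = FEATURE_NAMES
    hexamer_table_digest: str = ""
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise ValueError(
                f"expected {len(self.feature_names)} weights, got {self.weights.shape}"
            )
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0,1), got {self.cutoff}")


def _check_matrix(x: np.ndarray, n_features: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != n_features:
        raise ValueError(f"feature matrix must be (n, {n_features}), got {x.shape}")
    bad = ~np.isfinite(x)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-finite feature at row {r}, column {c} ({FEATURE_NAMES[c] if c < len(FEATURE_NAMES) else c})")
    return x


def _fit_lr(x: np.ndarray, y: np.ndarray, c: float) -> LogisticRegression:
    lr = LogisticRegression(penalty="l2", C=c, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        # unscaled nt-length features can leave lbfgs shy of full convergence
        # at extreme C without affecting held-out accuracy
        warnings.simplefilter("ignore")
        lr.fit(x, y)
    return lr


def train(
    feature_matrix: np.ndarray,
    labels: Sequence[int],
    folds: int = 10,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    standardize: bool = False,
    cutoff: float = DEFAULT_CUTOFF,
    feature_names: Sequence[str] = FEATURE_NAMES,
    hexamer_table_digest: str = "",
) -> tuple[TrainedModel, float]:
    """Cross-validate C, refit on all data, return (model, mean CV accuracy).

    ``labels`` are 1 = coding (positive class), 0 = noncoding.  Fold
    assignment is stratified and seeded, so selection is deterministic
    given (data, seed, grid).  The returned CV accuracy is the mean
    held-out accuracy of the selected C.
    """
    feature_names = tuple(feature_names)
    x = _check_matrix(feature_matrix, len(feature_names))
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training labels must contain both classes (0 and 1)")
    if len(y) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold CV")

    mean = scale = None
    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
        x = (x - mean) / scale

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    cv_acc = np.empty(len(C_grid))
    for ci, c in enumerate(C_grid):
        accs = []
        for train_idx, test_idx in splits:
            lr = _fit_lr(x[train_idx], y[train_idx], c)
            accs.append(lr.score(x[test_idx], y[test_idx]))
        cv_acc[ci] = float(np.mean(accs))
    best = int(np.argmax(cv_acc))  # first max -> smaller C on ties
    best_c = float(C_grid[best])

    lr = _fit_lr(x, y, best_c)
    # sklearn orders classes [0, 1]; coef_ row is for the positive class
    model = TrainedModel(
        weights=lr.coef_[0],
        intercept=float(lr.intercept_[0]),
        C=best_c,
        cutoff=cutoff,
        feature_names=feature_names,
        hexamer_table_digest=hexamer_table_digest,
        scaler_mean=mean,
        scaler_scale=scale,
        provenance={
            "n_samples": int(len(y)),
            "n_coding": int(y.sum()),
            "n_noncoding": int((1 - y).sum()),
            "cv_folds": folds,
            "cv_seed": seed,
            "C_grid": [float(c) for c in C_grid],
            "cv_accuracy": float(cv_acc[best]),
            "standardize": standardize,
            "distance_definition": "sum_i(S_m - S_i)/2",
            "orf_convention": "ATG start; terminal stop optional at sequence end",
            "log_base": "e",
        },
    )
    return model, float(cv_acc[best])


def predict_proba(model: TrainedModel, feature_matrix: np.ndarray,
                  feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Coding probability per row: the logistic of ``w . x + b``."""
    if feature_names is not None and tuple(feature_names) != tuple(model.feature_names):
        missing = set(model.feature_names) - set(feature_names)
        extra = set(feature_names) - set(model.feature_names)
        raise ValueError(
            f"feature column mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    x = _check_matrix(feature_matrix, len(model.feature_names))
    if model.scaler_mean is not None:
        x = (x - model.scaler_mean) / model.scaler_scale
    z = x @ model.weights + model.intercept
    # clip the linear predictor, not the probability: keeps p in (0,1)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def classify(probs: Sequence[float], cutoff: float) -> list[str]:
    """Label coding iff p >= cutoff (cutoff must lie in (0,1))."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    return ["coding" if p >= cutoff else "noncoding" for p in np.asarray(probs, dtype=float)]


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path) -> None:
    doc = {
        "format": "lncclass-model",
        "version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "weights": [float(w) for w in model.weights],
        "intercept": model.intercept,
        "C": model.C,
        "cutoff": model.cutoff,
        "hexamer_table_digest": model.hexamer_table_digest,
        "scaler_mean": None if model.scaler_mean is None else [float(v) for v in model.scaler_mean],
        "scaler_scale": None if model.scaler_scale is None else [float(v) for v in model.scaler_scale],
        "provenance": model.provenance,
    }
    with open(path, "w") as out:
        json.dump(doc, out, indent=1)
        out.write("\n")


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lncclass-model":
        raise ValueError(f"{path}: not a lncclass model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {doc.get('version')} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        weights=np.array(doc["weights"], dtype=float),
        intercept=float(doc["intercept"]),
        C=float(doc["C"]),
        cutoff=float(doc["cutoff"]),
        feature_names=tuple(doc["feature_names"]),
        hexamer_table_digest=doc.get("hexamer_table_digest", ""),
        scaler_mean=None if doc.get("scaler_mean") is None else np.array(doc["scaler_mean"]),
        scaler_scale=None if doc.get("scaler_scale") is None else np.array(doc["scaler_scale"]),
        provenance=doc.get("provenance", {}),
    )


def check_table_digest(model: TrainedModel, digest: str) -> None:
    """Warn when predicting with a hexamer table the model was not trained on."""
    if model.hexamer_table_digest and digest and model.hexamer_table_digest != digest:
        warnings.warn(
            f"hexamer table digest {digest} does not match the digest recorded "
            f"in the model ({model.hexamer_table_digest}); features may be on a "
            "different scale than at training time",
            stacklevel=2,
        )
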