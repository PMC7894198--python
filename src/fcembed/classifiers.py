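"""Regularized extreme learning machine and linear SVM.

The ELM is a single-hidden-layer feedforward network whose input weights
``w_i`` and biases ``b_i`` are drawn randomly once and never trained.  With
hidden output matrix ``H`` (rows ``g(w . x + b)``) and one-hot target matrix
``T``, the regularized output weights solve the ridge system

    beta = (I / C + H' H)^{-1} H' T,

computed as a symmetric positive-definite solve (never an explicit
inverse).  As ``C -> inf`` this converges to the Moore-Penrose solution
``beta = H^+ T``.  Prediction is the argmax over output columns of
``h(x) beta`` (ties resolve to the lowest class index).

The linear SVM is the standard soft-margin hinge-loss machine at fixed
``C``; both classifiers share the train/predict calling convention used by
the cross-validation driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.special import expit
from sklearn.svm import SVC

from ._seeds import STAGE_CLASSIFIER, seed_sequence

__all__ = ["ElmModel", "elm_train", "elm_predict",
           "LinearSvmModel", "lsvm_train", "lsvm_predict", "get_classifier"]

_ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
}


@dataclass
class ElmModel:
    """Frozen random hidden layer plus learned output weights."""

    weights: np.ndarray          # L x D input weights (frozen)
    biases: np.ndarray           # L
    beta: np.ndarray             # L x M output weights
    activation: str
    c: float
    seed: int
    classes: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[0]


def _hidden(x: np.ndarray, weights: np.ndarray, biases: np.ndarray,
            activation: str) -> np.ndarray:
    pre = x @ weights.T + biases
    h = _ACTIVATIONS[activation](pre)
    if not np.all(np.isfinite(h)):
        raise ValueError(
            f"non-finite hidden activations (max |pre-activation| = "
            f"{np.abs(pre).max():.3g}); rescale the inputs")
    return h


def elm_train(x: np.ndarray, y: np.ndarray, n_hidden: int = 1000,
              c: float = 1.0, activation: str = "sigmoid",
              seed: int = 0) -> ElmModel:
    """Fit the regularized ELM.

    ``y`` may be a label vector (one-hot encoded internally) or an S x M
    one-hot matrix.  Input weights are uniform on [-1, 1], sized for
    standardized features.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if c <= 0:
        raise ValueError("regularization C must be positive")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if y.ndim == 2:
        targets = y.astype(float)
        classes = np.arange(y.shape[1])
    else:
        classes = np.unique(y)
        targets = (y[:, None] == classes[None, :]).astype(float)
    rng = np.random.default_rng(seed_sequence(seed, STAGE_CLASSIFIER))
    weights = rng.uniform(-1.0, 1.0, size=(n_hidden, x.shape[1]))
    biases = rng.uniform(-1.0, 1.0, size=n_hidden)
    h = _hidden(x, weights, biases, activation)
    a = h.T @ h + np.eye(n_hidden) / c
    beta = solve(a, h.T @ targets, assume_a="pos")
    return ElmModel(weights, biases, beta, activation, c, seed, classes)


def elm_predict(model: ElmModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"feature width {x.shape[1]} does not match training width "
            f"{model.weights.shape[1]}")
    h = _hidden(x, model.weights, model.biases, model.activation)
    scores = h @ model.beta
    return model.classes[np.argmax(scores, axis=1)]


def elm_decision(model: ElmModel, x: np.ndarray) -> np.ndarray:
    """Raw output-layer scores h(x) beta (S x M)."""
    h = _hidden(np.asarray(x, dtype=float), model.weights, model.biases,
                model.activation)
    return h @ model.beta


@dataclass
class LinearSvmModel:
    w: np.ndarray
    b: float
    classes: np.ndarray
    svm: SVC = field(repr=False, default=None)


def lsvm_train(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> LinearSvmModel:
    """Soft-margin linear SVM at fixed C (default 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("linear SVM needs both classes present in y")
    svm = SVC(kernel="linear", C=c)
    svm.fit(x, y)
    return LinearSvmModel(svm.coef_[0].copy(), float(svm.intercept_[0]),
                          classes, svm)


def lsvm_predict(model: LinearSvmModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.w.size:
        raise ValueError("feature width does not match training width")
    return model.svm.predict(x)


def get_classifier(name: str, **kwargs):
    """(train, predict) callables with signature train(X, y, seed) -> model."""
    name = name.lower()
    if name == "relm":
        def train(x, y, seed=0):
            return elm_train(x, y, seed=seed, **kwargs)
        return train, elm_predict
    if name == "lsvm":
        def train(x, y, seed=0):
            return lsvm_train(x, y, **kwargs)
        return train, lsvm_predict
    raise ValueError(f"unknown classifier {name!r}")
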