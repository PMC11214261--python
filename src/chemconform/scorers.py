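"""Underlying scoring algorithms behind the conformal and Venn-ABERS layers.

A uniform contract over sparse-capable SVMs (linear or RBF kernel, for
classification and regression) and logistic regression: every fitted
:class:`Scorer` exposes per-class decision scores (classification) or a
real-valued midpoint (regression), and — where the algorithm supports it —
class probabilities. Signature count features are used raw; optional
per-column standardization applies only to appended dense external
descriptor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC, SVR


class UnsupportedOperation(RuntimeError):
    """Raised when a scorer cannot provide the requested output type."""


@dataclass
class ScorerConfig:
    """Algorithm + hyper-parameters for an underlying scoring model.

    C and gamma default to 1 and 1/n_features; these are deliberately
    generic and meant to be replaced via the tuning grid for serious use.
    """

    algorithm: str = "svc"  # svc | svr | logistic
    kernel: str = "linear"  # linear | rbf
    C: float = 1.0
    gamma: float | None = None  # None -> 1/n_features (rbf only)
    epsilon: float = 0.1  # svr tube
    probability: bool = False  # svc: enable internal Platt calibration
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("svc", "svr", "logistic"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")

    def replace(self, **kw) -> "ScorerConfig":
        return replace(self, **kw)


class Scorer:
    """A fitted scoring model with a task-independent output contract."""

    def __init__(self, config: ScorerConfig, estimator, task: str, classes: np.ndarray | None):
        self.config = config
        self.estimator = estimator
        self.task = task
        self.classes = classes
        self._scaler = None

    @property
    def n_features(self) -> int:
        return self.estimator.n_features_in_

    def decision(self, X) -> np.ndarray:
        """Per-class signed scores (n, n_classes) or regression midpoints (n,).

        Binary classification returns the signed margin for the second
        class and its negation for the first, so the two columns sum to 0.
        """
        X = self._check(X)
        if self.task == "regression":
            return self.estimator.predict(X)
        d = self.estimator.decision_function(X)
        if d.ndim == 1:
            return np.column_stack([-d, d])
        return d

    def probability(self, X) -> np.ndarray:
        """Per-class probabilities in [0,1], rows summing to 1."""
        if self.task == "regression":
            raise UnsupportedOperation("probabilities are undefined for regression scorers")
        X = self._check(X)
        if not hasattr(self.estimator, "predict_proba"):
            raise UnsupportedOperation("scorer has no probability support")
        try:
            return self.estimator.predict_proba(X)
        except AttributeError as exc:  # SVC without probability=True
            raise UnsupportedOperation(
                "enable probability support in ScorerConfig for SVC"
            ) from exc

    def predict(self, X) -> np.ndarray:
        X = self._check(X)
        return self.estimator.predict(X)

    def _check(self, X):
        X = _as_2d(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"row has {X.shape[1]} features, scorer was trained with {self.n_features}"
            )
        if self._scaler is not None:
            X = self._scaler.transform(X)
        return X


def _as_2d(X):
    if sp.issparse(X):
        return sp.csr_matrix(X)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


def build_estimator(config: ScorerConfig, task: str):
    gamma = config.gamma if config.gamma is not None else "auto"  # auto = 1/n_features
    if task == "classification":
        if config.algorithm == "logistic":
            return LogisticRegression(C=config.C, max_iter=2000, random_state=config.seed)
        if config.algorithm == "svc":
            kw = {}
            if config.probability:
                kw["probability"] = True
            return SVC(
                kernel=config.kernel,
                C=config.C,
                gamma=gamma,
                random_state=config.seed,
                decision_function_shape="ovr",
                **kw,
            )
        raise ValueError(f"{config.algorithm!r} does not support classification")
    if config.algorithm != "svr":
        raise ValueError(f"{config.algorithm!r} does not support regression")
    return SVR(kernel=config.kernel, C=config.C, gamma=gamma, epsilon=config.epsilon)


def train_scorer(config: ScorerConfig, X, y, task: str) -> Scorer:
    """Fit the configured algorithm; reproducible from the config seed."""
    X = _as_2d(X)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 records to train a scorer")
    classes = None
    if task == "classification":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("classification requires at least 2 classes present")
    est = build_estimator(config, task)
    scorer = Scorer(config, est, task, classes)
    if config.standardize and not sp.issparse(X):
        from sklearn.preprocessing import StandardScaler

        scorer._scaler = StandardScaler().fit(X)
        X = scorer._scaler.transform(X)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        est.fit(X, y.astype(float) if task == "regression" else y)
    if task == "classification":
        scorer.classes = est.classes_
    return scorer
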