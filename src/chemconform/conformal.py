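"""Mondrian conformal prediction for classification and regression.

Classification is class-conditional (mondrian) throughout: the test
nonconformity for a tentative label y is ranked only against calibration
examples whose true label is y, which makes the coverage guarantee hold
per class and copes with imbalanced data without balancing tricks. The
prediction set at significance ``epsilon`` contains every label whose
p-value is >= epsilon, so it may be empty, single or multi-label.

Regression outputs an interval ``midpoint +/- alpha_(k) * sigma(x)`` where
``alpha_(k)`` is the ceil((1-eps)(n+1))-th smallest calibration
nonconformity and ``sigma`` is the difficulty scale of the chosen
nonconformity measure (1 for abs-diff; an error-model estimate plus a
smoothing factor beta for the normalized kinds). With fewer calibration
instances than 1/eps - 1 the interval is (-inf, inf).

Three predictor flavours share one estimator each: ICP (one split), ACP
(several random splits) and CCP (folded splits) differ only in the
:class:`~chemconform.data.SamplingStrategy`; the transductive TCP
classifier retrains the scorer for every (test object, tentative label).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .data import SamplingStrategy, split_sampling
from .pvalues import PValueCalculator, pvalues_batch
from .scorers import Scorer, ScorerConfig, train_scorer, _as_2d

CLASSIFICATION_NCMS = (
    "negative-distance",
    "positive-distance",
    "inverse-probability",
    "probability-margin",
)
REGRESSION_NCMS = ("abs-diff", "normalized", "log-normalized")

_PROBABILITY_NCMS = ("inverse-probability", "probability-margin")


def classification_alphas(scorer: Scorer, X, ncm: str, class_order: np.ndarray) -> np.ndarray:
    """Nonconformity alpha(x, y) for every row and candidate class.

    Higher alpha = stranger. Columns follow ``class_order``.
    """
    if ncm in ("negative-distance", "positive-distance"):
        d = scorer.decision(X)
        d = d[:, _reorder(scorer.classes, class_order)]
        return -d if ncm == "negative-distance" else d
    if ncm in _PROBABILITY_NCMS:
        P = scorer.probability(X)
        P = P[:, _reorder(scorer.classes, class_order)]
        if ncm == "inverse-probability":
            return 1.0 - P
        # probability-margin: 0.5 * (1 - P(y|x) + max_{y' != y} P(y'|x))
        n, k = P.shape
        out = np.empty_like(P)
        for j in range(k):
            others = np.delete(P, j, axis=1)
            out[:, j] = 0.5 * (1.0 - P[:, j] + others.max(axis=1))
        return out
    raise ValueError(f"unknown classification NCM {ncm!r}")


def _reorder(scorer_classes: np.ndarray, class_order: np.ndarray) -> list[int]:
    lookup = {c: i for i, c in enumerate(scorer_classes)}
    return [lookup[c] for c in class_order]


class ConformalClassifier(BaseEstimator):
    """Mondrian inductive/aggregated/cross conformal classifier.

    Parameters
    ----------
    ncm : one of ``CLASSIFICATION_NCMS``.
    scorer_config : underlying scoring model; defaults to a linear SVC.
    sampling : proper-train/calibration strategy; one random split = ICP,
        several = ACP, ``kind='fold'`` = CCP. Defaults to a single random
        80/20 split.
    pvalue_mode : ``standard`` | ``smoothed`` | ``linear-interpolated``.
    tau : smoothing factor for smoothed mode, or ``"random"``.
    aggregation : multi-split p-value combination, ``mean`` (default) or
        ``median``.
    """

    def __init__(
        self,
        ncm: str = "negative-distance",
        scorer_config: ScorerConfig | None = None,
        sampling: SamplingStrategy | None = None,
        pvalue_mode: str = "standard",
        tau: float | str = "random",
        aggregation: str = "mean",
        seed: int = 0,
    ):
        self.ncm = ncm
        self.scorer_config = scorer_config
        self.sampling = sampling
        self.pvalue_mode = pvalue_mode
        self.tau = tau
        self.aggregation = aggregation
        self.seed = seed

    def fit(self, X, y) -> "ConformalClassifier":
        if self.ncm not in CLASSIFICATION_NCMS:
            raise ValueError(f"unknown classification NCM {self.ncm!r}")
        X = _as_2d(X)
        y = np.asarray(y)
        self.classes_ = pd.unique(y)  # first-appearance order
        config = self.scorer_config or ScorerConfig(seed=self.seed)
        if self.ncm in _PROBABILITY_NCMS and config.algorithm == "svc" and not config.probability:
            config = config.replace(probability=True)
        strategy = self.sampling or SamplingStrategy(seed=self.seed)
        splits = split_sampling(X.shape[0], strategy, labels=y)
        self.models_ = []
        for s, (tr, ca) in enumerate(splits):
            present = set(np.unique(y[ca]))
            missing = [c for c in self.classes_ if c not in present]
            if missing:
                raise ValueError(
                    f"class(es) {missing!r} absent from calibration part of split {s}"
                )
            scorer = train_scorer(config.replace(seed=config.seed + s), X[tr], y[tr], "classification")
            alphas = classification_alphas(scorer, X[ca], self.ncm, self.classes_)
            stores = {}
            for j, c in enumerate(self.classes_):
                stores[c] = np.sort(alphas[y[ca] == c, j])
            self.models_.append((scorer, stores))
        self.calibration_sizes_ = {
            c: np.array([len(st[c]) for _, st in self.models_]) for c in self.classes_
        }
        return self

    def predict_p(self, X) -> np.ndarray:
        """Per-class p-values, shape (n, n_classes), columns = ``classes_``;
        multi-split models aggregate per-split p-values."""
        X = _as_2d(X)
        m = X.shape[0]
        k = len(self.classes_)
        tau = None
        if self.pvalue_mode == "smoothed":
            if self.tau == "random":
                tau = np.random.default_rng(self.seed).uniform(size=(m, k))
            else:
                tau = np.full((m, k), float(self.tau))
        per_split = np.empty((len(self.models_), m, k))
        for s, (scorer, stores) in enumerate(self.models_):
            alphas = classification_alphas(scorer, X, self.ncm, self.classes_)
            for j, c in enumerate(self.classes_):
                per_split[s, :, j] = pvalues_batch(
                    stores[c],
                    alphas[:, j],
                    mode=self.pvalue_mode,
                    tau=tau[:, j] if tau is not None else None,
                )
        agg = np.median if self.aggregation == "median" else np.mean
        return agg(per_split, axis=0)

    def predict_set(self, X, epsilon: float) -> np.ndarray:
        """Boolean membership matrix of the prediction sets at ``epsilon``."""
        return prediction_set(self.predict_p(X), epsilon)

    def predict(self, X) -> np.ndarray:
        """Forced-choice label: the class with the largest p-value."""
        p = self.predict_p(X)
        return self.classes_[np.argmax(p, axis=1)]


def prediction_set(pvalues: np.ndarray, epsilon: float) -> np.ndarray:
    """Set rule: include every label with p-value >= epsilon."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    return np.atleast_2d(pvalues) >= epsilon


class ConformalRegressor(BaseEstimator):
    """Inductive/aggregated conformal regressor with scaled intervals.

    ``ncm='abs-diff'`` uses alpha = |y - yhat|; ``'normalized'`` divides by
    ehat(x) + beta with an error model trained on absolute proper-train
    residuals; ``'log-normalized'`` divides by exp(ghat(x)) + beta with the
    error model trained on log(|residual| + beta). ``interval_mode``
    selects the standard (stepwise) or linearly interpolated calibration
    quantile. Multi-split predictions aggregate bounds per-bound
    (median by default).
    """

    def __init__(
        self,
        ncm: str = "abs-diff",
        beta: float = 0.01,
        scorer_config: ScorerConfig | None = None,
        error_scorer_config: ScorerConfig | None = None,
        sampling: SamplingStrategy | None = None,
        interval_mode: str = "standard",
        aggregation: str = "median",
        seed: int = 0,
    ):
        self.ncm = ncm
        self.beta = beta
        self.scorer_config = scorer_config
        self.error_scorer_config = error_scorer_config
        self.sampling = sampling
        self.interval_mode = interval_mode
        self.aggregation = aggregation
        self.seed = seed

    def fit(self, X, y) -> "ConformalRegressor":
        if self.ncm not in REGRESSION_NCMS:
            raise ValueError(f"unknown regression NCM {self.ncm!r}")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        X = _as_2d(X)
        y = np.asarray(y, dtype=float)
        config = self.scorer_config or ScorerConfig(algorithm="svr", seed=self.seed)
        err_config = self.error_scorer_config or config
        strategy = self.sampling or SamplingStrategy(seed=self.seed)
        splits = split_sampling(X.shape[0], strategy)
        self.models_ = []
        for s, (tr, ca) in enumerate(splits):
            if len(ca) == 0:
                raise ValueError(f"empty calibration part in split {s}")
            scorer = train_scorer(config.replace(seed=config.seed + s), X[tr], y[tr], "regression")
            error_model = None
            if self.ncm != "abs-diff":
                resid = np.abs(y[tr] - scorer.predict(X[tr]))
                target = resid if self.ncm == "normalized" else np.log(resid + self.beta)
                error_model = train_scorer(
                    err_config.replace(seed=err_config.seed + s), X[tr], target, "regression"
                )
            sigma = self._sigma(error_model, X[ca])
            alphas = np.sort(np.abs(y[ca] - scorer.predict(X[ca])) / sigma)
            self.models_.append((scorer, error_model, alphas))
        return self

    def _sigma(self, error_model: Scorer | None, X) -> np.ndarray:
        if self.ncm == "abs-diff":
            return np.ones(X.shape[0])
        pred = error_model.predict(X)
        if self.ncm == "normalized":
            return np.maximum(pred, 0.0) + self.beta
        return np.exp(pred) + self.beta

    def predict(self, X) -> np.ndarray:
        """Aggregated midpoint prediction."""
        X = _as_2d(X)
        mids = np.stack([scorer.predict(X) for scorer, _, _ in self.models_])
        agg = np.mean if self.aggregation == "mean" else np.median
        return agg(mids, axis=0)

    def predict_interval(self, X, epsilon: float) -> np.ndarray:
        """Columns (midpoint, lower, upper) at significance ``epsilon``;
        infinite bounds when the calibration set is too small."""
        if not 0.0 < epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        X = _as_2d(X)
        m = X.shape[0]
        lowers = np.empty((len(self.models_), m))
        uppers = np.empty((len(self.models_), m))
        mids = np.empty((len(self.models_), m))
        for s, (scorer, error_model, alphas) in enumerate(self.models_):
            mid = scorer.predict(X)
            mult = interval_multiplier(alphas, epsilon, self.interval_mode)
            half = mult * self._sigma(error_model, X)
            mids[s] = mid
            lowers[s] = mid - half
            uppers[s] = mid + half
        agg = np.mean if self.aggregation == "mean" else np.median
        return np.column_stack([agg(mids, axis=0), agg(lowers, axis=0), agg(uppers, axis=0)])


def interval_multiplier(sorted_alphas: np.ndarray, epsilon: float, mode: str = "standard") -> float:
    """Calibration quantile multiplying sigma(x) to give the half-width.

    Standard mode takes the k-th smallest alpha with k = ceil((1-eps)(n+1));
    interpolated mode linearly interpolates between adjacent order
    statistics (with alpha_(0) = 0, truncated at alpha_(n)). Returns inf
    when the required rank exceeds n.
    """
    alphas = np.asarray(sorted_alphas, dtype=float)
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    q = (1.0 - epsilon) * (n + 1)
    if mode == "standard":
        k = math.ceil(q - 1e-9)
        if k > n:
            return math.inf
        return float(alphas[k - 1])
    if mode == "linear-interpolated":
        if q > n + 1e-9:
            return math.inf
        lo = math.floor(q + 1e-9)
        frac = q - lo
        if frac < 1e-9:
            frac = 0.0
        a_lo = 0.0 if lo == 0 else float(alphas[lo - 1])
        a_hi = float(alphas[min(lo, n - 1)]) if lo >= 1 else float(alphas[0])
        return a_lo + frac * (a_hi - a_lo)
    raise ValueError(f"unknown interval mode {mode!r}")


class TCPClassifier(BaseEstimator):
    """Transductive conformal classifier.

    No calibration split: for every test object and every tentative label
    the scorer is retrained on the training data plus the tentatively
    labelled test object, and the p-value is the mondrian rank of the test
    nonconformity among same-label training instances. Exact but
    computationally heavy — intended for small datasets.
    """

    def __init__(
        self,
        ncm: str = "negative-distance",
        scorer_config: ScorerConfig | None = None,
        pvalue_mode: str = "standard",
        tau: float | str = "random",
        seed: int = 0,
    ):
        self.ncm = ncm
        self.scorer_config = scorer_config
        self.pvalue_mode = pvalue_mode
        self.tau = tau
        self.seed = seed

    def fit(self, X, y) -> "TCPClassifier":
        self.X_ = _as_2d(X)
        self.y_ = np.asarray(y)
        self.classes_ = pd.unique(self.y_)
        return self

    def predict_p(self, X) -> np.ndarray:
        X = _as_2d(X)
        config = self.scorer_config or ScorerConfig(seed=self.seed)
        if self.ncm in _PROBABILITY_NCMS and config.algorithm == "svc" and not config.probability:
            config = config.replace(probability=True)
        calc = PValueCalculator(self.pvalue_mode, self.tau, self.seed)
        out = np.empty((X.shape[0], len(self.classes_)))
        for i in range(X.shape[0]):
            row = X[i]
            for j, c in enumerate(self.classes_):
                if sp.issparse(self.X_):
                    X_aug = sp.vstack([self.X_, row]).tocsr()
                else:
                    X_aug = np.vstack([self.X_, np.atleast_2d(row)])
                y_aug = np.append(self.y_, c)
                scorer = train_scorer(config, X_aug, y_aug, "classification")
                alphas = classification_alphas(scorer, X_aug, self.ncm, self.classes_)
                members = np.flatnonzero(self.y_ == c)
                store = alphas[members, j]
                out[i, j] = calc(np.sort(store), alphas[-1, j])
        return out

    def predict_set(self, X, epsilon: float) -> np.ndarray:
        return prediction_set(self.predict_p(X), epsilon)


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_conformal_classifier(X, y, scorer_config=None, ncm="negative-distance",
                             strategy=None, pvalue_mode="standard", tau="random",
                             aggregation="mean", seed=0) -> ConformalClassifier:
    return ConformalClassifier(
        ncm=ncm, scorer_config=scorer_config, sampling=strategy,
        pvalue_mode=pvalue_mode, tau=tau, aggregation=aggregation, seed=seed,
    ).fit(X, y)


def fit_conformal_regressor(X, y, scorer_config=None, ncm="abs-diff", beta=0.01,
                            strategy=None, interval_mode="standard",
                            aggregation="median", seed=0) -> ConformalRegressor:
    return ConformalRegressor(
        ncm=ncm, beta=beta, scorer_config=scorer_config, sampling=strategy,
        interval_mode=interval_mode, aggregation=aggregation, seed=seed,
    ).fit(X, y)


def predict_class_pvalues(model: ConformalClassifier, X) -> np.ndarray:
    return model.predict_p(X)


def predict_interval(model: ConformalRegressor, X, epsilon: float) -> np.ndarray:
    return model.predict_interval(X, epsilon)


def tcp_predict(X_train, y_train, row, scorer_config=None, ncm="negative-distance",
                pvalue_mode="standard", tau="random", seed=0) -> np.ndarray:
    tcp = TCPClassifier(ncm=ncm, scorer_config=scorer_config,
                        pvalue_mode=pvalue_mode, tau=tau, seed=seed)
    tcp.fit(X_train, y_train)
    return tcp.predict_p(row)[0]
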