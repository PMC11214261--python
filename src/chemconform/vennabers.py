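"""Venn-ABERS probabilistic calibration for binary classification.

An inductive Venn-ABERS predictor (IVAP) trains the underlying scorer on
the proper training set and keeps the calibration set as (score, 0/1
label) pairs. Predicting a new object with score t fits two isotonic
regressions over the calibration pairs augmented with (t, 0) and with
(t, 1); the fitted values at t are the multi-probabilities p0 <= p1, one
of which is the true conditional probability. The pair is merged into a
single probability p = p1 / (1 - p0 + p1), which minimises regret in the
log-loss sense. A cross Venn-ABERS predictor (CVAP) trains one IVAP per
fold and merges fold-wise pairs with geometric means:
p = GM(p1) / (GM(1 - p0) + GM(p1)).

Only defined for binary labels; imbalanced data may need caller-side
balancing (no balancing is built in).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .data import SamplingStrategy, split_sampling
from .scorers import ScorerConfig, train_scorer, _as_2d


def isotonic_fit_value(scores: np.ndarray, targets: np.ndarray, at: float) -> float:
    """Least-squares monotone non-decreasing fit (ties pooled), evaluated
    at ``at``. The score ``at`` must be one of ``scores``."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(scores, targets)
    return float(iso.predict([at])[0])


def _score_pairs(scorer, X, y, positive) -> tuple[np.ndarray, np.ndarray]:
    d = scorer.decision(X)
    pos_col = list(scorer.classes).index(positive)
    scores = d[:, pos_col]
    targets = (np.asarray(y) == positive).astype(float)
    order = np.argsort(scores, kind="stable")
    return scores[order], targets[order]


class VennAbersClassifier(BaseEstimator):
    """IVAP (one split) or CVAP (fold sampling) binary calibrator.

    ``predict_venn`` returns columns (p0, p1, merged p); ``predict_proba``
    returns the merged probability as a standard two-column matrix.
    """

    def __init__(
        self,
        scorer_config: ScorerConfig | None = None,
        sampling: SamplingStrategy | None = None,
        positive_class=None,
        seed: int = 0,
    ):
        self.scorer_config = scorer_config
        self.sampling = sampling
        self.positive_class = positive_class
        self.seed = seed

    def fit(self, X, y) -> "VennAbersClassifier":
        X = _as_2d(X)
        y = np.asarray(y)
        self.classes_ = pd.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"Venn-ABERS is only defined for binary classes, got {len(self.classes_)}"
            )
        self.positive_ = self.positive_class if self.positive_class is not None else self.classes_[1]
        config = self.scorer_config or ScorerConfig(seed=self.seed)
        strategy = self.sampling or SamplingStrategy(seed=self.seed)
        splits = split_sampling(X.shape[0], strategy, labels=y)
        self.folds_ = []
        for s, (tr, ca) in enumerate(splits):
            scorer = train_scorer(config.replace(seed=config.seed + s), X[tr], y[tr], "classification")
            scores, targets = _score_pairs(scorer, X[ca], y[ca], self.positive_)
            self.folds_.append((scorer, scores, targets))
        return self

    def _fold_p01(self, scorer, scores, targets, X) -> tuple[np.ndarray, np.ndarray]:
        d = scorer.decision(X)
        pos_col = list(scorer.classes).index(self.positive_)
        t = d[:, pos_col]
        p0 = np.empty(len(t))
        p1 = np.empty(len(t))
        for i, ti in enumerate(t):
            s_aug = np.append(scores, ti)
            p0[i] = isotonic_fit_value(s_aug, np.append(targets, 0.0), ti)
            p1[i] = isotonic_fit_value(s_aug, np.append(targets, 1.0), ti)
        return p0, p1

    def predict_venn(self, X) -> np.ndarray:
        """Columns (p0, p1, merged p) for the positive class.

        Multi-fold models report fold-wise min p0 / max p1 and the
        geometric-mean merge.
        """
        X = _as_2d(X)
        p0s, p1s = [], []
        for scorer, scores, targets in self.folds_:
            p0, p1 = self._fold_p01(scorer, scores, targets, X)
            p0s.append(p0)
            p1s.append(p1)
        p0s = np.stack(p0s)
        p1s = np.stack(p1s)
        if len(self.folds_) == 1:
            p0, p1 = p0s[0], p1s[0]
            merged = p1 / (1.0 - p0 + p1)
        else:
            gm1 = np.exp(np.mean(np.log(np.clip(p1s, 1e-12, None)), axis=0))
            gm0 = np.exp(np.mean(np.log(np.clip(1.0 - p0s, 1e-12, None)), axis=0))
            merged = gm1 / (gm0 + gm1)
            p0, p1 = p0s.min(axis=0), p1s.max(axis=0)
        return np.column_stack([p0, p1, merged])

    def predict_proba(self, X) -> np.ndarray:
        """Two-column probability matrix aligned with ``classes_``."""
        merged = self.predict_venn(X)[:, 2]
        out = np.empty((len(merged), 2))
        pos_idx = list(self.classes_).index(self.positive_)
        out[:, pos_idx] = merged
        out[:, 1 - pos_idx] = 1.0 - merged
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def fit_ivap(X, y, scorer_config=None, strategy=None, seed=0) -> VennAbersClassifier:
    """One-split inductive Venn-ABERS predictor."""
    strategy = strategy or SamplingStrategy(n_splits=1, seed=seed)
    if strategy.kind != "fold" and strategy.n_splits != 1:
        raise ValueError("IVAP uses exactly one split")
    return VennAbersClassifier(scorer_config=scorer_config, sampling=strategy, seed=seed).fit(X, y)


def fit_cvap(X, y, k: int = 5, scorer_config=None, seed=0) -> VennAbersClassifier:
    """Cross Venn-ABERS predictor over ``k`` folds."""
    return VennAbersClassifier(
        scorer_config=scorer_config,
        sampling=SamplingStrategy(kind="fold", n_splits=k, seed=seed),
        seed=seed,
    ).fit(X, y)


def predict_ivap(model: VennAbersClassifier, X) -> np.ndarray:
    return model.predict_venn(X)


def predict_cvap(model: VennAbersClassifier, X) -> np.ndarray:
    return model.predict_venn(X)
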