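"""Conformal-aware evaluation, validation strategies and grid-search tuning.

Efficiency metrics follow the conformal literature: observed fuzziness
(mean p-value mass on false labels, significance-free), average C (mean
prediction-set size at a significance level), single/multi/empty-set
ratios, and the conformal confusion counts per true class. Calibration is
summarised by the signed deviation of the error rate from the significance
level over a grid, its RMSE, and the capped RMSE that zeroes conservative
deviations (error rate below the significance level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import f1_score, mean_squared_error
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold, train_test_split

from .conformal import ConformalClassifier, ConformalRegressor, prediction_set
from .scorers import ScorerConfig, train_scorer

# 10 cost values x 6 gamma values = 60 combinations
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-6, 13, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-14, -3, 2))


def default_rbf_grid() -> dict[str, tuple]:
    """The default RBF-kernel tuning grid (C x gamma)."""
    return {"C": DEFAULT_C_GRID, "gamma": DEFAULT_GAMMA_GRID}


def significance_grid(task: str = "classification") -> np.ndarray:
    """Default significance grids: 0.01-0.30 for classification,
    0.05-0.30 for regression, step 0.01."""
    lo = 0.01 if task == "classification" else 0.05
    return np.round(np.arange(lo, 0.301, 0.01), 2)


def classification_metrics(
    pvalues: np.ndarray,
    y_true: np.ndarray,
    classes: Sequence,
    grid: np.ndarray | None = None,
) -> dict:
    """Per-significance error/efficiency metrics plus observed fuzziness.

    Returns ``{"observed_fuzziness": float, "per_epsilon": DataFrame,
    "confusion": {epsilon: DataFrame}}``. The per-epsilon frame carries
    overall and per-class error rates, average C and set-size ratios.
    """
    pvalues = np.atleast_2d(pvalues)
    y_true = np.asarray(y_true)
    classes = list(classes)
    unknown = set(y_true) - set(classes)
    if unknown:
        raise ValueError(f"true labels {unknown!r} outside the label domain")
    if grid is None:
        grid = significance_grid("classification")
    class_idx = np.array([classes.index(v) for v in y_true])
    n, k = pvalues.shape
    p_true = pvalues[np.arange(n), class_idx]
    fuzz = float((pvalues.sum(axis=1) - p_true).mean())

    rows = []
    confusion = {}
    for eps in grid:
        sets = prediction_set(pvalues, eps)
        sizes = sets.sum(axis=1)
        hit = sets[np.arange(n), class_idx]
        row = {
            "epsilon": eps,
            "error_rate": float((~hit).mean()),
            "average_c": float(sizes.mean()),
            "single_ratio": float((sizes == 1).mean()),
            "multi_ratio": float((sizes > 1).mean()),
            "empty_ratio": float((sizes == 0).mean()),
        }
        for j, c in enumerate(classes):
            mask = class_idx == j
            row[f"error_rate_{c}"] = float((~hit[mask]).mean()) if mask.any() else np.nan
        rows.append(row)
        conf = []
        for j, c in enumerate(classes):
            mask = class_idx == j
            s, h = sizes[mask], hit[mask]
            conf.append({
                "true_class": c,
                "correct_single": int(((s == 1) & h).sum()),
                "wrong_single": int(((s == 1) & ~h).sum()),
                "multi": int((s > 1).sum()),
                "empty": int((s == 0).sum()),
            })
        confusion[float(eps)] = pd.DataFrame(conf)
    return {
        "observed_fuzziness": fuzz,
        "per_epsilon": pd.DataFrame(rows),
        "confusion": confusion,
    }


def regression_metrics(
    intervals: dict[float, np.ndarray],
    y_true: np.ndarray,
) -> pd.DataFrame:
    """Per-significance coverage/error and interval widths.

    ``intervals`` maps significance -> (n, 3) arrays of (midpoint, lower,
    upper). Infinite-width intervals count toward coverage; widths are
    summarised over finite intervals with the infinite count reported.
    """
    y_true = np.asarray(y_true, dtype=float)
    rows = []
    for eps in sorted(intervals):
        arr = np.asarray(intervals[eps])
        lower, upper = arr[:, 1], arr[:, 2]
        width = upper - lower
        finite = np.isfinite(width)
        inside = (y_true >= lower) & (y_true <= upper)
        rows.append({
            "epsilon": eps,
            "error_rate": float((~inside).mean()),
            "coverage": float(inside.mean()),
            "mean_width": float(width[finite].mean()) if finite.any() else np.inf,
            "median_width": float(np.median(width[finite])) if finite.any() else np.inf,
            "n_infinite": int((~finite).sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class CalibrationStats:
    max_signed_deviation: float
    rmse: float
    capped_rmse: float


def calibration_stats(error_rates: Sequence[float], grid: Sequence[float]) -> CalibrationStats:
    """Deviation of the observed error rate from the significance level.

    The capped variant sets the error rate equal to the significance level
    wherever it is lower (conservative predictions are not penalised), so
    capped RMSE <= RMSE always.
    """
    err = np.asarray(error_rates, dtype=float)
    eps = np.asarray(grid, dtype=float)
    if err.shape != eps.shape:
        raise ValueError("error rates and grid must have the same length")
    dev = err - eps
    capped = np.maximum(dev, 0.0)
    return CalibrationStats(
        max_signed_deviation=float(dev.max()),
        rmse=float(np.sqrt(np.mean(dev**2))),
        capped_rmse=float(np.sqrt(np.mean(capped**2))),
    )


def _evaluate_predictor(model, X_test, y_test, grid) -> dict:
    if isinstance(model, ConformalRegressor):
        intervals = {float(e): model.predict_interval(X_test, e) for e in grid}
        per_eps = regression_metrics(intervals, y_test)
        stats = calibration_stats(per_eps["error_rate"], per_eps["epsilon"])
        return {
            "per_epsilon": per_eps,
            "median_width_at_0.2": float(
                per_eps.loc[np.isclose(per_eps["epsilon"], 0.2), "median_width"].iloc[0]
            ) if np.isclose(per_eps["epsilon"], 0.2).any() else np.nan,
            "capped_rmse": stats.capped_rmse,
            "rmse": stats.rmse,
        }
    p = model.predict_p(X_test)
    met = classification_metrics(p, y_test, model.classes_, grid)
    stats = calibration_stats(met["per_epsilon"]["error_rate"], met["per_epsilon"]["epsilon"])
    return {
        "per_epsilon": met["per_epsilon"],
        "observed_fuzziness": met["observed_fuzziness"],
        "capped_rmse": stats.capped_rmse,
        "rmse": stats.rmse,
    }


def run_validation(
    X,
    y,
    model,
    scheme: str = "kfold",
    k: int = 10,
    test_fraction: float = 0.2,
    repetitions: int = 1,
    stratified: bool = True,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Evaluate a conformal predictor under k-fold CV, a single test-train
    split, or leave-one-out; repetition r re-seeds with seed + r.

    Returns per-fold metric frames plus mean +/- standard deviation of the
    scalar metrics across folds.
    """
    y = np.asarray(y)
    n = len(y)
    task = "regression" if isinstance(model, ConformalRegressor) else "classification"
    if grid is None:
        grid = significance_grid(task)
    folds = []
    for r in range(repetitions):
        rs = seed + r
        if scheme == "kfold":
            if k > n:
                raise ValueError("more folds than records")
            cv = (StratifiedKFold if stratified and task == "classification" else KFold)(
                n_splits=k, shuffle=True, random_state=rs
            )
            splits = cv.split(np.zeros(n), y if task == "classification" else None)
        elif scheme == "split":
            if not 0 < test_fraction < 1:
                raise ValueError("test_fraction must be in (0, 1)")
            tr, te = train_test_split(
                np.arange(n), test_size=test_fraction, random_state=rs,
                stratify=y if stratified and task == "classification" else None,
            )
            splits = [(tr, te)]
        elif scheme == "loo":
            splits = LeaveOneOut().split(np.zeros(n))
        else:
            raise ValueError(f"unknown validation scheme {scheme!r}")
        for tr, te in splits:
            m = clone(model)
            m.seed = rs
            m.fit(X[tr], y[tr])
            folds.append(_evaluate_predictor(m, X[te], y[te], grid))
    summary = {}
    for key in folds[0]:
        if key == "per_epsilon":
            continue
        vals = np.array([f[key] for f in folds], dtype=float)
        summary[key] = {"mean": float(np.nanmean(vals)), "std": float(np.nanstd(vals))}
    return {"folds": folds, "summary": summary, "n_folds": len(folds)}


def _scorer_objective(task: str):
    if task == "classification":
        return lambda y_true, y_pred: f1_score(y_true, y_pred, average="macro"), True
    return lambda y_true, y_pred: float(np.sqrt(mean_squared_error(y_true, y_pred))), False


def grid_search(
    X,
    y,
    base_config: ScorerConfig,
    grid: dict[str, Sequence] | None = None,
    mode: str = "scorer-only",
    objective: str | None = None,
    target_epsilon: float = 0.2,
    predictor_factory: Callable | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search over scorer hyper-parameters.

    ``mode='scorer-only'`` evaluates the bare scoring model by k-fold CV
    (macro F1 for classification, RMSE for regression) and never builds a
    conformal calibration store — the cheap way to tune. With
    ``mode='full-predictor'`` a predictor built by ``predictor_factory``
    (config -> estimator) is evaluated on the conformal objective
    (observed fuzziness, median interval width at ``target_epsilon``, or
    capped RMSE). Ties are broken by grid enumeration order.
    """
    task = "regression" if base_config.algorithm == "svr" else "classification"
    if grid is None:
        grid = default_rbf_grid() if base_config.kernel == "rbf" else {"C": DEFAULT_C_GRID}
    names = list(grid)
    for name in names:
        if name not in ("C", "gamma", "epsilon"):
            raise ValueError(f"unknown tunable parameter {name!r}")
    combos = [()]
    for name in names:
        combos = [c + (v,) for c in combos for v in grid[name]]
    if not combos or not names:
        raise ValueError("empty tuning grid")
    y = np.asarray(y)
    n = len(y)
    results = []
    for combo in combos:
        config = base_config.replace(**dict(zip(names, combo)))
        if mode == "scorer-only":
            metric_fn, higher_better = _scorer_objective(task)
            cv = (StratifiedKFold if task == "classification" else KFold)(
                n_splits=k, shuffle=True, random_state=seed
            )
            scores = []
            for tr, te in cv.split(np.zeros(n), y if task == "classification" else None):
                scorer = train_scorer(config, X[tr], y[tr], task)
                scores.append(metric_fn(y[te], scorer.predict(X[te])))
            value = float(np.mean(scores))
        elif mode == "full-predictor":
            obj = objective or ("observed_fuzziness" if task == "classification" else "median_width_at_0.2")
            factory = predictor_factory or (
                (lambda cfg: ConformalClassifier(scorer_config=cfg, seed=seed))
                if task == "classification"
                else (lambda cfg: ConformalRegressor(scorer_config=cfg, seed=seed))
            )
            higher_better = False
            res = run_validation(X, y, factory(config), scheme="kfold", k=k, seed=seed)
            value = res["summary"][obj]["mean"]
        else:
            raise ValueError(f"unknown tuning mode {mode!r}")
        results.append({"params": dict(zip(names, combo)), "value": value})
    sign = -1.0 if higher_better else 1.0
    best_i = min(range(len(results)), key=lambda i: (sign * results[i]["value"], i))
    order = sorted(range(len(results)), key=lambda i: (sign * results[i]["value"], i))
    return {
        "results": results,
        "ranked": [results[i] for i in order],
        "best": results[best_i],
        "n_combinations": len(results),
    }
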