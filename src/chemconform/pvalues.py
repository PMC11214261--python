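"""Conformal p-value calculators.

The standard p-value of a test nonconformity alpha against a calibration
list alpha_1..alpha_n is the rank of the test instance within the pooled
list of n+1 values:

    p = |{ j = 1..n+1 : alpha_j >= alpha_test }| / (n + 1)

where the test instance itself is included in the count. The smoothed
variant splits ties with a factor tau in [0, 1]; the linearly interpolated
variant turns the step function of the standard calculation into a
piecewise-linear, monotone non-increasing function of alpha with knots at
the calibration values — useful when only a handful of calibration
instances are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def pvalue_standard(calibration_alphas: np.ndarray, test_alpha: float) -> float:
    """Rank-based p-value; calibration values >= the test value, plus the
    test instance itself, over n+1."""
    alphas = np.asarray(calibration_alphas, dtype=float)
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    return (np.count_nonzero(alphas >= test_alpha) + 1) / (n + 1)


def pvalue_smoothed(calibration_alphas: np.ndarray, test_alpha: float, tau: float) -> float:
    """Tie-splitting p-value: strictly-greater count plus tau times the tie
    count (the test instance always ties itself); tau=1 reproduces the
    standard calculation."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    alphas = np.asarray(calibration_alphas, dtype=float)
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    greater = np.count_nonzero(alphas > test_alpha)
    ties = np.count_nonzero(alphas == test_alpha) + 1
    return (greater + tau * ties) / (n + 1)


def pvalue_interpolated(calibration_alphas: np.ndarray, test_alpha: float) -> float:
    """Piecewise-linear p-value through the knots (alpha_(k), standard p at
    alpha_(k)); clamped to 1 below the smallest calibration value and to
    1/(n+1) above the largest."""
    alphas = np.sort(np.asarray(calibration_alphas, dtype=float))
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    if test_alpha < alphas[0]:
        return 1.0
    if test_alpha > alphas[-1]:
        return 1.0 / (n + 1)
    knots, idx = np.unique(alphas, return_index=True)
    pk = np.array([pvalue_standard(alphas, k) for k in knots])
    return float(np.interp(test_alpha, knots, pk))


def pvalues_batch(
    sorted_alphas: np.ndarray,
    test_alphas: np.ndarray,
    mode: str = "standard",
    tau: np.ndarray | float | None = None,
) -> np.ndarray:
    """Vectorized p-values for many test nonconformities against one sorted
    calibration list; equivalent to the scalar calculators element-wise.

    ``tau`` is a scalar or per-test array (smoothed mode only).
    """
    alphas = np.asarray(sorted_alphas, dtype=float)
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    t = np.atleast_1d(np.asarray(test_alphas, dtype=float))
    lo = np.searchsorted(alphas, t, side="left")
    hi = np.searchsorted(alphas, t, side="right")
    if mode == "standard":
        return (n - lo + 1) / (n + 1)
    if mode == "smoothed":
        greater = n - hi
        ties = hi - lo + 1
        return (greater + np.asarray(tau) * ties) / (n + 1)
    if mode == "linear-interpolated":
        knots, _ = np.unique(alphas, return_index=True)
        pk = (n - np.searchsorted(alphas, knots, side="left") + 1) / (n + 1)
        out = np.interp(t, knots, pk)
        out[t < knots[0]] = 1.0
        out[t > knots[-1]] = 1.0 / (n + 1)
        return out
    raise ValueError(f"unknown p-value mode {mode!r}")


@dataclass
class PValueCalculator:
    """Configured p-value calculation: standard, smoothed or
    linear-interpolated.

    In smoothed mode ``tau`` is either a fixed value in [0, 1] or
    ``"random"``, in which case one uniform draw is made per call from the
    seeded generator (one per (test object, class) when driven by the
    conformal layer).
    """

    mode: str = "standard"  # standard | smoothed | linear-interpolated
    tau: float | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "smoothed", "linear-interpolated"):
            raise ValueError(f"unknown p-value mode {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def __call__(self, calibration_alphas: np.ndarray, test_alpha: float) -> float:
        if self.mode == "standard":
            return pvalue_standard(calibration_alphas, test_alpha)
        if self.mode == "smoothed":
            tau = self._rng.uniform() if self.tau == "random" else float(self.tau)
            return pvalue_smoothed(calibration_alphas, test_alpha, tau)
        return pvalue_interpolated(calibration_alphas, test_alpha)
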