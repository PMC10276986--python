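"""FDR-controlling multiple-testing procedures with optional p-value weights.

This module provides the building blocks shared by every procedure in the
package:

* the Benjamini–Hochberg (BH) linear step-up procedure,
* its weighted variant (wBH), which applies the step-up rule to ``p_i / w_i``
  for non-negative weights summing to the number of hypotheses,
* the covariate-driven weight family ``w(x, a) ∝ x^{-a}`` used by the wBHa
  procedure to prioritize markers with small covariate values (e.g. low
  minor allele frequency),
* a Storey-type estimator of the true-null proportion ``pi0`` and the
  associated adaptive ("q-value") step-up procedure.

All procedures operate on plain NumPy arrays and return small result
dataclasses; tabular I/O lives in :mod:`wbha.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.special import logsumexp

__all__ = [
    "WeightVector",
    "RejectionResult",
    "Pi0Estimate",
    "bh_stepup",
    "covariate_weights",
    "weighted_bh",
    "storey_pi0",
    "qvalue_procedure",
    "DEFAULT_LAMBDA_GRID",
]

#: Default lambda grid for the Storey pi0 estimator: 0.05, 0.10, ..., 0.95.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)


@dataclass(frozen=True)
class WeightVector:
    """Per-hypothesis non-negative weights normalized to sum to ``m``.

    Attributes
    ----------
    w : ndarray
        Weight per hypothesis, ``w_i >= 0`` and ``sum(w) == len(w)`` up to
        floating-point tolerance.
    a : float or None
        Exponent of the generating family ``w(x, a) ∝ x^{-a}``; ``None`` for
        user-supplied weights that did not come from the family.
    """

    w: np.ndarray
    a: float | None = None

    def __len__(self) -> int:
        return self.w.size


@dataclass(frozen=True)
class RejectionResult:
    """Outcome of a step-up procedure at nominal FDR level ``alpha``.

    ``rejected`` is a boolean mask over the input hypotheses, ``k`` the
    number of rejections, and ``weights_used`` the weights that produced the
    decision (``None`` means unit weights).
    """

    rejected: np.ndarray
    k: int
    alpha: float
    weights_used: WeightVector | None = None


@dataclass(frozen=True)
class Pi0Estimate:
    """Smoothed estimate of the proportion of true null hypotheses."""

    pi0_hat: float
    lambda_grid: np.ndarray
    raw_estimates: np.ndarray


def _as_pvalues(p) -> np.ndarray:
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.ndim != 1:
        raise ValueError("p-values must form a one-dimensional vector")
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _as_covariate(x) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.ndim != 1 or x.size == 0:
        raise ValueError("covariate must form a non-empty one-dimensional vector")
    if not np.all(np.isfinite(x)) or np.any(x <= 0.0):
        raise ValueError("covariate values must be strictly positive and finite")
    return x


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha


def _stepup(scores: np.ndarray, alpha: float) -> tuple[np.ndarray, int]:
    """Linear step-up on arbitrary non-negative scores.

    Scores may exceed 1 (weighted p-values are not capped).  Returns the
    boolean rejection mask and k = max{i >= 0 : s_(i) <= i*alpha/m}.  Ties at
    the critical score are rejected together: tied scores share s_(i), so
    they are all among the k smallest.
    """
    m = scores.size
    order = np.argsort(scores, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(scores[order] <= thresholds)[0]
    k = 0 if passing.size == 0 else int(passing[-1]) + 1
    rejected = np.zeros(m, dtype=bool)
    if k:
        rejected[order[:k]] = True
    return rejected, k


def bh_stepup(p, alpha: float = 0.05) -> RejectionResult:
    """Benjamini–Hochberg linear step-up procedure.

    Rejects the ``k`` hypotheses with the smallest p-values, where
    ``k = max{i >= 0 : p_(i) <= i*alpha/m}`` and ``p_(i)`` are the ordered
    p-values.  Under independence (and PRDS dependence) this controls the
    FDR at ``pi0 * alpha <= alpha``.

    Parameters
    ----------
    p : array-like
        p-values in [0, 1].
    alpha : float
        Nominal FDR level in (0, 1).
    """
    p = _as_pvalues(p)
    alpha = _check_alpha(alpha)
    rejected, k = _stepup(p, alpha)
    return RejectionResult(rejected=rejected, k=k, alpha=alpha, weights_used=None)


def covariate_weights(x, a: float) -> WeightVector:
    """Weights ``w_i = m * x_i^{-a} / sum_j x_j^{-a}`` from a positive covariate.

    ``a = 0`` gives unit weights; larger ``a`` concentrates weight on the
    hypotheses with the smallest covariate values (e.g. rare variants when
    the covariate is the minor allele frequency).  Computed in log-space so
    that extreme ``a * log(x)`` never overflows.
    """
    x = _as_covariate(x)
    a = float(a)
    if not np.isfinite(a) or a < 0.0:
        raise ValueError(f"exponent a must be finite and >= 0, got {a}")
    logw = -a * np.log(x)
    logw -= logsumexp(logw)
    w = np.exp(logw + np.log(x.size))
    if not np.all(np.isfinite(w)):  # pragma: no cover - defensive
        raise FloatingPointError("non-finite weights; covariate degenerate")
    return WeightVector(w=w, a=a)


def weighted_bh(p, w, alpha: float = 0.05) -> RejectionResult:
    """Weighted Benjamini–Hochberg procedure.

    Applies the BH step-up rule to ``p_i / w_i`` where the non-negative
    weights ``w`` sum to the number of hypotheses.  A zero weight maps to an
    infinite weighted p-value: the hypothesis is never rejected.  With unit
    weights the rejected set is exactly that of :func:`bh_stepup`.

    Parameters
    ----------
    p : array-like
        p-values in [0, 1].
    w : WeightVector or array-like
        Non-negative weights with ``sum(w) == len(p)`` (relative tolerance
        1e-6, to admit weights that round-tripped through text files).
    alpha : float
        Nominal FDR level.
    """
    p = _as_pvalues(p)
    alpha = _check_alpha(alpha)
    wv = w if isinstance(w, WeightVector) else WeightVector(w=np.asarray(w, dtype=float), a=None)
    weights = np.atleast_1d(np.asarray(wv.w, dtype=float))
    if weights.shape != p.shape:
        raise ValueError(
            f"length mismatch: {p.size} p-values vs {weights.size} weights"
        )
    if not np.all(np.isfinite(weights)) or np.any(weights < 0.0):
        raise ValueError("weights must be finite and non-negative")
    m = p.size
    if abs(weights.sum() - m) > 1e-6 * m:
        raise ValueError(
            f"weights must sum to the number of hypotheses ({m}), got {weights.sum():g}"
        )
    ratios = np.full(m, np.inf)
    positive = weights > 0.0
    ratios[positive] = p[positive] / weights[positive]
    rejected, k = _stepup(ratios, alpha)
    return RejectionResult(rejected=rejected, k=k, alpha=alpha, weights_used=wv)


def storey_pi0(p, lambda_grid=None) -> Pi0Estimate:
    """Storey-type estimate of the true-null proportion ``pi0``.

    For each grid value ``lambda`` the raw estimate is
    ``#{p_i > lambda} / (m * (1 - lambda))``; a cubic smoothing spline
    through the raw estimates is evaluated at the largest grid value and
    clipped to (0, 1].  With fewer than 20 p-values the spline has no
    support and the estimator falls back to the conservative ``pi0 = 1``.
    """
    p = _as_pvalues(p)
    if lambda_grid is None:
        grid = DEFAULT_LAMBDA_GRID.copy()
    else:
        grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
        if grid.size < 4:
            raise ValueError("lambda grid needs at least 4 points for a cubic spline")
        if np.any(np.diff(grid) <= 0) or grid[0] <= 0.0 or grid[-1] >= 1.0:
            raise ValueError("lambda grid must be strictly increasing within (0, 1)")
    m = p.size
    raw = np.array([np.count_nonzero(p > lam) / (m * (1.0 - lam)) for lam in grid])
    if m < 20:
        warnings.warn(
            f"only {m} p-values: falling back to conservative pi0 = 1", stacklevel=2
        )
        pi0 = 1.0
    else:
        spline = UnivariateSpline(grid, raw, k=3)
        pi0 = float(spline(grid[-1]))
        if pi0 <= 0.0:
            warnings.warn("non-positive smoothed pi0 estimate; clipping", stacklevel=2)
        pi0 = float(min(max(pi0, 1e-8), 1.0))
    return Pi0Estimate(pi0_hat=pi0, lambda_grid=grid, raw_estimates=raw)


def qvalue_procedure(p, alpha: float = 0.05, lambda_grid=None) -> RejectionResult:
    """Adaptive BH step-up at the effective level ``alpha / pi0_hat``.

    Equivalent to rejecting hypotheses with Storey q-value <= alpha.  Since
    ``pi0_hat <= 1`` the procedure never rejects fewer hypotheses than
    :func:`bh_stepup` at the same nominal level.
    """
    p = _as_pvalues(p)
    alpha = _check_alpha(alpha)
    estimate = storey_pi0(p, lambda_grid=lambda_grid)
    # effective level may exceed 1 when pi0_hat is tiny; the step-up rule
    # handles that naturally, so no clipping is applied here.
    rejected, k = _stepup(p, alpha / estimate.pi0_hat)
    return RejectionResult(rejected=rejected, k=k, alpha=alpha, weights_used=None)
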