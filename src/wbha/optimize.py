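"""Data-adaptive choice of the weight exponent ``a`` (the wBHa procedure).

The weight family ``w(x, a) ∝ x^{-a}`` leaves one free parameter.  The
optimizer picks it by maximizing the number of weighted-BH rejections over a
grid of exponents, with a tie-breaking cascade for plateaus, and stabilizes
the choice by bagging: K bootstrap subsamples of ``m/K`` hypotheses are
drawn with replacement, the grid search runs on each, and the final
exponent is the mean of the K per-round winners.

Throughout — inside bagging rounds as well as in the final weighted-BH
pass — the weight of a hypothesis is its weight in the full-set family
``w_i = m x_i^{-a} / sum_j x_j^{-a}`` with the sum over all m hypotheses:
each round thereby scores the behaviour of the actual procedure on a
subsample, rather than of a re-normalized surrogate.  This matters: were
weights re-normalized within each small subsample, exponents whose weight
mass concentrates on hypotheses outside the subsample would keep scoring
rejections they could never produce on the full data, biasing the selected
exponent upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .procedures import (
    RejectionResult,
    _as_covariate,
    _as_pvalues,
    _check_alpha,
    covariate_weights,
    weighted_bh,
)

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "rejections_over_grid",
    "tie_break_a",
    "naive_optimal_a",
    "bagging_optimize",
    "wbha",
    "DEFAULT_EXPONENT_GRID",
]

#: Default exponent grid 0, 0.1, ..., 10.
DEFAULT_EXPONENT_GRID = np.round(np.arange(0.0, 10.0001, 0.1), 10)


@dataclass
class OptimizerConfig:
    """Configuration of the bagged grid search for the exponent ``a``.

    Parameters
    ----------
    grid : ndarray
        Strictly increasing exponent grid with (approximately) constant
        step; default 0 to 10 in steps of 0.1.
    K : int
        Number of bagging rounds (default 100).
    sample_size : int or None
        Hypotheses drawn per round; ``None`` means ``max(1, floor(m / K))``.
    alpha : float
        Nominal FDR level used inside the grid search and in the final
        weighted-BH pass.
    seed : int or None
        Root seed; round ``k`` uses an independently derived substream, so
        changing ``K`` does not reshuffle earlier rounds.
    sampling : {"bootstrap", "identity"}
        "bootstrap" draws with replacement; "identity" uses every
        hypothesis exactly once per round, which with ``K=1`` reduces
        bagging to the naive full-data grid search.
    """

    grid: np.ndarray = field(default_factory=lambda: DEFAULT_EXPONENT_GRID.copy())
    K: int = 100
    sample_size: int | None = None
    alpha: float = 0.05
    seed: int | None = None
    sampling: str = "bootstrap"

    def __post_init__(self) -> None:
        self.grid = np.atleast_1d(np.asarray(self.grid, dtype=float))
        if self.grid.size == 0:
            raise ValueError("exponent grid must be non-empty")
        if np.any(self.grid < 0) or not np.all(np.isfinite(self.grid)):
            raise ValueError("exponent grid values must be finite and >= 0")
        diffs = np.diff(self.grid)
        if diffs.size:
            if np.any(diffs <= 0):
                raise ValueError("exponent grid must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
                raise ValueError("exponent grid must have a constant step")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        self.alpha = _check_alpha(self.alpha)
        if self.sampling not in ("bootstrap", "identity"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 0.0


@dataclass(frozen=True)
class OptimizationTrace:
    """Per-round record of the bagged grid search.

    ``a_rounds[k]`` is the winning exponent of round ``k`` (always a grid
    element); ``rejections[k, j]`` the weighted-BH rejection count of grid
    value ``j`` in round ``k``; ``final_a`` the arithmetic mean of the round
    winners, which need not itself lie on the grid.
    """

    a_rounds: np.ndarray
    rejections: np.ndarray
    grid: np.ndarray
    final_a: float


def _stepup_counts_from_logw(p, logw, alpha: float) -> np.ndarray:
    """Step-up rejection counts per grid row given per-row log-weights."""
    m = p.size
    with np.errstate(over="ignore"):
        ratios = p[None, :] * np.exp(-logw)
    ratios = np.where(np.isnan(ratios), 0.0, ratios)  # p = 0 against w -> 0
    sorted_ratios = np.sort(ratios, axis=1)
    thresholds = alpha * np.arange(1, m + 1) / m
    passing = sorted_ratios <= thresholds[None, :]
    any_pass = passing.any(axis=1)
    counts = np.where(any_pass, m - passing[:, ::-1].argmax(axis=1), 0)
    return counts.astype(int)


def rejections_over_grid(p, x, grid=None, alpha: float = 0.05) -> np.ndarray:
    """Weighted-BH rejection counts for every exponent on the grid.

    Weights are computed (and normalized) over the supplied hypothesis
    set, in log-space for numerical safety; the step-up rule is applied to
    the weighted p-values ``p_i / w_i`` for every grid value at once.

    Returns an integer array ``counts`` with
    ``counts[j] = #rejections at a = grid[j]``.
    """
    p = _as_pvalues(p)
    x = _as_covariate(x)
    if x.shape != p.shape:
        raise ValueError("p-values and covariate must have the same length")
    alpha = _check_alpha(alpha)
    grid = DEFAULT_EXPONENT_GRID if grid is None else np.atleast_1d(np.asarray(grid, dtype=float))
    logx = np.log(x)
    logw = -grid[:, None] * logx[None, :]
    logw = logw - logsumexp(logw, axis=1, keepdims=True) + np.log(p.size)
    return _stepup_counts_from_logw(p, logw, alpha)


def tie_break_a(A, grid_step: float) -> float:
    """Resolve ties between exponents that maximize the rejection count.

    ``A`` holds the (sorted, possibly duplicated) maximizing grid values.
    They are split into runs of consecutive grid points wherever the gap
    between neighbours exceeds the grid step.  A single run returns its
    maximum; otherwise the longest run wins (maximum returned); runs tied
    for length are ranked by the distance of their closest endpoint to 1,
    the larger maximum breaking any remaining tie.
    """
    A = np.unique(np.asarray(A, dtype=float))
    if A.size == 0:
        raise ValueError("empty maximizer set")
    if A.size == 1:
        return float(A[0])
    # a gap of one grid step keeps values in the same run; use 1.5 steps as
    # the cut so floating-point drift on the grid cannot split a run.
    cut = grid_step * 1.5 if grid_step > 0 else 0.0
    breaks = np.nonzero(np.diff(A) > cut)[0]
    runs = np.split(A, breaks + 1)
    if len(runs) == 1:
        return float(A[-1])
    longest = max(len(r) for r in runs)
    candidates = [r for r in runs if len(r) == longest]
    if len(candidates) == 1:
        return float(candidates[0][-1])
    best = min(
        candidates,
        key=lambda r: (min(abs(r[0] - 1.0), abs(r[-1] - 1.0)), -r[-1]),
    )
    return float(best[-1])


def naive_optimal_a(p, x, grid=None, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Full-data grid search: the exponent maximizing rejections, after ties.

    Returns ``(a, counts)`` where ``counts`` are the per-grid-value
    rejection counts.  When no exponent achieves a single rejection the
    search is uninformative and the neutral exponent 0 (unit weights) is
    returned; the tie-breaking cascade only arbitrates between exponents
    that actually maximize a nontrivial rejection count.
    """
    grid = DEFAULT_EXPONENT_GRID if grid is None else np.atleast_1d(np.asarray(grid, dtype=float))
    counts = rejections_over_grid(p, x, grid, alpha)
    best = counts.max()
    if best == 0:
        return 0.0, counts
    winners = grid[counts == best]
    step = float(grid[1] - grid[0]) if grid.size > 1 else 0.0
    return tie_break_a(winners, step), counts


def bagging_optimize(p, x, config: OptimizerConfig | None = None) -> OptimizationTrace:
    """Bagged grid search for the exponent ``a``.

    Each of the ``K`` rounds draws ``sample_size`` hypotheses (p-value and
    covariate jointly) with replacement, applies the weighted step-up to
    the subsample — using each hypothesis's *full-set* weight
    ``m x_i^{-a} / sum_j x_j^{-a}`` — and records the tie-broken winner
    among the exponents maximizing the rejection count.  A round that
    rejects nothing at every exponent is uninformative and contributes the
    neutral exponent 0 — without this rule, sparse-signal studies (where
    most small subsamples contain no signal) would drive the averaged
    exponent toward the top of the grid and degrade overall power.  The
    final exponent is the mean of the round winners.  Fully reproducible
    given ``config.seed``.
    """
    p = _as_pvalues(p)
    x = _as_covariate(x)
    if x.shape != p.shape:
        raise ValueError("p-values and covariate must have the same length")
    config = config or OptimizerConfig()
    m = p.size
    size = config.sample_size if config.sample_size is not None else max(1, m // config.K)
    grid = config.grid
    logx = np.log(x)
    # full-set log-normalizer log(sum_j x_j^{-a}) per grid value; row-wise
    # to keep memory linear in m
    lognorm = np.array([logsumexp(-a * logx) for a in grid])
    children = np.random.SeedSequence(config.seed).spawn(config.K)
    a_rounds = np.empty(config.K)
    rejections = np.empty((config.K, grid.size), dtype=int)
    for k in range(config.K):
        rng = np.random.default_rng(children[k])
        if config.sampling == "identity":
            idx = np.arange(m)
        else:
            idx = rng.integers(0, m, size=size)
        logw = -grid[:, None] * logx[idx][None, :] - lognorm[:, None] + np.log(m)
        counts = _stepup_counts_from_logw(p[idx], logw, config.alpha)
        best = counts.max()
        if best == 0:
            a_rounds[k] = 0.0
        else:
            winners = grid[counts == best]
            a_rounds[k] = tie_break_a(winners, config.grid_step)
        rejections[k] = counts
    return OptimizationTrace(
        a_rounds=a_rounds,
        rejections=rejections,
        grid=config.grid.copy(),
        final_a=float(a_rounds.mean()),
    )


def wbha(
    p, x, alpha: float | None = None, config: OptimizerConfig | None = None
) -> tuple[RejectionResult, OptimizationTrace]:
    """The wBHa procedure: bagged exponent selection, then weighted BH.

    Parameters
    ----------
    p : array-like
        p-values in [0, 1].
    x : array-like
        Strictly positive informative covariate (e.g. minor allele
        frequency) — hypotheses with small covariate values are prioritized.
    alpha : float, optional
        Nominal FDR level; overrides ``config.alpha`` when given.
    config : OptimizerConfig, optional
        Grid, bagging and seeding parameters.

    Returns
    -------
    (RejectionResult, OptimizationTrace)
        The rejection decision at level alpha with weights
        ``w(x, final_a)`` normalized over all hypotheses, and the per-round
        optimization record.
    """
    config = config or OptimizerConfig()
    if alpha is not None:
        config = replace(config, alpha=_check_alpha(alpha))
    trace = bagging_optimize(p, x, config)
    weights = covariate_weights(x, trace.final_a)
    result = weighted_bh(p, weights, config.alpha)
    return result, trace
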