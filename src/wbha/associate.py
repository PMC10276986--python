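"""Single-marker association scans.

Each marker is tested marginally against the phenotype: a simple linear
regression with a two-sided t-test on the slope for quantitative traits,
and a per-marker logistic regression with a two-sided Wald test for binary
traits.  Both scans are fully vectorized across markers — the quantitative
scan through the closed-form simple-regression identities, the binary scan
through a batched two-parameter Newton–Raphson — which is what makes
replicated genome-scale simulation studies tractable.

Results are returned as a :class:`pandas.DataFrame` with one row per
marker (columns ``marker_id``, ``p``, ``beta``, ``se``, ``maf``), directly
consumable by the multiple-testing procedures with the observed minor
allele frequency as the informative covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["observed_maf", "scan_quantitative", "scan_binary"]


def observed_maf(G) -> np.ndarray:
    """Observed minor allele frequency per marker of a 0/1/2 matrix."""
    G = np.asarray(G)
    freq = G.mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def _marker_ids(m: int) -> np.ndarray:
    width = len(str(m))
    return np.array([f"snp{j + 1:0{width}d}" for j in range(m)], dtype=object)


def _check_genotypes(G) -> np.ndarray:
    G = np.asarray(G)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be two-dimensional (individuals x markers)")
    return G


def scan_quantitative(G, y) -> pd.DataFrame:
    """Per-marker simple linear regression of a quantitative phenotype.

    For marker ``j`` fits ``y ~ intercept + G_j`` and reports the two-sided
    t-test p-value on the slope.  Monomorphic markers carry no information
    and get ``p = 1`` (with a warning).  p-values are invariant to affine
    rescaling of ``y``.
    """
    G = _check_genotypes(G)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n, m = G.shape
    if y.size != n:
        raise ValueError("phenotype length must equal the number of individuals")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    Gf = G.astype(np.float64, copy=False)
    gmean = Gf.mean(axis=0)
    yc = y - y.mean()
    sxy = yc @ Gf
    sxx = np.einsum("ij,ij->j", Gf, Gf) - n * gmean**2
    syy = float(yc @ yc)
    dof = n - 2
    monomorphic = sxx <= 0.0
    if monomorphic.any():
        warnings.warn(
            f"{int(monomorphic.sum())} monomorphic marker(s): p-value set to 1",
            stacklevel=2,
        )
    safe_sxx = np.where(monomorphic, 1.0, sxx)
    slope = sxy / safe_sxx
    sse = np.maximum(syy - sxy**2 / safe_sxx, 0.0)
    se = np.sqrt(sse / dof / safe_sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    pvalues = 2.0 * stats.t.sf(np.abs(t), dof)
    pvalues = np.where(np.isnan(pvalues), 1.0, pvalues)
    slope[monomorphic] = 0.0
    se[monomorphic] = np.nan
    pvalues[monomorphic] = 1.0
    return pd.DataFrame(
        {
            "marker_id": _marker_ids(m),
            "p": pvalues,
            "beta": slope,
            "se": se,
            "maf": observed_maf(G),
        }
    )


def scan_binary(G, y, max_iter: int = 25, tol: float = 1e-8) -> pd.DataFrame:
    """Per-marker logistic regression of a case/control phenotype.

    For marker ``j`` fits ``logit P(y = 1) = b0 + b1 G_j`` by a batched
    Newton–Raphson and reports the two-sided Wald p-value on ``b1``.
    Monomorphic markers, non-converged fits and (quasi-)separated markers
    are conservatively reported with ``p = 1`` and a warning.
    """
    G = _check_genotypes(G)
    y = np.atleast_1d(np.asarray(y))
    n, m = G.shape
    if y.size != n:
        raise ValueError("phenotype length must equal the number of individuals")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("binary phenotype must be coded 0/1")
    if classes.size < 2:
        raise ValueError("binary phenotype must contain both classes")
    yf = y.astype(np.float64)
    Gf = G.astype(np.float64, copy=False)
    monomorphic = Gf.var(axis=0) == 0.0
    ybar = yf.mean()
    b0 = np.full(m, np.log(ybar / (1.0 - ybar)))
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    i00 = i01 = i11 = det = None
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + Gf * b1[None, :], -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        resid = yf[:, None] - mu
        weight = mu * (1.0 - mu)
        u0 = resid.sum(axis=0)
        u1 = np.einsum("ij,ij->j", Gf, resid)
        i00 = weight.sum(axis=0)
        i01 = np.einsum("ij,ij->j", weight, Gf)
        i11 = np.einsum("ij,ij->j", weight, Gf * Gf)
        det = i00 * i11 - i01**2
        bad = det <= 1e-12
        safe_det = np.where(bad, 1.0, det)
        d0 = np.where(bad, 0.0, (i11 * u0 - i01 * u1) / safe_det)
        d1 = np.where(bad, 0.0, (-i01 * u0 + i00 * u1) / safe_det)
        b0 += d0
        b1 += d1
        converged = np.maximum(np.abs(d0), np.abs(d1)) < tol
        if converged.all():
            break
    failed = monomorphic | ~converged | (det <= 1e-12) | (np.abs(b1) > 15.0)
    if (failed & ~monomorphic).any():
        warnings.warn(
            f"{int((failed & ~monomorphic).sum())} logistic fit(s) did not "
            "converge (possible separation): p-value set to 1",
            stacklevel=2,
        )
    safe_det = np.where(det <= 1e-12, 1.0, det)
    se = np.sqrt(i00 / safe_det)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    pvalues = np.where(failed | np.isnan(pvalues), 1.0, pvalues)
    b1 = np.where(failed, 0.0, b1)
    se = np.where(failed, np.nan, se)
    return pd.DataFrame(
        {
            "marker_id": _marker_ids(m),
            "p": pvalues,
            "beta": b1,
            "se": se,
            "maf": observed_maf(G),
        }
    )
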