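"""GWAS genotype–phenotype simulator with LD-like block correlation.

The generative model mimics the statistical structure of a genome-wide
association study:

* latent marker values for each individual are multivariate normal with a
  block-diagonal equicorrelation structure (blocks of ``block_size``
  markers equicorrelated at level ``rho``), simulated with the one-factor
  construction ``sqrt(rho) * Z_block + sqrt(1 - rho) * Z_marker`` so the
  full covariance matrix is never materialized;
* latent values are discretized into additive genotypes 0/1/2 at the
  quantiles implied by Hardy–Weinberg equilibrium, so genotype
  frequencies are (p^2, 2pq, q^2) for minor allele frequency p;
* null-marker MAFs are U[0.01, 0.5]; causal markers are split into four
  MAF groups — rare U[0.01, 0.05], medium-rare U[0.05, 0.15], medium
  U[0.15, 0.25] and common U[0.30, 0.40] — with ``m1 // 4`` markers per
  group and the remainder added to the common group;
* per-group effect sizes follow three scenarios (rare variants with the
  largest, the smallest, or equal effects);
* quantitative traits are ``y = G beta + eps`` with the residual variance
  solved from a target coefficient of determination R^2; binary traits are
  Bernoulli draws from a logistic model whose intercept is calibrated to a
  balanced case/control split.

A user-supplied genotype matrix can replace the simulated genotypes, in
which case causal markers are drawn from observed-MAF bins; this covers
semi-simulations seeded from real genotype data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtri

__all__ = [
    "GROUPS",
    "CAUSAL_MAF_RANGES",
    "EFFECT_TABLE",
    "SimulationDesign",
    "SimulatedStudy",
    "causal_group_sizes",
    "assign_mafs",
    "simulate_genotypes",
    "assign_effects",
    "residual_variance",
    "simulate_quantitative_trait",
    "calibrate_intercept",
    "simulate_binary_trait",
    "simulate_study",
]

#: Causal MAF groups ordered from rarest to most common.
GROUPS = ("rare", "medium-rare", "medium", "common")

#: MAF sampling range per causal group.
CAUSAL_MAF_RANGES = {
    "rare": (0.01, 0.05),
    "medium-rare": (0.05, 0.15),
    "medium": (0.15, 0.25),
    "common": (0.30, 0.40),
}

#: Observed-MAF bin edges used to classify markers of a user-supplied
#: genotype matrix into the four causal groups (upper bin is open-ended).
PLUGIN_MAF_BINS = (0.01, 0.05, 0.15, 0.30)

NULL_MAF_RANGE = (0.01, 0.5)

#: Effect sizes per (trait, scenario), ordered rare -> common.  Scenario 1:
#: rare variants carry the largest effects; scenario 2 reverses the
#: ordering; scenario 3 gives all causal variants the same effect.
EFFECT_TABLE = {
    "quantitative": {
        1: (4.0, 3.0, 2.0, 1.0),
        2: (1.0, 2.0, 3.0, 4.0),
        3: (2.0, 2.0, 2.0, 2.0),
    },
    "binary": {
        1: tuple(np.log([2.2, 1.8, 1.5, 1.3])),
        2: tuple(np.log([1.3, 1.5, 1.8, 2.2])),
        3: tuple(np.log([1.5, 1.5, 1.5, 1.5])),
    },
}


@dataclass
class SimulationDesign:
    """Full generative configuration of one simulated study."""

    n: int = 2000
    m: int = 8000
    m1: int = 25
    rho: float = 0.0
    block_size: int = 10
    trait: str = "quantitative"
    scenario: int = 1
    r_squared: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 individuals")
        if self.m < 1:
            raise ValueError("need at least 1 marker")
        if not 0 <= self.m1 <= self.m:
            raise ValueError("m1 must satisfy 0 <= m1 <= m")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.trait not in EFFECT_TABLE:
            raise ValueError(f"trait must be one of {tuple(EFFECT_TABLE)}")
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if not 0.0 < self.r_squared < 1.0:
            raise ValueError("r_squared must lie in (0, 1)")


@dataclass
class SimulatedStudy:
    """One realized dataset: genotypes, truth labels and phenotype."""

    G: np.ndarray  # (n, m) int8 additive genotypes
    maf: np.ndarray  # design MAF per marker
    beta: np.ndarray  # effect size per marker (0 for null markers)
    y: np.ndarray  # phenotype (real, or 0/1 for binary traits)
    is_causal: np.ndarray  # bool per marker
    maf_group: np.ndarray  # group label per marker ("null" for non-causal)
    design: SimulationDesign = field(repr=False, default=None)


def causal_group_sizes(m1: int) -> tuple[int, int, int, int]:
    """Euclidean split of ``m1`` causal markers over the four MAF groups.

    Each group gets ``m1 // 4`` markers; the remainder goes to the common
    group.
    """
    q, r = divmod(m1, 4)
    return (q, q, q, q + r)


def assign_mafs(design: SimulationDesign, rng=None):
    """Draw per-marker design MAFs, causal positions and group labels.

    Null MAFs are U[0.01, 0.5]; causal positions are drawn uniformly
    without replacement and their MAFs re-drawn from the group-specific
    ranges.

    Returns
    -------
    (maf, causal_idx, maf_group)
        ``maf`` has length ``m``; ``causal_idx`` the ``m1`` causal marker
        indices (in assignment order rare -> common); ``maf_group`` a
        length-``m`` label array with "null" for non-causal markers.
    """
    rng = np.random.default_rng(rng if rng is not None else design.seed)
    maf = rng.uniform(*NULL_MAF_RANGE, size=design.m)
    causal = rng.choice(design.m, size=design.m1, replace=False)
    labels = np.full(design.m, "null", dtype=object)
    pos = 0
    for group, size in zip(GROUPS, causal_group_sizes(design.m1)):
        idx = causal[pos : pos + size]
        lo, hi = CAUSAL_MAF_RANGES[group]
        maf[idx] = rng.uniform(lo, hi, size=size)
        labels[idx] = group
        pos += size
    return maf, causal, labels


def simulate_genotypes(
    design: SimulationDesign, maf, rng=None, return_latent: bool = False
) -> np.ndarray:
    """Simulate additive 0/1/2 genotypes under HWE with block correlation.

    Latent values follow an m-dimensional normal with block-diagonal
    equicorrelation at level ``design.rho``; each marker is discretized at
    the quantiles ``ndtri(p^2)`` and ``ndtri(1 - (1-p)^2)`` so that the
    expected genotype frequencies are (p^2, 2pq, q^2).
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if maf.size != design.m:
        raise ValueError("maf vector length must equal design.m")
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("MAF values must lie in (0, 0.5]")
    rng = np.random.default_rng(rng if rng is not None else design.seed)
    n, m, B, rho = design.n, design.m, design.block_size, design.rho
    z = rng.standard_normal((n, m))
    if rho > 0.0:
        n_blocks = math.ceil(m / B)
        factors = rng.standard_normal((n, n_blocks))
        latent = math.sqrt(1.0 - rho) * z
        latent += math.sqrt(rho) * np.repeat(factors, B, axis=1)[:, :m]
    else:
        latent = z
    t_lower = ndtri(maf**2)  # below: homozygous minor (G = 2)
    t_upper = ndtri(1.0 - (1.0 - maf) ** 2)  # above: homozygous major (G = 0)
    G = (latent < t_lower).astype(np.int8)
    G += latent < t_upper
    if return_latent:
        return G, latent
    return G


def assign_effects(design: SimulationDesign, maf_group) -> np.ndarray:
    """Per-marker effect sizes from the scenario table; 0 for null markers."""
    maf_group = np.asarray(maf_group, dtype=object)
    effects = EFFECT_TABLE[design.trait][design.scenario]
    beta = np.zeros(maf_group.size)
    for group, value in zip(GROUPS, effects):
        beta[maf_group == group] = value
    return beta


def residual_variance(score, r_squared: float) -> float:
    """Residual variance matching a target coefficient of determination.

    ``sigma^2 = (1 - R^2) * sum((s - mean(s))^2) / (R^2 * (n - 2))`` for
    the genetic score ``s = G beta``.  A constant score (no genetic signal)
    leaves the target unattainable; the variance falls back to 1 with a
    warning, giving a pure-noise phenotype.
    """
    score = np.atleast_1d(np.asarray(score, dtype=float))
    n = score.size
    if n < 3:
        raise ValueError("need at least 3 individuals to calibrate the variance")
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must lie in (0, 1)")
    ss = float(np.sum((score - score.mean()) ** 2))
    if ss == 0.0:
        warnings.warn(
            "constant genetic score: residual variance set to 1 (pure noise)",
            stacklevel=2,
        )
        return 1.0
    return (1.0 - r_squared) * ss / (r_squared * (n - 2))


def _genetic_score(G, beta) -> np.ndarray:
    G = np.asarray(G)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != G.shape[1]:
        raise ValueError("beta length must equal the number of markers")
    causal = beta != 0.0
    if not causal.any():
        return np.zeros(G.shape[0])
    return G[:, causal].astype(float) @ beta[causal]


def simulate_quantitative_trait(G, beta, r_squared: float = 0.2, rng=None) -> np.ndarray:
    """Quantitative phenotype ``y = G beta + eps`` at target R^2."""
    rng = np.random.default_rng(rng)
    score = _genetic_score(G, beta)
    sigma2 = residual_variance(score, r_squared)
    return score + rng.normal(0.0, math.sqrt(sigma2), size=score.size)


def calibrate_intercept(score) -> float:
    """Logistic intercept giving mean predicted prevalence 0.5.

    Solves ``mean(expit(b0 + s)) = 0.5`` on the realized genetic scores by
    root bracketing; the mean is strictly increasing in ``b0`` so the root
    is unique.
    """
    score = np.atleast_1d(np.asarray(score, dtype=float))
    limit = float(np.abs(score).max()) + 40.0 if score.size else 40.0

    def gap(b0: float) -> float:
        return float(expit(b0 + score).mean() - 0.5)

    return brentq(gap, -limit, limit, xtol=1e-12)


def simulate_binary_trait(G, beta, rng=None) -> np.ndarray:
    """Case/control phenotype from a logistic model with balanced prevalence."""
    rng = np.random.default_rng(rng)
    score = _genetic_score(G, beta)
    b0 = calibrate_intercept(score)
    prob = expit(b0 + score)
    return (rng.random(score.size) < prob).astype(np.int8)


def _assign_causal_from_observed(maf, m1: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Causal positions and labels for a user-supplied genotype matrix.

    Markers are binned by observed MAF (0.01–0.05, 0.05–0.15, 0.15–0.30,
    >= 0.30) and causal markers drawn per bin in the same proportions as
    for fully simulated data.
    """
    maf = np.asarray(maf, dtype=float)
    edges = (*PLUGIN_MAF_BINS, np.inf)
    labels = np.full(maf.size, "null", dtype=object)
    causal: list[np.ndarray] = []
    for group, size, lo, hi in zip(GROUPS, causal_group_sizes(m1), edges[:-1], edges[1:]):
        eligible = np.nonzero((maf >= lo) & (maf < hi) & (labels == "null"))[0]
        if eligible.size < size:
            raise ValueError(
                f"genotype matrix has only {eligible.size} markers with MAF in "
                f"[{lo}, {hi}) but {size} causal {group} markers are required"
            )
        chosen = rng.choice(eligible, size=size, replace=False)
        labels[chosen] = group
        causal.append(chosen)
    return np.concatenate(causal) if causal else np.empty(0, dtype=int), labels


def simulate_study(design: SimulationDesign, genotypes=None) -> SimulatedStudy:
    """Generate one complete study (genotypes, effects, phenotype, truth).

    Composes MAF assignment, genotype simulation, effect assignment and
    phenotype generation; bit-reproducible given ``design.seed``.  When a
    ``genotypes`` matrix (individuals x markers, additive 0/1/2 coding) is
    supplied, it replaces the simulated genotypes: MAFs are computed from
    the matrix and causal markers drawn from observed-MAF bins.
    """
    streams = np.random.SeedSequence(design.seed).spawn(3)
    maf_rng, geno_rng, pheno_rng = (np.random.default_rng(s) for s in streams)
    if genotypes is None:
        maf, _, labels = assign_mafs(design, maf_rng)
        G = simulate_genotypes(design, maf, geno_rng)
    else:
        G = np.asarray(genotypes)
        if G.ndim != 2:
            raise ValueError("genotype matrix must be two-dimensional")
        if not np.isin(G, (0, 1, 2)).all():
            raise ValueError("genotype entries must be coded 0/1/2")
        if G.shape != (design.n, design.m):
            raise ValueError(
                f"genotype matrix shape {G.shape} does not match design "
                f"(n={design.n}, m={design.m})"
            )
        G = G.astype(np.int8)
        freq = G.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        _, labels = _assign_causal_from_observed(maf, design.m1, maf_rng)
    beta = assign_effects(design, labels)
    if design.trait == "quantitative":
        y = simulate_quantitative_trait(G, beta, design.r_squared, pheno_rng)
    else:
        y = simulate_binary_trait(G, beta, pheno_rng)
    return SimulatedStudy(
        G=G,
        maf=maf,
        beta=beta,
        y=y,
        is_causal=np.asarray(labels, dtype=object) != "null",
        maf_group=labels,
        design=design,
    )
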