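"""Power and FDR estimation over replicated simulated studies.

Per replicate, rejection decisions are cross-tabulated against the causal
truth labels (Table-of-outcomes counts TP/FP/TN/FN).  With correlated
markers, single-marker truth is ambiguous — one causal marker drags its
neighbours to significance — so counting switches to *cluster* units:
connected components of markers whose pairwise |Pearson correlation| meets
a threshold (default 0.8).  A cluster is causal if it contains a causal
marker and rejected if any member is rejected.

Summaries report, per procedure, the empirical mean (and standard error)
over replicates of:

* overall power  E[TP / m1],
* per-MAF-subgroup power  E[TP_g / m1_g]  (g = rare ... common),
* the false discovery proportion FP / max(R, 1), whose mean estimates the
  FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .associate import scan_binary, scan_quantitative
from .optimize import OptimizerConfig, wbha
from .procedures import bh_stepup, covariate_weights, qvalue_procedure, weighted_bh
from .simulate import GROUPS, SimulationDesign, simulate_study

__all__ = [
    "EvaluationCounts",
    "ReplicateOutcome",
    "confusion_counts",
    "cluster_markers",
    "replicate_outcome",
    "power_estimates",
    "run_study",
    "PROCEDURES",
]


@dataclass(frozen=True)
class EvaluationCounts:
    """TP/FP/TN/FN cross-tabulation at marker or cluster granularity."""

    tp: int
    fp: int
    tn: int
    fn: int
    granularity: str = "marker"

    @property
    def n_units(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def r(self) -> int:
        """Number of rejected units."""
        return self.tp + self.fp

    @property
    def fdp(self) -> float:
        """False discovery proportion FP / max(R, 1)."""
        return self.fp / max(self.r, 1)


@dataclass(frozen=True)
class ReplicateOutcome:
    """One replicate's counts plus per-MAF-group true-positive tallies."""

    counts: EvaluationCounts
    group_tp: np.ndarray  # length 4, ordered as GROUPS
    group_m1: np.ndarray  # length 4


def _cluster_reduce(values: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Logical-or of a boolean marker property within each cluster."""
    _, inverse = np.unique(clusters, return_inverse=True)
    out = np.zeros(inverse.max() + 1, dtype=bool)
    np.logical_or.at(out, inverse, values)
    return out


def confusion_counts(rejected, is_causal, clusters=None) -> EvaluationCounts:
    """Cross-tabulate rejections against truth labels.

    With ``clusters`` (a cluster id per marker) the tabulation runs over
    cluster units: a cluster counts as causal if it contains at least one
    causal marker and as rejected if at least one member is rejected.
    """
    rejected = np.atleast_1d(np.asarray(rejected, dtype=bool))
    is_causal = np.atleast_1d(np.asarray(is_causal, dtype=bool))
    if rejected.shape != is_causal.shape:
        raise ValueError("rejected and is_causal must have the same length")
    granularity = "marker"
    if clusters is not None:
        clusters = np.atleast_1d(np.asarray(clusters))
        if clusters.shape != rejected.shape:
            raise ValueError("clusters must assign a label to every marker")
        rejected = _cluster_reduce(rejected, clusters)
        is_causal = _cluster_reduce(is_causal, clusters)
        granularity = "cluster"
    tp = int(np.count_nonzero(rejected & is_causal))
    fp = int(np.count_nonzero(rejected & ~is_causal))
    fn = int(np.count_nonzero(~rejected & is_causal))
    tn = int(np.count_nonzero(~rejected & ~is_causal))
    return EvaluationCounts(tp=tp, fp=fp, tn=tn, fn=fn, granularity=granularity)


def _components_from_corr(corr: np.ndarray, threshold: float) -> np.ndarray:
    adj = np.abs(np.nan_to_num(corr, nan=0.0)) >= threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def cluster_markers(G=None, corr=None, threshold: float = 0.8, blocks=None) -> np.ndarray:
    """Partition markers into clusters of empirically correlated markers.

    Clusters are the connected components of the graph joining marker
    pairs with ``|r| >= threshold`` (Pearson correlation on the 0/1/2
    codes).  When a block structure is declared — ``blocks`` as an integer
    block size or an explicit block id per marker — correlations are only
    computed within blocks, which keeps the cost linear in the number of
    markers; otherwise the scan is genome-wide.

    Returns an integer cluster id per marker.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if (G is None) == (corr is None):
        raise ValueError("provide exactly one of G or corr")
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        return _components_from_corr(corr, threshold)
    G = np.asarray(G)
    m = G.shape[1]
    if blocks is None:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(G.astype(float), rowvar=False)
        return _components_from_corr(np.atleast_2d(corr), threshold)
    if np.isscalar(blocks):
        block_ids = np.arange(m) // int(blocks)
    else:
        block_ids = np.atleast_1d(np.asarray(blocks))
        if block_ids.size != m:
            raise ValueError("blocks must assign a block id to every marker")
    labels = np.empty(m, dtype=int)
    offset = 0
    for block in np.unique(block_ids):
        idx = np.nonzero(block_ids == block)[0]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(G[:, idx].astype(float), rowvar=False)
        local = _components_from_corr(np.atleast_2d(corr), threshold)
        labels[idx] = local + offset
        offset += local.max() + 1
    return labels


def replicate_outcome(rejected, is_causal, maf_group, clusters=None) -> ReplicateOutcome:
    """Counts plus subgroup tallies for one replicate.

    Subgroup power stays marker-anchored under clustering: a causal marker
    counts as detected when any member of its cluster is rejected.
    """
    rejected = np.atleast_1d(np.asarray(rejected, dtype=bool))
    is_causal = np.atleast_1d(np.asarray(is_causal, dtype=bool))
    maf_group = np.atleast_1d(np.asarray(maf_group, dtype=object))
    counts = confusion_counts(rejected, is_causal, clusters)
    if clusters is None:
        detected = rejected
    else:
        clusters = np.atleast_1d(np.asarray(clusters))
        cluster_rejected = _cluster_reduce(rejected, clusters)
        _, inverse = np.unique(clusters, return_inverse=True)
        detected = cluster_rejected[inverse]
    group_tp = np.array(
        [int(np.count_nonzero(detected & (maf_group == g))) for g in GROUPS]
    )
    group_m1 = np.array([int(np.count_nonzero(maf_group == g)) for g in GROUPS])
    return ReplicateOutcome(counts=counts, group_tp=group_tp, group_m1=group_m1)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def power_estimates(outcomes: Sequence[ReplicateOutcome]) -> dict[str, float]:
    """Mean power, subgroup powers and FDR (with standard errors).

    Overall power is the mean over replicates of TP / m1 (at the counting
    granularity of each replicate's outcome); the FDR estimate is the mean
    false discovery proportion.  Standard errors are sample SD / sqrt(#
    replicates).  Power is undefined (NaN) when no causal units exist.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one replicate")
    if len(outcomes) == 1:
        warnings.warn("single replicate: standard errors reported as 0", stacklevel=2)
    powers = np.array(
        [
            o.counts.tp / (o.counts.tp + o.counts.fn)
            if (o.counts.tp + o.counts.fn) > 0
            else np.nan
            for o in outcomes
        ]
    )
    fdps = np.array([o.counts.fdp for o in outcomes])
    summary: dict[str, float] = {}
    summary["power"], summary["power_se"] = _mean_se(powers)
    summary["fdr"], summary["fdr_se"] = _mean_se(fdps)
    for gi, group in enumerate(GROUPS):
        gp = np.array(
            [
                o.group_tp[gi] / o.group_m1[gi] if o.group_m1[gi] > 0 else np.nan
                for o in outcomes
            ]
        )
        key = f"power_{group.replace('-', '_')}"
        summary[key], summary[key + "_se"] = _mean_se(gp)
    summary["n_replicates"] = len(outcomes)
    return summary


def _bh_adapter(p, x, alpha, seed, optimizer_config):
    return bh_stepup(p, alpha).rejected


def _qvalue_adapter(p, x, alpha, seed, optimizer_config):
    return qvalue_procedure(p, alpha).rejected


def _wbh_adapter(p, x, alpha, seed, optimizer_config):
    # fixed-weight comparator: the wBHa weight family pinned at a = 1
    return weighted_bh(p, covariate_weights(x, 1.0), alpha).rejected


def _wbha_adapter(p, x, alpha, seed, optimizer_config):
    config = optimizer_config or OptimizerConfig()
    config = replace(config, alpha=alpha, seed=seed)
    result, _ = wbha(p, x, config=config)
    return result.rejected


#: Procedure adapters ``f(p, x, alpha, seed, optimizer_config) -> rejected``;
#: external procedures can be slotted in by registering a callable here.
PROCEDURES = {
    "bh": _bh_adapter,
    "qvalue": _qvalue_adapter,
    "wbh": _wbh_adapter,
    "wbha": _wbha_adapter,
}


def _derived_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def _one_replicate(
    design: SimulationDesign,
    seeds: tuple[int, int, int],
    procedures: Sequence[str],
    alpha: float,
    covariate: str,
    optimizer_config: OptimizerConfig | None,
    cluster_threshold: float,
) -> dict[str, ReplicateOutcome]:
    sim_seed, cov_seed, opt_seed = seeds
    study = simulate_study(replace(design, seed=sim_seed))
    if design.trait == "quantitative":
        assoc = scan_quantitative(study.G, study.y)
    else:
        assoc = scan_binary(study.G, study.y)
    p = assoc["p"].to_numpy()
    maf = assoc["maf"].to_numpy()
    # monomorphic markers (MAF 0) would break the weight family; give them
    # the smallest representable frequency instead
    maf = np.where(maf > 0.0, maf, 0.5 / design.n)
    rng = np.random.default_rng(cov_seed)
    if covariate == "maf":
        x = maf
    elif covariate == "inverse_maf":
        x = 1.0 / maf
    elif covariate == "uniform":
        x = rng.uniform(1e-12, 1.0, size=p.size)
    else:
        raise ValueError(f"unknown covariate mode {covariate!r}")
    clusters = (
        cluster_markers(study.G, threshold=cluster_threshold, blocks=design.block_size)
        if design.rho > 0.0
        else None
    )
    outcomes = {}
    for name in procedures:
        rejected = PROCEDURES[name](p, x, alpha, opt_seed, optimizer_config)
        outcomes[name] = replicate_outcome(
            rejected, study.is_causal, study.maf_group, clusters
        )
    return outcomes


def run_study(
    designs,
    procedures: Sequence[str] = ("bh", "qvalue", "wbh", "wbha"),
    replicates: int = 100,
    seed: int | None = 0,
    alpha: float = 0.05,
    covariate: str = "maf",
    optimizer_config: OptimizerConfig | None = None,
    cluster_threshold: float = 0.8,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Replicated simulate → test → adjust → evaluate pipeline.

    Parameters
    ----------
    designs : SimulationDesign or sequence of SimulationDesign
        Simulation configurations to evaluate.
    procedures : sequence of str
        Names from :data:`PROCEDURES` (default all four: BH, qvalue, wBH
        with fixed 1/MAF weights, and wBHa).
    replicates : int
        Number of simulated datasets per configuration.
    seed : int or None
        Root seed; per-replicate seeds are derived through a splittable
        seed sequence, so the same root yields the same study.
    covariate : {"maf", "inverse_maf", "uniform"}
        Informative covariate fed to the weighted procedures: the observed
        MAF (rare-variant prioritization), its reciprocal (common-variant
        prioritization), or an uninformative U[0, 1] draw.
    cluster_threshold : float
        |correlation| threshold defining cluster units; clustering is
        applied automatically for designs with ``rho > 0``.
    n_jobs : int
        joblib parallelism over replicates (default serial).

    Returns
    -------
    pandas.DataFrame
        One row per (configuration, procedure) with the metrics of
        :func:`power_estimates` as columns.
    """
    if isinstance(designs, SimulationDesign):
        designs = [designs]
    designs = list(designs)
    procedures = list(procedures)
    if not procedures:
        raise ValueError("need at least one procedure")
    unknown = [name for name in procedures if name not in PROCEDURES]
    if unknown:
        raise ValueError(f"unknown procedure(s): {unknown}; known: {sorted(PROCEDURES)}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    root = np.random.SeedSequence(seed)
    rows = []
    for di, (design, design_seq) in enumerate(zip(designs, root.spawn(len(designs)))):
        seed_triplets = [
            tuple(_derived_seed(s) for s in child.spawn(3))
            for child in design_seq.spawn(replicates)
        ]
        work = (
            delayed(_one_replicate)(
                design,
                triplet,
                procedures,
                alpha,
                covariate,
                optimizer_config,
                cluster_threshold,
            )
            for triplet in seed_triplets
        )
        per_replicate = Parallel(n_jobs=n_jobs)(work)
        for name in procedures:
            summary = power_estimates([rep[name] for rep in per_replicate])
            row = {
                "design": di,
                "n": design.n,
                "m": design.m,
                "m1": design.m1,
                "rho": design.rho,
                "trait": design.trait,
                "scenario": design.scenario,
                "covariate": covariate,
                "alpha": alpha,
                "procedure": name,
            }
            row.update(summary)
            rows.append(row)
    return pd.DataFrame(rows)
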