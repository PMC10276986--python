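"""Tabular I/O, configuration handling and test fixtures.

The universal procedure input is a delimited text table (TSV, or CSV by
file extension) with one row per marker: required columns ``marker_id``
and ``p``, optional ``covariate`` (strictly positive, e.g. MAF),
``is_causal`` and ``maf_group``.  Validation errors name the offending
data row.  Adjustment output appends ``weight``, ``weighted_p`` and
``rejected`` columns while preserving the input columns unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associate import scan_binary, scan_quantitative
from .optimize import OptimizerConfig, wbha
from .procedures import bh_stepup, covariate_weights, qvalue_procedure, weighted_bh
from .simulate import SimulationDesign, SimulatedStudy, simulate_study

__all__ = [
    "PValueTable",
    "read_pvalue_table",
    "write_table",
    "adjust_table",
    "design_from_dict",
    "load_design",
    "make_fixture",
    "FIXTURE_KINDS",
]

REQUIRED_COLUMNS = ("marker_id", "p")
OPTIONAL_COLUMNS = ("covariate", "is_causal", "maf_group")


def _sep_for(path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class PValueTable:
    """Validated per-marker p-value table wrapping a pandas DataFrame."""

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PValueTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        if len(frame) == 0:
            raise ValueError("table contains no markers")
        ids = frame["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker_id {dup!r}")
        p = pd.to_numeric(frame["p"], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(p) | (p < 0.0) | (p > 1.0))[0]
        if bad.size:
            row = int(bad[0])
            raise ValueError(
                f"invalid p-value {frame['p'].iloc[row]!r} at row {row + 1} "
                f"(marker {ids.iloc[row]!r}): must lie in [0, 1]"
            )
        if "covariate" in frame.columns:
            x = pd.to_numeric(frame["covariate"], errors="coerce").to_numpy(dtype=float)
            bad = np.nonzero(~np.isfinite(x) | (x <= 0.0))[0]
            if bad.size:
                row = int(bad[0])
                raise ValueError(
                    f"invalid covariate {frame['covariate'].iloc[row]!r} at row "
                    f"{row + 1} (marker {ids.iloc[row]!r}): must be > 0"
                )
        return cls(frame=frame.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> np.ndarray:
        return self.frame["p"].to_numpy(dtype=float)

    @property
    def covariate(self) -> np.ndarray | None:
        if "covariate" not in self.frame.columns:
            return None
        return self.frame["covariate"].to_numpy(dtype=float)

    @property
    def is_causal(self) -> np.ndarray | None:
        if "is_causal" not in self.frame.columns:
            return None
        return self.frame["is_causal"].astype(bool).to_numpy()


def read_pvalue_table(path) -> PValueTable:
    """Read and validate a marker table from TSV/CSV (by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    return PValueTable.from_frame(frame)


def write_table(frame, path) -> None:
    """Write a DataFrame (or PValueTable) as TSV/CSV chosen by extension.

    Floats are written with 17 significant digits so numeric columns
    round-trip bit-exactly through read/write cycles.
    """
    if isinstance(frame, PValueTable):
        frame = frame.frame
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def adjust_table(
    table: PValueTable,
    method: str = "wbha",
    alpha: float = 0.05,
    config: OptimizerConfig | None = None,
):
    """Apply a multiple-testing procedure to a marker table.

    Returns ``(frame, trace)`` where ``frame`` is the input table with
    ``weight``, ``weighted_p`` and ``rejected`` columns appended and
    ``trace`` is the wBHa optimization trace (``None`` for the other
    methods).  Weighted methods require a ``covariate`` column.
    """
    p = table.p
    m = p.size
    trace = None
    if method == "bh":
        result = bh_stepup(p, alpha)
        weights = np.ones(m)
    elif method == "qvalue":
        result = qvalue_procedure(p, alpha)
        weights = np.ones(m)
    elif method in ("wbh", "wbha"):
        x = table.covariate
        if x is None:
            raise ValueError(f"method {method!r} requires a 'covariate' column")
        if method == "wbh":
            wv = covariate_weights(x, 1.0)
            result = weighted_bh(p, wv, alpha)
        else:
            result, trace = wbha(p, x, alpha=alpha, config=config)
            wv = result.weights_used
        weights = wv.w
    else:
        raise ValueError(f"unknown method {method!r}")
    out = table.frame.copy()
    out["weight"] = weights
    with np.errstate(divide="ignore"):
        out["weighted_p"] = np.where(weights > 0, p / np.where(weights > 0, weights, 1.0), np.inf)
    out["rejected"] = result.rejected
    return out, trace


def design_from_dict(d: dict) -> SimulationDesign:
    """Build a SimulationDesign from a mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimulationDesign)}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown design key(s): {unknown}; known: {sorted(known)}")
    return SimulationDesign(**d)


def load_design(path) -> SimulationDesign:
    """Read a simulation design from a JSON config file."""
    with open(path) as fh:
        return design_from_dict(json.load(fh))


def run_metadata(**extra) -> dict:
    """Metadata block recorded next to every run's outputs."""
    meta = {"package": "wbha", "version": __version__}
    meta.update(extra)
    return meta


# deterministic miniature designs used by the test suite and docs
FIXTURE_KINDS = {
    "null-only": dict(n=200, m=400, m1=0, rho=0.0, trait="quantitative"),
    "sparse-signal": dict(n=200, m=400, m1=8, rho=0.0, trait="quantitative"),
    "correlated": dict(n=200, m=400, m1=8, rho=0.75, trait="quantitative"),
    "binary": dict(n=200, m=400, m1=8, rho=0.0, trait="binary"),
}


def make_fixture(kind: str, seed: int = 0, outdir=None) -> tuple[SimulatedStudy, pd.DataFrame]:
    """Generate a small on-disk dataset for tests and documentation.

    Simulates a miniature study (n=200, m=400) of the requested kind, runs
    the matching association scan, and — when ``outdir`` is given — writes
    ``association.tsv`` (marker table with truth columns),
    ``phenotype.tsv``, ``genotypes.tsv`` and ``metadata.json`` (the
    resolved design and seed, sufficient to reproduce the files bit for
    bit).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {sorted(FIXTURE_KINDS)}")
    design = design_from_dict({**FIXTURE_KINDS[kind], "seed": seed})
    study = simulate_study(design)
    if design.trait == "quantitative":
        assoc = scan_quantitative(study.G, study.y)
    else:
        assoc = scan_binary(study.G, study.y)
    table = assoc.rename(columns={"maf": "covariate"})
    table["is_causal"] = study.is_causal
    table["maf_group"] = study.maf_group
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(table, outdir / "association.tsv")
        pd.DataFrame({"y": study.y}).to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
        geno = pd.DataFrame(study.G, columns=assoc["marker_id"])
        geno.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        meta = run_metadata(kind=kind, seed=seed, design=dataclasses.asdict(design))
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return study, table
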