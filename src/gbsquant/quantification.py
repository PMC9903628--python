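"""Calibration-key learning and conversion of read counts to abundances.

The key is learned at strain level: for each calibration sample the
per-strain read share is computed, and a strain's factor is the arithmetic
mean of its shares across calibration samples (factors therefore sum to
one).  A mock sample's abundance estimate divides each strain's read
weight by its factor and renormalises:

    abundance(s, j) = (r_sj / f_s) / sum_t (r_tj / f_t)

Counts exactly proportional to the factors thus invert to equal
abundances, and multiplying a sample's counts by any constant leaves its
estimates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_reference import MetaReference
from .read_mapping import CountMatrix
from .synthetic_data import SampleDesign

ROW_SUM_TOL = 1e-9


@dataclass
class CalibrationKey:
    factor: pd.Series  # strain -> mean calibration read share
    shares: pd.DataFrame  # calibration sample × strain shares
    variance: pd.Series  # strain -> s^2 of shares across calibration samples

    def __post_init__(self) -> None:
        if (self.factor <= 0).any():
            raise ValueError("calibration factors must be positive")

    @property
    def spread(self) -> float:
        return float(self.factor.max() / self.factor.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"factor": self.factor, "s2": self.variance})

    @classmethod
    def uniform(cls, strains: Sequence[str]) -> "CalibrationKey":
        """Bypass key (all strains equal) for no-calibration baselines."""
        n = len(strains)
        factor = pd.Series(1.0 / n, index=list(strains))
        return cls(
            factor=factor,
            shares=pd.DataFrame(columns=list(strains), dtype=float),
            variance=pd.Series(0.0, index=list(strains)),
        )


@dataclass
class AbundanceTable:
    values: pd.DataFrame  # sample × strain proportions, rows sum to 1
    method: str  # "GBS" | "LM" | "expected"

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size:
            if (vals < -ROW_SUM_TOL).any() or (vals > 1 + ROW_SUM_TOL).any():
                raise ValueError("abundances must lie in [0, 1]")
            if not np.allclose(vals.sum(axis=1), 1.0, atol=ROW_SUM_TOL):
                raise ValueError("abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.columns)


def strain_counts(matrix: CountMatrix, reference: MetaReference) -> pd.DataFrame:
    """Aggregate cluster × sample weights to a sample × strain table."""
    strain_of = pd.Series(
        {c.cluster_id: c.strain_id for c in reference.clusters}, name="strain"
    )
    strains = strain_of.reindex(matrix.weights.index)
    if strains.isna().any():
        missing = list(strains[strains.isna()].index[:5])
        raise ValueError(f"matrix rows missing from reference, e.g. {missing}")
    return matrix.weights.groupby(strains).sum().T


def build_calibration_key(
    counts: pd.DataFrame, calibration_samples: Sequence[str]
) -> CalibrationKey:
    """Learn per-strain factors from equal-proportion calibration samples.

    ``counts`` is the sample × strain table from :func:`strain_counts`.
    A strain with zero reads in every calibration sample cannot be
    calibrated and raises.
    """
    calib = [s for s in calibration_samples if s in counts.index]
    if not calib:
        raise ValueError("no calibration samples present in the count table")
    sub = counts.loc[calib]
    dead = [s for s in sub.columns if sub[s].sum() == 0]
    if dead:
        raise ValueError(f"strain(s) with zero calibration reads: {dead}")
    totals = sub.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("calibration sample with zero total reads")
    shares = sub.div(totals, axis=0)
    variance = shares.var(axis=0, ddof=1)
    if len(calib) == 1:
        variance = pd.Series(0.0, index=shares.columns)
    return CalibrationKey(factor=shares.mean(axis=0), shares=shares, variance=variance)


def estimate_abundances(
    counts: pd.DataFrame,
    key: CalibrationKey,
    samples: Sequence[str] | None = None,
) -> tuple[AbundanceTable, list[str]]:
    """Convert read counts to calibrated relative abundances (method GBS).

    Returns the table plus the ids of samples excluded for having zero
    total reads.  Strains with zero reads get abundance 0 (no pseudocount).
    """
    if samples is not None:
        rows = counts.loc[[s for s in samples if s in counts.index]]
    else:
        rows = counts
    missing = [s for s in rows.columns if s not in key.factor.index]
    if missing:
        raise ValueError(f"calibration key does not cover strain(s): {missing}")
    adjusted = rows.div(key.factor.reindex(rows.columns), axis=1)
    totals = adjusted.sum(axis=1)
    excluded = list(totals[totals == 0].index)
    kept = adjusted.loc[totals > 0]
    values = kept.div(kept.sum(axis=1), axis=0)
    return AbundanceTable(values=values, method="GBS"), excluded


def expected_abundances(
    designs: Sequence[SampleDesign],
    excluded_strains: Sequence[str] = (),
    roles: Sequence[str] = ("mock",),
) -> tuple[AbundanceTable, list[str]]:
    """Design-truth abundances, renormalised after strain exclusions.

    Cells of excluded strains (e.g. a strain dropped from the reference)
    are subtracted before renormalising, mirroring how expected values
    must be recomputed when a strain leaves the analysis.  Samples left
    empty are dropped and reported.
    """
    excluded_set = set(excluded_strains)
    strains = sorted(
        {s for d in designs if d.role in roles for s in d.cells} - excluded_set
    )
    rows = {}
    dropped = []
    for d in designs:
        if d.role not in roles:
            continue
        cells = {s: c for s, c in d.cells.items() if s not in excluded_set}
        total = sum(cells.values())
        if total == 0:
            dropped.append(d.sample_id)
            continue
        rows[d.sample_id] = [cells.get(s, 0) / total for s in strains]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    return AbundanceTable(values=values, method="expected"), dropped


def lm_abundances(
    valve_counts: Mapping[str, Mapping[str, int]],
    excluded_strains: Sequence[str] = (),
) -> AbundanceTable:
    """Light-microscopy valve counts -> proportions (method LM).

    Valves assigned to excluded strains are removed before normalising,
    exactly as for the expected table.
    """
    excluded_set = set(excluded_strains)
    strains = sorted(
        {s for counts in valve_counts.values() for s in counts} - excluded_set
    )
    rows = {}
    for sample, counts in valve_counts.items():
        kept = {s: c for s, c in counts.items() if s not in excluded_set}
        total = sum(kept.values())
        if total == 0:
            continue
        rows[sample] = [kept.get(s, 0) / total for s in strains]
    return AbundanceTable(
        values=pd.DataFrame.from_dict(rows, orient="index", columns=strains),
        method="LM",
    )


def side_by_side(
    observed: AbundanceTable, expected: AbundanceTable
) -> pd.DataFrame:
    """Expected and observed abundances in one long table for export."""
    rows = []
    for sample in observed.sample_ids:
        if sample not in expected.values.index:
            continue
        for strain in observed.strain_ids:
            rows.append(
                (
                    sample,
                    strain,
                    float(expected.values.at[sample, strain])
                    if strain in expected.values.columns
                    else 0.0,
                    float(observed.values.at[sample, strain]),
                )
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "strain_id", "expected", observed.method.lower()]
    )
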