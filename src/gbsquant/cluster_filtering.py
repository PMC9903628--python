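"""Homologous-cluster removal, driven by monoclonal-sample cross-mappings.

A cluster is removed from the reference if, over the monoclonal samples:

1. more reads map from some non-target strain than from its own strain,
2. fewer than ``min_target`` reads map from its own strain, or
3. the worst non-target/target read ratio exceeds ``ratio_max`` (1/15).

Non-target pressure is aggregated as the MAXIMUM over non-target strains
(a ``sum`` aggregate is available but over-removes).  The retained set
depends only on the disjunction of the rules; the per-cluster rule
attribution in the report follows the 1 → 2 → 3 evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .meta_reference import MetaReference
from .read_mapping import CountMatrix
from .synthetic_data import SampleDesign

DEFAULT_MIN_TARGET = 8
DEFAULT_RATIO_MAX = 1 / 15


class QCError(RuntimeError):
    """Structured failure for quality gates (e.g. collapsed target rates)."""


@dataclass(frozen=True)
class ClusterHomologyStats:
    cluster_id: str
    strain_id: str
    target_reads: float
    nontarget_reads: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.target_reads < 0 or any(v < 0 for v in self.nontarget_reads.values()):
            raise ValueError(f"{self.cluster_id}: negative read weight")

    @property
    def max_nontarget(self) -> tuple[str | None, float]:
        if not self.nontarget_reads:
            return None, 0.0
        strain = max(self.nontarget_reads, key=lambda s: (self.nontarget_reads[s], s))
        return strain, self.nontarget_reads[strain]


@dataclass
class FilterReport:
    removed: dict[str, int]  # cluster_id -> first rule fired (1|2|3)
    pairwise: pd.DataFrame  # strain × strain removal counts (row = cluster's strain)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def rule_counts(self) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0}
        for rule in self.removed.values():
            counts[rule] += 1
        return counts


def monoclonal_sample_of(designs: Sequence[SampleDesign]) -> dict[str, str]:
    """strain -> its monoclonal sample id."""
    out: dict[str, str] = {}
    for d in designs:
        if d.role == "monoclonal":
            (strain,) = d.strains
            out[strain] = d.sample_id
    return out


def compute_homology_stats(
    matrix: CountMatrix,
    designs: Sequence[SampleDesign],
    reference: MetaReference,
) -> list[ClusterHomologyStats]:
    """Per-cluster target and non-target read weights from monoclonal samples."""
    mono = monoclonal_sample_of(designs)
    strains = reference.strain_ids
    missing = [s for s in strains if s not in mono or mono[s] not in matrix.sample_ids]
    if missing:
        raise ValueError(f"no monoclonal sample mapped for strain(s): {missing}")
    weights = matrix.weights
    stats = []
    for cluster in reference.clusters:
        row = weights.loc[cluster.cluster_id] if cluster.cluster_id in weights.index else None
        def _w(sample: str) -> float:
            return float(row[sample]) if row is not None else 0.0
        stats.append(
            ClusterHomologyStats(
                cluster_id=cluster.cluster_id,
                strain_id=cluster.strain_id,
                target_reads=_w(mono[cluster.strain_id]),
                nontarget_reads={
                    s: _w(mono[s]) for s in strains if s != cluster.strain_id
                },
            )
        )
    return stats


def filter_homologous(
    stats: Sequence[ClusterHomologyStats],
    min_target: float = DEFAULT_MIN_TARGET,
    ratio_max: float = DEFAULT_RATIO_MAX,
    aggregate: str = "max",
) -> tuple[set[str], FilterReport]:
    """Apply the three removal rules; return retained ids and a report."""
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    strains = sorted(
        {s.strain_id for s in stats} | {t for s in stats for t in s.nontarget_reads}
    )
    pairwise = pd.DataFrame(0, index=strains, columns=strains)
    retained: set[str] = set()
    removed: dict[str, int] = {}
    for st in stats:
        if aggregate == "max":
            nt_strain, nt = st.max_nontarget
        else:
            nt = sum(st.nontarget_reads.values())
            nt_strain = st.max_nontarget[0]
        rule = _first_rule(st.target_reads, nt, min_target, ratio_max)
        if rule is None:
            retained.add(st.cluster_id)
        else:
            removed[st.cluster_id] = rule
            if nt_strain is not None and nt > 0:
                pairwise.at[st.strain_id, nt_strain] += 1
    return retained, FilterReport(removed=removed, pairwise=pairwise)


def _first_rule(
    target: float, nontarget: float, min_target: float, ratio_max: float
) -> int | None:
    if nontarget > target:
        return 1
    if target < min_target:
        return 2
    # multiplicative form sidesteps division by a zero target (reachable
    # only when min_target == 0)
    if nontarget > ratio_max * target:
        return 3
    return None


def target_mapping_rate(
    matrix: CountMatrix,
    designs: Sequence[SampleDesign],
    reference: MetaReference,
) -> dict[str, float]:
    """Per monoclonal sample: fraction of its retained read mass on
    clusters of its own strain."""
    mono = monoclonal_sample_of(designs)
    strain_of = {c.cluster_id: c.strain_id for c in reference.clusters}
    rates: dict[str, float] = {}
    for strain, sample in mono.items():
        if sample not in matrix.sample_ids:
            continue
        col = matrix.weights[sample]
        total = float(col.sum())
        if total == 0:
            rates[sample] = float("nan")
            continue
        own = sum(
            float(col[cid]) for cid in matrix.cluster_ids if strain_of.get(cid) == strain
        )
        rates[sample] = own / total
    return rates


def check_target_rates(rates: Mapping[str, float], minimum: float = 0.95) -> None:
    """QC gate: raise if any monoclonal target-mapping rate is missing or low."""
    bad = {
        s: r for s, r in rates.items() if r != r or r < minimum  # r != r catches NaN
    }
    if bad:
        raise QCError(
            "target mapping rate below "
            f"{minimum:.2f} (or undefined) for: "
            + ", ".join(f"{s}={r:.3f}" if r == r else f"{s}=NA" for s, r in bad.items())
        )
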