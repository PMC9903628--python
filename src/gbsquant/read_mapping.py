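"""Mapping processed reads against the meta-reference.

Scores are matches / read length under ungapped semi-global placement
(read slides along the reference; reference overhangs are free and
overhanging read bases are unmatched).  The simulator introduces
substitutions only, so ungapped placement is exact and cheap.  A read's
retained events are the clusters attaining its exact maximum match count,
provided the normalised score clears ``score_min``; joined reads are
mapped as two half-placements whose matches are pooled before
normalisation, with spacer Ns counting against the denominator.  Reads
and centroids share one strand convention (reverse-orientation molecules
found their own clusters), so no reverse-complement search is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from ._align import KmerIndex, gapless_matches, one_hot
from .meta_reference import MetaReference
from .preprocessing import ProcessedRead
from .synthetic_data import SampleDesign

_SPLIT_N = re.compile(r"N+")

DEFAULT_SCORE_MIN = 0.8
DEFAULT_MAX_HITS = 50


class MappingEvent(NamedTuple):
    read_id: str
    sample_id: str
    cluster_id: str
    score: float


@dataclass
class MappingResult:
    events: list[MappingEvent]
    n_reads: int
    n_unmapped: int
    n_discarded_repeats: int


def map_reads(
    reads: Sequence[ProcessedRead],
    reference: MetaReference,
    score_min: float = DEFAULT_SCORE_MIN,
    max_hits: int = DEFAULT_MAX_HITS,
    prefilter_k: int | None = 16,
) -> MappingResult:
    """Map reads, keeping for each read all clusters that tie its maximum
    score at or above ``score_min`` (tie tolerance 0).

    Reads tying more than ``max_hits`` clusters are discarded as
    unmappable repeats.  ``prefilter_k=None`` forces the exhaustive scan
    over every cluster.
    """
    if not reference.clusters:
        raise ValueError("empty meta-reference")
    centroids = [c.centroid for c in reference.clusters]
    ids = [c.cluster_id for c in reference.clusters]
    centroid_oh = [one_hot(c) for c in centroids]
    index = None
    if prefilter_k is not None:
        index = KmerIndex(k=prefilter_k)
        for i, centroid in enumerate(centroids):
            index.add(i, centroid)

    events: list[MappingEvent] = []
    n_unmapped = 0
    n_discarded = 0
    for read in reads:
        parts = [p for p in _SPLIT_N.split(read.sequence) if p]
        denom = len(read.sequence)
        if not parts:
            n_unmapped += 1
            continue
        if index is not None:
            candidates: set[int] = set()
            for part in parts:
                candidates |= index.candidates(part)
        else:
            candidates = set(range(len(centroids)))
        part_oh = [one_hot(p) for p in parts]
        best = -1
        hits: list[int] = []
        for i in candidates:
            matches = sum(
                gapless_matches(part, centroids[i], oh, centroid_oh[i])
                for part, oh in zip(parts, part_oh)
            )
            if matches > best:
                best = matches
                hits = [i]
            elif matches == best:
                hits.append(i)
        if best < 0 or best / denom < score_min:
            n_unmapped += 1
            continue
        if len(hits) > max_hits:
            n_discarded += 1
            continue
        score = best / denom
        for i in hits:
            events.append(MappingEvent(read.read_id, read.sample_id, ids[i], score))
    return MappingResult(
        events=events,
        n_reads=len(reads),
        n_unmapped=n_unmapped,
        n_discarded_repeats=n_discarded,
    )


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Cluster × sample table of fractional mapped-read weights.

    ``weights`` holds the 1/k multi-mapping allocation; ``raw`` the plain
    event counts.  Column sums of ``weights`` equal the number of retained
    mapped reads per sample.
    """

    weights: pd.DataFrame
    raw: pd.DataFrame

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.weights.columns)

    def column_sums(self) -> pd.Series:
        return self.weights.sum(axis=0)

    def drop_clusters(self, cluster_ids: set[str]) -> "CountMatrix":
        keep = [c for c in self.weights.index if c not in cluster_ids]
        return CountMatrix(
            weights=self.weights.loc[keep], raw=self.raw.loc[keep]
        )

    def to_long(self, reference: MetaReference | None = None) -> pd.DataFrame:
        strain_of = (
            {c.cluster_id: c.strain_id for c in reference.clusters} if reference else {}
        )
        rows = []
        for cid in self.weights.index:
            for sid in self.weights.columns:
                w = self.weights.at[cid, sid]
                r = self.raw.at[cid, sid]
                if r:
                    rows.append((cid, strain_of.get(cid, ""), sid, w, int(r)))
        return pd.DataFrame(
            rows, columns=["cluster_id", "strain_id", "sample_id", "weight", "raw_events"]
        )


def build_count_matrix(
    events: Sequence[MappingEvent],
    cluster_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Aggregate mapping events: a read with k retained events contributes
    1/k of a read to each of its clusters."""
    by_read: dict[str, list[MappingEvent]] = {}
    for ev in events:
        by_read.setdefault(ev.read_id, []).append(ev)
    weights: dict[tuple[str, str], float] = {}
    raw: dict[tuple[str, str], int] = {}
    for read_events in by_read.values():
        share = 1.0 / len(read_events)
        for ev in read_events:
            key = (ev.cluster_id, ev.sample_id)
            weights[key] = weights.get(key, 0.0) + share
            raw[key] = raw.get(key, 0) + 1
    clusters = list(cluster_ids) if cluster_ids is not None else sorted(
        {c for c, _ in weights}
    )
    samples = list(sample_ids) if sample_ids is not None else sorted(
        {s for _, s in weights}
    )
    w = pd.DataFrame(0.0, index=clusters, columns=samples)
    r = pd.DataFrame(0, index=clusters, columns=samples)
    for (cid, sid), val in weights.items():
        w.at[cid, sid] = val
    for (cid, sid), val in raw.items():
        r.at[cid, sid] = val
    return CountMatrix(weights=w, raw=r)


def exclude_low_read_samples(
    matrix: CountMatrix,
    designs: Sequence[SampleDesign],
    min_reads: float = 3000,
) -> tuple[CountMatrix, list[tuple[str, float]]]:
    """Drop mock/calibration samples whose retained read mass is < min_reads.

    Monoclonal samples are never dropped here (they only feed QC).  If
    every calibration sample falls below the threshold, calibration is
    impossible and a hard error is raised.
    """
    role_of = {d.sample_id: d.role for d in designs}
    sums = matrix.column_sums()
    excluded = [
        (sid, float(sums[sid]))
        for sid in matrix.sample_ids
        if role_of.get(sid) in ("mock", "calibration") and sums[sid] < min_reads
    ]
    excluded_ids = {sid for sid, _ in excluded}
    calib = [sid for sid in matrix.sample_ids if role_of.get(sid) == "calibration"]
    if calib and all(sid in excluded_ids for sid in calib):
        raise ValueError("all calibration samples fell below the read threshold")
    keep = [sid for sid in matrix.sample_ids if sid not in excluded_ids]
    return (
        CountMatrix(weights=matrix.weights[keep], raw=matrix.raw[keep]),
        excluded,
    )
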