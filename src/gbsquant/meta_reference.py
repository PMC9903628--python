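"""Meta-reference construction: greedy centroid clustering of dereplicated
monoclonal reads and concatenation into a strain-labelled cluster database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import pandas as pd

from ._align import KmerIndex, global_identity
from .preprocessing import UniqueSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    strain_id: str
    centroid: str
    member_count: int

    def __post_init__(self) -> None:
        if not self.centroid:
            raise ValueError(f"{self.cluster_id}: empty centroid")
        if self.member_count < 1:
            raise ValueError(f"{self.cluster_id}: member_count < 1")


@dataclass
class MetaReference:
    clusters: list[Cluster]
    excluded_strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids in meta-reference")

    @property
    def strain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clusters:
            seen.setdefault(c.strain_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.clusters)

    def by_id(self) -> dict[str, Cluster]:
        return {c.cluster_id: c for c in self.clusters}

    def subset(self, cluster_ids: set[str]) -> "MetaReference":
        return MetaReference(
            clusters=[c for c in self.clusters if c.cluster_id in cluster_ids],
            excluded_strains=list(self.excluded_strains),
        )

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for c in self.clusters:
                fh.write(f">{c.cluster_id}|size={c.member_count}\n{c.centroid}\n")

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.cluster_id, c.strain_id, c.member_count, len(c.centroid))
                for c in self.clusters
            ],
            columns=["cluster_id", "strain_id", "member_count", "centroid_length"],
        )


def cluster_sequences(
    uniques: Sequence[UniqueSequence],
    identity: float = 0.95,
    strain_id: str = "",
    prefilter_k: int | None = 12,
) -> list[Cluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Sequences are visited in size-descending order (ties broken by
    sequence) and join the first existing centroid — in centroid creation
    order — whose global-alignment identity is at least ``identity``;
    otherwise they found a new cluster with themselves as centroid.

    The k-mer prefilter (``prefilter_k=None`` disables it) only skips
    centroid/sequence pairs that cannot reach the identity threshold, so
    results are identical to the exhaustive scan.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    centroids: list[str] = []
    members: list[int] = []
    exact: dict[str, int] = {}
    index = KmerIndex(k=prefilter_k) if prefilter_k else None
    for seq, size in ordered:
        hit = exact.get(seq)
        if hit is None:
            if index is not None:
                # creation order preserved: first qualifying centroid wins
                scan = sorted(index.candidates(seq))
            else:
                scan = range(len(centroids))
            for i in scan:
                if global_identity(seq, centroids[i]) >= identity:
                    hit = i
                    break
        if hit is None:
            centroids.append(seq)
            members.append(size)
            exact[seq] = len(centroids) - 1
            if index is not None:
                index.add(len(centroids) - 1, seq)
        else:
            members[hit] += size
    return [
        Cluster(
            cluster_id=f"{strain_id or 'c'}|cluster{i + 1}",
            strain_id=strain_id,
            centroid=centroid,
            member_count=count,
        )
        for i, (centroid, count) in enumerate(zip(centroids, members))
    ]


def contaminant_filter(
    clusters: Sequence[Cluster],
    classifier: Callable[[str], bool] | None = None,
) -> tuple[list[Cluster], list[str]]:
    """Drop clusters the classifier rejects (centroid -> keep?).

    The default classifier keeps everything; real deployments plug in a
    taxonomy screen here.  Dropped cluster ids are returned for logging.
    """
    if classifier is None:
        return list(clusters), []
    kept, dropped = [], []
    for c in clusters:
        if classifier(c.centroid):
            kept.append(c)
        else:
            dropped.append(c.cluster_id)
    if dropped:
        logger.info("contaminant filter dropped %d clusters", len(dropped))
    return kept, dropped


def build_meta_reference(
    per_strain_clusters: Mapping[str, Sequence[Cluster]],
) -> MetaReference:
    """Concatenate per-strain clusters into one reference.

    Strains contributing zero clusters (e.g. a failed library) are
    excluded and recorded.  Cluster ids are rewritten to
    ``strain|clusterN`` so they are unique across strains.
    """
    excluded = [s for s, cl in per_strain_clusters.items() if not cl]
    if len(excluded) == len(per_strain_clusters):
        raise ValueError("every strain has zero clusters; cannot build a reference")
    for s in excluded:
        logger.warning("strain %s excluded from meta-reference (no clusters)", s)
    clusters: list[Cluster] = []
    for strain, strain_clusters in per_strain_clusters.items():
        if not strain_clusters:
            continue
        for i, c in enumerate(strain_clusters):
            clusters.append(
                replace(c, cluster_id=f"{strain}|cluster{i + 1}", strain_id=strain)
            )
    return MetaReference(clusters=clusters, excluded_strains=excluded)
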