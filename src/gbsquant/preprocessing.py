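"""Read preprocessing: demultiplexing, pair merging, UMI dedup, dereplication.

Pairs whose mates overlap by at least ``min_overlap`` bases with at most
``max_mismatch_frac`` mismatches are merged into a consensus; all others
are joined with a fixed 10-N spacer so both kinds live in one alphabet
(mapping treats N as a mismatch).  Duplicate removal collapses reads
identical in (UMI, sequence) and happens before mapping.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from ._seq import revcomp, seq_to_array

SPACER = "N" * 10

MERGED = "merged"
JOINED = "joined"


@dataclass(frozen=True)
class ProcessedRead:
    sample_id: str
    umi: str
    sequence: str
    origin: str  # "merged" | "joined"
    read_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty processed read")
        if self.origin not in (MERGED, JOINED):
            raise ValueError(f"unknown origin {self.origin!r}")


class UniqueSequence(NamedTuple):
    sequence: str
    size: int


class DemuxPair(NamedTuple):
    read_id: str
    umi: str
    mate1: str
    mate2: str


# ---------------------------------------------------------------------------
# demultiplexing


def validate_barcode_map(barcode_map: Mapping[str, str], max_mismatch: int = 1) -> None:
    """Reject barcode tables that cannot be decoded unambiguously."""
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in table")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError("barcodes must share one length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            dist = sum(x != y for x, y in zip(a, b))
            if dist <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {a} and {b} are within 2*max_mismatch ({dist} <= {2 * max_mismatch})"
                )


def demultiplex(
    read_pairs: Iterable[tuple[str, str, str]],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 1,
    umi_length: int = 3,
) -> tuple[dict[str, list[DemuxPair]], int]:
    """Assign raw (read_id, R1, R2) tuples to samples by the R1 barcode.

    The barcode and UMI are stripped from R1.  Returns per-sample pairs
    plus the count of unassigned pairs (never silently dropped).
    """
    validate_barcode_map(barcode_map, max_mismatch)
    bc_len = len(next(iter(barcode_map.values())))
    exact = {bc: sample for sample, bc in barcode_map.items()}
    items = list(barcode_map.items())
    out: dict[str, list[DemuxPair]] = {sample: [] for sample in barcode_map}
    unassigned = 0
    for read_id, seq1, seq2 in read_pairs:
        observed = seq1[:bc_len]
        sample = exact.get(observed)
        if sample is None and max_mismatch > 0:
            for cand, bc in items:
                if sum(x != y for x, y in zip(observed, bc)) <= max_mismatch:
                    sample = cand
                    break
        if sample is None:
            unassigned += 1
            continue
        umi = seq1[bc_len : bc_len + umi_length]
        out[sample].append(DemuxPair(read_id, umi, seq1[bc_len + umi_length :], seq2))
    return out, unassigned


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[tuple[str, str, str]]:
    """Iterate (read_id, R1, R2) from a pair of (optionally gzipped) FASTQs."""
    import gzip

    from Bio import SeqIO

    def _open(path: str):
        if str(path).endswith(".gz"):
            return gzip.open(path, "rt")
        return open(path)

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            name = rec1.id.removesuffix("/1")
            yield name, str(rec1.seq), str(rec2.seq)


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    mate1: str,
    mate2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
    spacer: str = SPACER,
    sample_id: str = "",
    umi: str = "NNN",
    read_id: str = "",
) -> ProcessedRead:
    """Merge a read pair into a consensus, or join with a spacer.

    ``mate2`` is reverse-complemented before the overlap search.  The scan
    takes the longest overlap ``o >= min_overlap`` whose mismatch fraction
    is at most ``max_mismatch_frac``; the consensus takes mate1's base at
    any mismatching column.  If no overlap qualifies the pair is joined as
    ``mate1 + spacer + revcomp(mate2)``.
    """
    if not mate1 or not mate2:
        raise ValueError("mates must be non-empty")
    sequence, origin = _merge_core(mate1, mate2, min_overlap, max_mismatch_frac, spacer)
    return ProcessedRead(
        sample_id=sample_id, umi=umi, sequence=sequence, origin=origin, read_id=read_id
    )


def _merge_core(
    mate1: str, mate2: str, min_overlap: int, max_mismatch_frac: float, spacer: str
) -> tuple[str, str]:
    rc2 = revcomp(mate2)
    max_o = min(len(mate1), len(mate2))
    if max_o >= min_overlap:
        # matches for every overlap length at once via cross-correlation;
        # overlap o corresponds to correlation lag len(mate1) - o
        a1 = seq_to_array(mate1)
        a2 = seq_to_array(rc2)
        corr = np.zeros(a1.size + a2.size - 1)
        for base in b"ACGT":
            corr += np.correlate(
                (a1 == base).astype(np.float64),
                (a2 == base).astype(np.float64),
                mode="full",
            )
        overlaps = np.arange(max_o, min_overlap - 1, -1)
        matches = np.rint(corr[a1.size + a2.size - 1 - overlaps]).astype(np.int64)
        ok = overlaps - matches <= max_mismatch_frac * overlaps
        if ok.any():
            o = int(overlaps[np.argmax(ok)])  # longest qualifying overlap
            return mate1 + rc2[o:], MERGED
    return mate1 + spacer + rc2, JOINED


def process_pairs(
    sample_id: str,
    pairs: Sequence[DemuxPair],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
    spacer: str = SPACER,
) -> list[ProcessedRead]:
    out = []
    for pair in pairs:
        seq, origin = _merge_core(
            pair.mate1, pair.mate2, min_overlap, max_mismatch_frac, spacer
        )
        out.append(
            ProcessedRead(
                sample_id=sample_id,
                umi=pair.umi,
                sequence=seq,
                origin=origin,
                read_id=pair.read_id,
            )
        )
    return out


def merged_fraction(reads: Sequence[ProcessedRead]) -> float:
    if not reads:
        return 0.0
    return sum(r.origin == MERGED for r in reads) / len(reads)


# ---------------------------------------------------------------------------
# duplicates and dereplication


def deduplicate(reads: Sequence[ProcessedRead]) -> tuple[list[ProcessedRead], float]:
    """Collapse reads identical in (UMI, sequence); report duplicate fraction."""
    seen: set[tuple[str, str]] = set()
    out: list[ProcessedRead] = []
    for read in reads:
        key = (read.umi, read.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(read)
    fraction = 1.0 - len(out) / len(reads) if reads else 0.0
    return out, fraction


def dereplicate(
    reads: Sequence[ProcessedRead] | Sequence[str], min_unique_size: int = 5
) -> list[UniqueSequence]:
    """Collapse identical sequences; drop those seen fewer than
    ``min_unique_size`` times.  Output is sorted by size descending, then
    sequence, the canonical order for greedy clustering."""
    if not reads:
        warnings.warn("dereplicate: empty input", stacklevel=2)
        return []
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    counts = Counter(seqs)
    uniques = [
        UniqueSequence(seq, size)
        for seq, size in counts.items()
        if size >= min_unique_size
    ]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques
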