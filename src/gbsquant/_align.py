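"""Pairwise comparison primitives shared by clustering and read mapping.

Two scoring conventions are used throughout the package:

* ``global_identity`` — identity of a gapped global alignment, defined as
  matches / alignment length where the alignment length counts every
  column including end gaps.  Used by greedy centroid clustering, where
  member sequences may differ in length.
* ``gapless_matches`` — the best ungapped placement of a query along a
  reference (reference overhangs free, query bases off either end simply
  unmatched).  Used by read mapping, where the normalised score is
  matches / read length.  The read simulator emits substitution errors
  only, so ungapped placement loses nothing and stays exactly
  reproducible by an independent sliding-window oracle.

``N`` never matches anything, including itself, so spacer bases in joined
sequences count as mismatches wherever they land.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_ALPHABET = "ACGTN"
_BASE_BYTES = (65, 67, 71, 84)  # A C G T


def _substitution_matrix():
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if (a == b and a != "N") else -1.0
    return m


@lru_cache(maxsize=None)
def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment of ``a`` and ``b``.

    Scoring: match +1, mismatch −1, gap −2 (linear).  Identity =
    matches / alignment length, where the denominator counts all columns
    including end gaps (the strictest common definition).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if a == b:
        return 1.0
    alignment = _global_aligner().align(a, b)[0]
    c = alignment.counts()
    length = c.identities + c.mismatches + c.gaps
    return c.identities / length


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) float64 indicator array over A/C/G/T; N rows are all zero."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros((arr.size, 4))
    for i, code in enumerate(_BASE_BYTES):
        out[arr == code, i] = 1.0
    return out


def gapless_matches(
    query: str,
    reference: str,
    query_oh: np.ndarray | None = None,
    reference_oh: np.ndarray | None = None,
) -> int:
    """Maximum matching positions over all ungapped placements of ``query``
    along ``reference`` (both orientations are the caller's concern).

    All shifts are considered, including partial overhangs at either end;
    overhanging query bases are simply unmatched.  Computed for every
    shift at once via per-base cross-correlation.
    """
    if not query or not reference:
        return 0
    if query in reference:
        return len(query)
    q = query_oh if query_oh is not None else one_hot(query)
    r = reference_oh if reference_oh is not None else one_hot(reference)
    corr = np.zeros(r.shape[0] + q.shape[0] - 1)
    for c in range(4):
        corr += np.correlate(r[:, c], q[:, c], mode="full")
    return int(round(corr.max()))


class KmerIndex:
    """Inverted k-mer index used to prefilter comparison candidates.

    For clustering at ≥ 95 % identity, requiring a single shared k-mer is
    lossless for k ≤ 12: a qualifying alignment has at most ~0.053·L
    edits, which destroy at most k times that many of the query's
    L − k + 1 k-mers — strictly fewer than are available.
    """

    def __init__(self, k: int = 12) -> None:
        self.k = k
        self._index: dict[str, list[int]] = {}
        self.size = 0

    def add(self, key: int, sequence: str) -> None:
        k = self.k
        seen: set[str] = set()
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            if "N" in kmer or kmer in seen:
                continue
            seen.add(kmer)
            self._index.setdefault(kmer, []).append(key)
        self.size += 1

    def candidates(self, sequence: str) -> set[int]:
        k = self.k
        index = self._index
        out: set[int] = set()
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            if "N" in kmer:
                continue
            hits = index.get(kmer)
            if hits:
                out.update(hits)
        return out
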