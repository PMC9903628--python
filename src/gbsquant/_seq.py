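"""Small nucleotide-string helpers."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 codes used for vectorised mutation / comparison
_CODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement; ``N`` maps to ``N``."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_CODE, size=length).tobytes().decode("ascii")


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    A substituted base is always changed to a *different* base.
    """
    if rate == 0:
        return seq
    arr = seq_to_array(seq)
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # shift within the 4-letter alphabet by 1..3 to guarantee a change
        idx = np.searchsorted(_CODE, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _CODE[(idx + shift) % 4]
    return array_to_seq(arr)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))
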