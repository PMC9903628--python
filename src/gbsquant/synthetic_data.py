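"""Truth-tagged simulator for double-digest GBS studies of strain mixtures.

Generates strain genomes with controlled divergence (optionally a mosaic
hybrid), digests them with two restriction enzymes, and produces paired-end
libraries for monoclonal, calibration, and mock samples — with per-strain
yield biases, PCR duplicates sharing a 3-nt UMI, and per-base substitution
errors.  Every read carries a truth tag so downstream stages can be scored
exactly.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seq import BASES, mutate, random_sequence, revcomp

PACI_SITE = "TTAATTAA"
NSII_SITE = "ATGCAT"
# both enzymes cut after the 5th base of their recognition site
PACI_CUT = 5
NSII_CUT = 5

READ_LENGTH = 150
UMI_LENGTH = 3
_UMI_CYCLE = ["".join(p) for p in product(BASES, repeat=UMI_LENGTH)]

ROLES = ("monoclonal", "calibration", "mock")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StrainGenome:
    strain_id: str
    sequence: str
    parent_id: str | None = None
    divergence: float = 0.0
    is_hybrid: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.strain_id}: empty genome sequence")
        if not 0.0 <= self.divergence < 0.5:
            raise ValueError(
                f"{self.strain_id}: divergence {self.divergence} outside [0, 0.5)"
            )


@dataclass
class StrainPanel:
    """Result of :func:`simulate_strain_genomes`: strains plus their ancestor."""

    ancestor: str
    strains: list[StrainGenome]

    def __iter__(self):
        return iter(self.strains)

    def __len__(self) -> int:
        return len(self.strains)

    def __getitem__(self, i):
        return self.strains[i]

    @property
    def strain_ids(self) -> list[str]:
        return [g.strain_id for g in self.strains]


@dataclass(frozen=True)
class HybridSpec:
    """Mosaic hybrid: alternating segments of two parents, then own mutations."""

    parent_a: int
    parent_b: int
    breakpoints: tuple[int, ...]
    child: int = -1


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    role: str
    cells: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if any(c < 0 for c in self.cells.values()):
            raise ValueError(f"{self.sample_id}: negative cell count")
        positive = [s for s, c in self.cells.items() if c > 0]
        if self.role == "monoclonal" and len(positive) != 1:
            raise ValueError(f"{self.sample_id}: monoclonal must have exactly one strain")
        if self.role == "calibration" and len(set(self.cells.values())) != 1:
            raise ValueError(f"{self.sample_id}: calibration cells must be equal")
        if self.role == "mock" and self.total_cells == 0:
            raise ValueError(f"{self.sample_id}: mock with zero total cells")

    @property
    def total_cells(self) -> int:
        return sum(self.cells.values())

    @property
    def strains(self) -> list[str]:
        return [s for s, c in self.cells.items() if c > 0]


@dataclass(frozen=True)
class BiasModel:
    yield_factor: Mapping[str, float]
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(y <= 0 for y in self.yield_factor.values()):
            raise ValueError("yield factors must be positive")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def yield_spread(self) -> float:
        """Max/min ratio of yield factors."""
        ys = list(self.yield_factor.values())
        return max(ys) / min(ys)


@dataclass(frozen=True)
class Fragment:
    strain_id: str
    start: int
    end: int
    left_site: str  # "a" or "b"
    right_site: str
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    sample_id: str
    barcode: str
    umi: str
    mate1: str
    mate2: str
    truth: tuple[str, int, int]  # (strain_id, fragment start, fragment end)
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if len(self.umi) != UMI_LENGTH:
            raise ValueError(f"UMI must be {UMI_LENGTH} nt")


# ---------------------------------------------------------------------------
# genomes


def simulate_strain_genomes(
    n_strains: int,
    genome_length: int,
    divergences: Sequence[float],
    hybrid_spec: HybridSpec | None = None,
    seed: int = 0,
    site_spacing: int | tuple[int, int] | None = None,
    site_a: str = PACI_SITE,
    site_b: str = NSII_SITE,
) -> StrainPanel:
    """Simulate strain genomes as mutated copies of a common ancestor.

    ``site_spacing`` optionally plants alternating copies of the two
    restriction sites into the ancestor (an int for regular spacing, or a
    ``(lo, hi)`` tuple for uniformly jittered gaps) so that small genomes
    still yield a usable double-digest fragment set.  The hybrid, when
    requested, is a mosaic of its two parents' finished sequences with its
    own divergence applied on top.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    if len(divergences) != n_strains:
        raise ValueError("need one divergence per strain")
    for d in divergences:
        if not 0.0 <= d < 0.5:
            raise ValueError(f"divergence {d} outside [0, 0.5)")

    rng = np.random.default_rng(seed)
    ancestor = random_sequence(genome_length, rng)
    if site_spacing is not None:
        ancestor = _plant_sites(ancestor, site_spacing, site_a, site_b, rng)

    ids = [f"S{i + 1}" for i in range(n_strains)]
    hybrid_idx = None
    if hybrid_spec is not None:
        hybrid_idx = hybrid_spec.child % n_strains
        if hybrid_idx in (hybrid_spec.parent_a % n_strains, hybrid_spec.parent_b % n_strains):
            raise ValueError("hybrid cannot be its own parent")

    strains: list[StrainGenome | None] = [None] * n_strains
    for i in range(n_strains):
        if i == hybrid_idx:
            continue
        strains[i] = StrainGenome(
            strain_id=ids[i],
            sequence=mutate(ancestor, divergences[i], rng),
            parent_id="ancestor",
            divergence=divergences[i],
        )
    if hybrid_spec is not None:
        pa = strains[hybrid_spec.parent_a % n_strains]
        pb = strains[hybrid_spec.parent_b % n_strains]
        mosaic = _mosaic(pa.sequence, pb.sequence, hybrid_spec.breakpoints)
        strains[hybrid_idx] = StrainGenome(
            strain_id=ids[hybrid_idx],
            sequence=mutate(mosaic, divergences[hybrid_idx], rng),
            parent_id=f"{pa.strain_id}+{pb.strain_id}",
            divergence=divergences[hybrid_idx],
            is_hybrid=True,
        )
    return StrainPanel(ancestor=ancestor, strains=list(strains))


def _plant_sites(
    ancestor: str,
    spacing: int | tuple[int, int],
    site_a: str,
    site_b: str,
    rng: np.random.Generator,
) -> str:
    arr = bytearray(ancestor.encode("ascii"))
    length = len(arr)
    if isinstance(spacing, tuple):
        lo, hi = spacing
    else:
        lo = hi = spacing
    pos = int(rng.integers(lo, hi + 1))
    which = 0
    sites = (site_a.encode("ascii"), site_b.encode("ascii"))
    while pos + max(len(site_a), len(site_b)) < length:
        motif = sites[which]
        arr[pos : pos + len(motif)] = motif
        which ^= 1
        pos += int(rng.integers(lo, hi + 1))
    return arr.decode("ascii")


def _mosaic(a: str, b: str, breakpoints: Sequence[int]) -> str:
    if len(a) != len(b):
        raise ValueError("hybrid parents must have equal genome lengths")
    bps = list(breakpoints)
    if bps != sorted(bps) or any(not 0 < p < len(a) for p in bps):
        raise ValueError("breakpoints must be strictly increasing within the genome")
    bounds = [0, *bps, len(a)]
    parts = []
    for i in range(len(bounds) - 1):
        src = a if i % 2 == 0 else b
        parts.append(src[bounds[i] : bounds[i + 1]])
    return "".join(parts)


# ---------------------------------------------------------------------------
# digestion


def digest_genome(
    genome: StrainGenome,
    site_a: str = PACI_SITE,
    site_b: str = NSII_SITE,
    min_fragment: int = 150,
    cut_offset_a: int = PACI_CUT,
    cut_offset_b: int = NSII_CUT,
) -> list[Fragment]:
    """Double-digest a genome and apply size selection.

    A fragment is retained iff it is flanked by one cut from each enzyme
    and its length is strictly greater than ``min_fragment``.  Genome ends
    do not count as cuts; fragments flanked by two cuts of the same enzyme
    are discarded (enzyme-specific adapters).  Sites are searched on the
    given strand only; coordinates are 0-based half-open.
    """
    if not site_a or not site_b:
        raise ValueError("recognition sequences must be non-empty")
    seq = genome.sequence
    cuts = [(p + cut_offset_a, "a") for p in _find_all(seq, site_a)]
    cuts += [(p + cut_offset_b, "b") for p in _find_all(seq, site_b)]
    cuts.sort()
    fragments = []
    for (c1, s1), (c2, s2) in zip(cuts, cuts[1:]):
        if s1 != s2 and c2 - c1 > min_fragment:
            fragments.append(
                Fragment(
                    strain_id=genome.strain_id,
                    start=c1,
                    end=c2,
                    left_site=s1,
                    right_site=s2,
                    sequence=seq[c1:c2],
                )
            )
    return fragments


def _find_all(seq: str, motif: str) -> Iterable[int]:
    i = seq.find(motif)
    while i != -1:
        yield i
        i = seq.find(motif, i + 1)


# ---------------------------------------------------------------------------
# study design


def make_study_design(
    strains: int | Sequence[str],
    seed: int = 0,
    n_calibration: int = 5,
    mock_sizes: Sequence[int] = (5,) * 18 + (3,) * 3 + (2,) * 3 + (1,),
    mock_cells: int = 1_000_000,
    calibration_cells: int = 990_000,
    monoclonal_cells: int = 6_000_000,
    min_share: float = 0.03,
) -> list[SampleDesign]:
    """Build the study's sample sheet: one monoclonal per strain, equal-
    proportion calibration samples, and mock mixtures of known composition.

    The default mock set is 18 five-strain, 3 three-strain, 3 two-strain
    and 1 single-strain mixture of ~1e6 cells each.  Calibration cells are
    split as ``calibration_cells // n_strains`` per strain (floor; the
    remainder is dropped so proportions stay exactly equal).
    """
    if isinstance(strains, int):
        strain_ids = [f"S{i + 1}" for i in range(strains)]
    else:
        strain_ids = list(strains)
    n = len(strain_ids)
    if n < max(mock_sizes):
        raise ValueError("fewer strains than the largest mock mixture")

    rng = np.random.default_rng(seed)
    designs = [
        SampleDesign(f"mono_{s}", "monoclonal", {s: monoclonal_cells}) for s in strain_ids
    ]
    per_strain = calibration_cells // n
    for j in range(n_calibration):
        designs.append(
            SampleDesign(f"cal{j + 1}", "calibration", {s: per_strain for s in strain_ids})
        )
    for j, k in enumerate(mock_sizes):
        chosen = sorted(rng.choice(strain_ids, size=k, replace=False))
        shares = _draw_shares(k, min_share, rng)
        counts = largest_remainder(shares * mock_cells)
        designs.append(
            SampleDesign(
                f"mock{j + 1:02d}", "mock", dict(zip(chosen, (int(c) for c in counts)))
            )
        )
    return designs


def _draw_shares(k: int, min_share: float, rng: np.random.Generator) -> np.ndarray:
    if k == 1:
        return np.array([1.0])
    for _ in range(1000):
        shares = rng.dirichlet(np.full(k, 2.0))
        if shares.min() >= min_share:
            return shares
    raise RuntimeError("could not draw mock shares above min_share")


def largest_remainder(values: np.ndarray) -> np.ndarray:
    """Round non-negative reals to integers preserving their exact sum."""
    values = np.asarray(values, dtype=float)
    floors = np.floor(values)
    remainder = int(round(values.sum() - floors.sum()))
    order = np.argsort(-(values - floors), kind="stable")
    out = floors.astype(np.int64)
    out[order[:remainder]] += 1
    return out


# ---------------------------------------------------------------------------
# barcodes


def default_barcodes(n: int, length: int = 6, min_dist: int = 3) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    for cand in ("".join(p) for p in product(BASES, repeat=length)):
        if all(_hamming_str(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise ValueError(f"cannot build {n} barcodes of length {length} at distance {min_dist}")


def _hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    fragments: Mapping[str, Sequence[Fragment]] | Sequence[Fragment],
    design: SampleDesign,
    bias: BiasModel,
    reads_per_cell: float,
    barcode_map: Mapping[str, str],
    read_length: int = READ_LENGTH,
    exact: bool = False,
) -> list[ReadPair]:
    """Simulate one sample's paired-end library.

    Reads are allocated to strains with expected counts proportional to
    ``cells × yield_factor``; within a strain, fragments are sampled
    uniformly and sequenced from either end with equal probability.  PCR
    duplicates are exact copies (sequence and UMI) of an earlier molecule;
    substitution errors are applied at the molecule level so duplicates
    remain identical copies.

    ``exact=True`` switches to a deterministic allocation (largest-
    remainder strain counts, round-robin fragments, alternating
    orientation, cycling UMIs) for noise-free end-to-end checks; it
    requires zero duplicate and error rates.
    """
    by_strain = _group_fragments(fragments)
    active = [s for s in design.cells if design.cells[s] > 0]
    for s in active:
        if not by_strain.get(s):
            raise ValueError(
                f"strain {s!r} has positive cells in {design.sample_id} but no fragments"
            )
    barcode = barcode_map[design.sample_id]
    weights = np.array(
        [design.cells[s] * bias.yield_factor[s] for s in active], dtype=float
    )
    n_total = int(round(reads_per_cell * design.total_cells))
    if n_total == 0 or not active:
        return []

    if exact:
        if bias.duplicate_rate or bias.error_rate:
            raise ValueError("exact mode requires zero duplicate and error rates")
        n_by_strain = largest_remainder(n_total * weights / weights.sum())
        return _generate_exact(
            by_strain, design, active, n_by_strain, barcode, read_length
        )

    rng = np.random.default_rng(
        [bias.seed, zlib.crc32(design.sample_id.encode("ascii"))]
    )
    n_by_strain = rng.multinomial(n_total, weights / weights.sum())
    reads: list[ReadPair] = []
    counter = 0
    for s, n in zip(active, n_by_strain):
        frs = by_strain[s]
        molecules: list[ReadPair] = []
        for _ in range(int(n)):
            read_id = f"{design.sample_id}:{counter}"
            counter += 1
            if molecules and rng.random() < bias.duplicate_rate:
                src = molecules[int(rng.integers(len(molecules)))]
                reads.append(replace(src, read_id=read_id, is_duplicate=True))
                continue
            fr = frs[int(rng.integers(len(frs)))]
            template = fr.sequence if rng.random() < 0.5 else revcomp(fr.sequence)
            mate1 = mutate(template[:read_length], bias.error_rate, rng)
            mate2 = mutate(revcomp(template)[:read_length], bias.error_rate, rng)
            pair = ReadPair(
                read_id=read_id,
                sample_id=design.sample_id,
                barcode=barcode,
                umi=random_sequence(UMI_LENGTH, rng),
                mate1=mate1,
                mate2=mate2,
                truth=(s, fr.start, fr.end),
            )
            molecules.append(pair)
            reads.append(pair)
    return reads


def _generate_exact(
    by_strain: Mapping[str, Sequence[Fragment]],
    design: SampleDesign,
    active: Sequence[str],
    n_by_strain: np.ndarray,
    barcode: str,
    read_length: int,
) -> list[ReadPair]:
    reads: list[ReadPair] = []
    counter = 0
    for s, n in zip(active, n_by_strain):
        frs = by_strain[s]
        slots = len(frs) * 2  # (fragment, orientation)
        umi_counters = [0] * slots
        for i in range(int(n)):
            slot = i % slots
            fr = frs[slot // 2]
            template = fr.sequence if slot % 2 == 0 else revcomp(fr.sequence)
            umi = _UMI_CYCLE[umi_counters[slot] % len(_UMI_CYCLE)]
            umi_counters[slot] += 1
            reads.append(
                ReadPair(
                    read_id=f"{design.sample_id}:{counter}",
                    sample_id=design.sample_id,
                    barcode=barcode,
                    umi=umi,
                    mate1=template[:read_length],
                    mate2=revcomp(template)[:read_length],
                    truth=(s, fr.start, fr.end),
                )
            )
            counter += 1
    return reads


def _group_fragments(
    fragments: Mapping[str, Sequence[Fragment]] | Sequence[Fragment],
) -> dict[str, list[Fragment]]:
    if isinstance(fragments, Mapping):
        return {s: list(frs) for s, frs in fragments.items()}
    grouped: dict[str, list[Fragment]] = {}
    for fr in fragments:
        grouped.setdefault(fr.strain_id, []).append(fr)
    return grouped


# ---------------------------------------------------------------------------
# light microscopy


def simulate_lm_counts(
    design: SampleDesign,
    confusion: pd.DataFrame,
    n_valves: int = 200,
    seed: int = 0,
) -> dict[str, int]:
    """Simulate expert valve counts with misidentification.

    ``confusion`` is a row-stochastic strain × strain matrix: row = true
    strain, column = reported strain.  Counts are a single multinomial
    draw of ``n_valves`` from the true proportions pushed through the
    confusion matrix.
    """
    if n_valves < 1:
        raise ValueError("n_valves must be >= 1")
    total = design.total_cells
    if total == 0:
        raise ValueError(f"{design.sample_id}: zero total cells")
    rowsums = confusion.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-8):
        raise ValueError("confusion matrix rows must sum to 1")
    p_true = np.array([design.cells.get(s, 0) / total for s in confusion.index])
    q = p_true @ confusion.to_numpy()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_valves, q / q.sum())
    return dict(zip(confusion.columns, (int(c) for c in counts)))


def identity_confusion(strain_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        np.eye(len(strain_ids)), index=list(strain_ids), columns=list(strain_ids)
    )


# ---------------------------------------------------------------------------
# writers


def write_fastq(reads: Sequence[ReadPair], r1_path: str, r2_path: str) -> None:
    """Write R1/R2 FASTQ (gzipped iff the path ends in .gz).

    Barcode and UMI are prepended to R1, per GBS convention.  Qualities
    are a constant placeholder (quality modelling is out of scope).
    """
    with _open_write(r1_path) as r1, _open_write(r2_path) as r2:
        for read in reads:
            seq1 = read.barcode + read.umi + read.mate1
            r1.write(f"@{read.read_id}/1\n{seq1}\n+\n{'I' * len(seq1)}\n")
            r2.write(f"@{read.read_id}/2\n{read.mate2}\n+\n{'I' * len(read.mate2)}\n")


def _open_write(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def truth_table(reads: Sequence[ReadPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.read_id, r.sample_id, r.truth[0], r.truth[1], r.truth[2])
            for r in reads
        ],
        columns=["read_id", "sample_id", "strain_id", "fragment_start", "fragment_end"],
    )


def write_truth_table(reads: Sequence[ReadPair], path: str) -> None:
    truth_table(reads).to_csv(path, sep="\t", index=False)


def designs_table(designs: Sequence[SampleDesign]) -> pd.DataFrame:
    rows = [
        (d.sample_id, d.role, s, c) for d in designs for s, c in d.cells.items()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "role", "strain_id", "cells"])


def write_designs(designs: Sequence[SampleDesign], path: str) -> None:
    designs_table(designs).to_csv(path, sep="\t", index=False)


def read_designs(path: str) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    designs = []
    for (sample_id, role), grp in df.groupby(["sample_id", "role"], sort=False):
        designs.append(
            SampleDesign(sample_id, role, dict(zip(grp.strain_id, grp.cells.astype(int))))
        )
    return designs


def write_genomes(panel: StrainPanel, path: str) -> None:
    """All strain genomes in one FASTA."""
    with open(path, "w") as fh:
        for g in panel:
            fh.write(f">{g.strain_id}\n{g.sequence}\n")


def write_config(config: Mapping, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
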