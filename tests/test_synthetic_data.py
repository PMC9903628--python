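import math

import pandas as pd
import pytest
from scipy import stats as sps

from gbsquant import synthetic_data as sd
from gbsquant._seq import hamming, revcomp
from gbsquant.preprocessing import deduplicate, merge_pairs


# ---------------------------------------------------------------------------
# genomes


class TestSimulateStrainGenomes:
    def test_zero_divergence_identical_to_ancestor(self):
        panel = sd.simulate_strain_genomes(3, 5000, [0.0, 0.0, 0.0], seed=1)
        for g in panel:
            assert g.sequence == panel.ancestor

    def test_divergence_within_binomial_bound(self):
        n = 100_000
        d = 0.05
        panel = sd.simulate_strain_genomes(1, n, [d], seed=42)
        observed = hamming(panel[0].sequence, panel.ancestor) / n
        bound = 3 * math.sqrt(d * (1 - d) / n)
        assert abs(observed - d) <= bound

    def test_hybrid_midpoint_breakpoint(self):
        length = 10_000
        spec = sd.HybridSpec(parent_a=0, parent_b=1, breakpoints=(length // 2,), child=2)
        panel = sd.simulate_strain_genomes(
            3, length, [0.05, 0.05, 0.0], hybrid_spec=spec, seed=3
        )
        a, b, h = (g.sequence for g in panel)
        mid = length // 2
        assert panel[2].is_hybrid
        assert h[:mid] == a[:mid]
        assert h[mid:] == b[mid:]

    def test_reproducible_under_seed(self):
        p1 = sd.simulate_strain_genomes(2, 2000, [0.02, 0.04], seed=9)
        p2 = sd.simulate_strain_genomes(2, 2000, [0.02, 0.04], seed=9)
        assert [g.sequence for g in p1] == [g.sequence for g in p2]

    @pytest.mark.parametrize("bad", [-0.01, 0.5, 0.9])
    def test_divergence_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.simulate_strain_genomes(1, 2000, [bad], seed=0)

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_strain_genomes(1, 999, [0.0], seed=0)


# ---------------------------------------------------------------------------
# digestion


class TestDigestGenome:
    def test_no_sites_no_fragments(self):
        g = sd.StrainGenome("X", "ACGT" * 500)
        assert sd.digest_genome(g) == []

    def test_hand_constructed_single_fragment(self):
        # cuts: PacI after 200+5=205, NsiI after 200+8+300+5=513
        g = sd.StrainGenome("X", "A" * 200 + "TTAATTAA" + "C" * 300 + "ATGCAT" + "G" * 200)
        frags = sd.digest_genome(g)
        assert len(frags) == 1
        (f,) = frags
        assert (f.start, f.end) == (205, 513)
        assert f.sequence == g.sequence[205:513]
        assert {f.left_site, f.right_site} == {"a", "b"}

    def test_short_fragment_size_selected_away(self):
        g = sd.StrainGenome("X", "A" * 200 + "TTAATTAA" + "C" * 100 + "ATGCAT" + "G" * 200)
        assert sd.digest_genome(g) == []

    def test_length_boundary_strictly_greater(self):
        # distance between cuts exactly 150 -> dropped; 151 -> kept
        for n_c, expect in [(142, 0), (143, 1)]:  # cuts at 205 and 205+8-5+n_c+5
            g = sd.StrainGenome(
                "X", "A" * 200 + "TTAATTAA" + "C" * n_c + "ATGCAT" + "G" * 200
            )
            frags = sd.digest_genome(g)
            assert len(frags) == expect, n_c

    def test_same_enzyme_flanks_discarded(self):
        g = sd.StrainGenome(
            "X",
            "A" * 100
            + "TTAATTAA"
            + "C" * 300
            + "TTAATTAA"
            + "G" * 300
            + "ATGCAT"
            + "T" * 100,
        )
        frags = sd.digest_genome(g)
        assert len(frags) == 1
        assert {frags[0].left_site, frags[0].right_site} == {"a", "b"}


# ---------------------------------------------------------------------------
# study design


@pytest.fixture(scope="module")
def designs():
    return sd.make_study_design(6, seed=5)


class TestMakeStudyDesign:
    def test_sample_counts(self, designs):
        roles = pd.Series([d.role for d in designs]).value_counts()
        assert roles["monoclonal"] == 6
        assert roles["calibration"] == 5
        assert roles["mock"] == 25

    def test_mock_mixture_sizes(self, designs):
        sizes = pd.Series(
            [len(d.strains) for d in designs if d.role == "mock"]
        ).value_counts()
        assert sizes.to_dict() == {5: 18, 3: 3, 2: 3, 1: 1}

    def test_calibration_equal_cells(self, designs):
        for d in designs:
            if d.role == "calibration":
                assert set(d.cells.values()) == {990_000 // 6}

    def test_monoclonals_cover_all_strains(self, designs):
        monos = [d for d in designs if d.role == "monoclonal"]
        assert sorted(s for d in monos for s in d.strains) == [f"S{i}" for i in range(1, 7)]

    def test_mock_totals(self, designs):
        for d in designs:
            if d.role == "mock":
                assert d.total_cells == 1_000_000


class TestSampleDesignInvariants:
    def test_monoclonal_single_strain(self):
        with pytest.raises(ValueError):
            sd.SampleDesign("m", "monoclonal", {"A": 10, "B": 10})

    def test_calibration_equal(self):
        with pytest.raises(ValueError):
            sd.SampleDesign("c", "calibration", {"A": 10, "B": 20})

    def test_mock_nonzero(self):
        with pytest.raises(ValueError):
            sd.SampleDesign("k", "mock", {"A": 0})


# ---------------------------------------------------------------------------
# reads


def _toy_fragments(rng, n=30, length=400):
    from gbsquant._seq import random_sequence

    return {
        "A": [
            sd.Fragment("A", i * length, i * length + length, "a", "b",
                        random_sequence(length, rng))
            for i in range(n)
        ],
        "B": [
            sd.Fragment("B", i * length, i * length + length, "a", "b",
                        random_sequence(length, rng))
            for i in range(n)
        ],
    }


class TestGenerateReads:
    def test_no_noise_mates_are_fragment_substrings(self, rng):
        frags = _toy_fragments(rng)
        design = sd.SampleDesign("m1", "mock", {"A": 500, "B": 500})
        bias = sd.BiasModel({"A": 1.0, "B": 1.0}, seed=1)
        reads = sd.generate_reads(frags, design, bias, 1.0, {"m1": "AAAAAA"})
        by_id = {f.start: f for fs in frags.values() for f in fs}
        assert len(reads) == 1000
        for r in reads[:200]:
            frag = next(
                f for f in frags[r.truth[0]] if (f.start, f.end) == r.truth[1:]
            )
            assert r.mate1 in frag.sequence or r.mate1 in revcomp(frag.sequence)
            assert r.mate2 in frag.sequence or r.mate2 in revcomp(frag.sequence)

    def test_yield_ratio_within_multinomial_bound(self, rng):
        frags = _toy_fragments(rng)
        design = sd.SampleDesign("m1", "mock", {"A": 1000, "B": 1000})
        bias = sd.BiasModel({"A": 1.0, "B": 4.0}, seed=2)
        n = 100_000
        reads = sd.generate_reads(frags, design, bias, n / 2000, {"m1": "AAAAAA"})
        n_b = sum(r.truth[0] == "B" for r in reads)
        p = 0.8  # 4 / (1 + 4)
        sigma = math.sqrt(len(reads) * p * (1 - p))
        assert abs(n_b - p * len(reads)) <= 3 * sigma

    def test_duplicate_rate_measured_by_dedup(self, rng):
        frags = _toy_fragments(rng, n=60)
        design = sd.SampleDesign("m1", "mock", {"A": 500, "B": 500})
        bias = sd.BiasModel({"A": 1.0, "B": 1.0}, duplicate_rate=0.5, seed=3)
        reads = sd.generate_reads(frags, design, bias, 5.0, {"m1": "AAAAAA"})
        processed = [
            merge_pairs(r.mate1, r.mate2, umi=r.umi, sample_id=r.sample_id)
            for r in reads
        ]
        _, frac = deduplicate(processed)
        # UMI collisions between independent molecules add a small excess
        assert abs(frac - 0.5) < 0.05

    def test_missing_fragments_error_names_strain(self, rng):
        frags = {"A": _toy_fragments(rng)["A"]}
        design = sd.SampleDesign("m1", "mock", {"A": 500, "B": 500})
        bias = sd.BiasModel({"A": 1.0, "B": 1.0}, seed=4)
        with pytest.raises(ValueError, match="B"):
            sd.generate_reads(frags, design, bias, 1.0, {"m1": "AAAAAA"})

    def test_reproducible_and_conserving(self, rng):
        frags = _toy_fragments(rng)
        design = sd.SampleDesign("m1", "mock", {"A": 700, "B": 300})
        bias = sd.BiasModel({"A": 1.0, "B": 2.0}, duplicate_rate=0.3,
                            error_rate=0.01, seed=5)
        r1 = sd.generate_reads(frags, design, bias, 3.0, {"m1": "AAAAAA"})
        r2 = sd.generate_reads(frags, design, bias, 3.0, {"m1": "AAAAAA"})
        assert r1 == r2
        truth = sd.truth_table(r1)
        assert len(truth) == len(r1)  # every read truth-tagged
        assert truth.strain_id.isin(["A", "B"]).all()

    def test_fastq_round_trip_byte_identical(self, rng, tmp_path):
        frags = _toy_fragments(rng, n=5)
        design = sd.SampleDesign("m1", "mock", {"A": 100})
        bias = sd.BiasModel({"A": 1.0}, seed=6)
        reads = sd.generate_reads(frags, design, bias, 2.0, {"m1": "ACGTCA"})
        paths = [tmp_path / f"r{i}_{j}.fastq" for i in (1, 2) for j in (1, 2)]
        sd.write_fastq(reads, paths[0], paths[1])
        sd.write_fastq(reads, paths[2], paths[3])
        assert paths[0].read_bytes() == paths[2].read_bytes()
        assert paths[1].read_bytes() == paths[3].read_bytes()

    def test_yield_bias_law_slope_near_one(self, rng):
        frags = _toy_fragments(rng)
        bias = sd.BiasModel({"A": 1.0, "B": 3.0}, seed=7)
        xs, ys = [], []
        for i in range(8):
            ca = int(rng.integers(200, 1800))
            design = sd.SampleDesign(f"m{i}", "mock", {"A": ca, "B": 2000 - ca})
            reads = sd.generate_reads(frags, design, bias, 10.0, {f"m{i}": "AAAAAA"})
            n_a = sum(r.truth[0] == "A" for r in reads)
            for strain, n_reads in [("A", n_a), ("B", len(reads) - n_a)]:
                w = design.cells[strain] * bias.yield_factor[strain]
                denom = sum(design.cells[s] * bias.yield_factor[s] for s in ("A", "B"))
                xs.append(math.log(w / denom))
                ys.append(math.log(n_reads / len(reads)))
        slope = sps.linregress(xs, ys).slope
        assert abs(slope - 1.0) < 0.05


# ---------------------------------------------------------------------------
# light microscopy


class TestSimulateLmCounts:
    def test_identity_confusion_matches_composition(self):
        design = sd.SampleDesign("m", "mock", {"A": 750_000, "B": 250_000})
        conf = sd.identity_confusion(["A", "B"])
        counts = sd.simulate_lm_counts(design, conf, n_valves=2000, seed=1)
        sigma = math.sqrt(2000 * 0.75 * 0.25)
        assert abs(counts["A"] - 1500) <= 3 * sigma
        assert counts["A"] + counts["B"] == 2000

    def test_full_swap_swaps_labels(self):
        design = sd.SampleDesign("m", "mock", {"A": 1_000_000})
        conf = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        counts = sd.simulate_lm_counts(design, conf, n_valves=500, seed=2)
        assert counts == {"A": 0, "B": 500}

    def test_leak_to_absent_strain_creates_false_positive(self):
        design = sd.SampleDesign("m", "mock", {"A": 1_000_000})
        conf = pd.DataFrame(
            [[0.9, 0.1], [0.0, 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        counts = sd.simulate_lm_counts(design, conf, n_valves=2000, seed=3)
        sigma = math.sqrt(2000 * 0.1 * 0.9)
        assert abs(counts["B"] - 200) <= 3 * sigma
        assert counts["B"] > 0

    def test_zero_cells_rejected(self):
        # a zero-cell design cannot be built normally; bypass validation
        empty = sd.SampleDesign.__new__(sd.SampleDesign)
        object.__setattr__(empty, "sample_id", "z")
        object.__setattr__(empty, "role", "mock")
        object.__setattr__(empty, "cells", {"A": 0})
        with pytest.raises(ValueError):
            sd.simulate_lm_counts(empty, sd.identity_confusion(["A"]), seed=0)

    def test_nonstochastic_rows_rejected(self):
        design = sd.SampleDesign("m", "mock", {"A": 10})
        conf = pd.DataFrame([[0.5]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            sd.simulate_lm_counts(design, conf, seed=0)


# ---------------------------------------------------------------------------
# barcodes and bias model


def test_default_barcodes_pairwise_distance():
    codes = sd.default_barcodes(36)
    assert len(set(codes)) == 36
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            assert sum(x != y for x, y in zip(a, b)) >= 3


def test_bias_model_validation_and_spread():
    with pytest.raises(ValueError):
        sd.BiasModel({"A": 0.0})
    with pytest.raises(ValueError):
        sd.BiasModel({"A": 1.0}, duplicate_rate=1.0)
    bias = sd.BiasModel({"A": 0.25, "B": 8.0})
    assert bias.yield_spread == 32.0
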