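import pytest
from oracles import sliding_matches

from gbsquant import read_mapping as rm
from gbsquant.meta_reference import Cluster, MetaReference
from gbsquant.preprocessing import JOINED, MERGED, ProcessedRead, SPACER
from gbsquant.synthetic_data import SampleDesign
from gbsquant._seq import mutate, random_sequence


def _read(seq, read_id="r1", sample="s1", origin=MERGED):
    return ProcessedRead(sample_id=sample, umi="AAA", sequence=seq,
                         origin=origin, read_id=read_id)


def _ref(centroids):
    return MetaReference(
        clusters=[Cluster(f"c{i}", f"S{i}", c, 5) for i, c in enumerate(centroids)]
    )


def _flip(seq, positions):
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    arr = list(seq)
    for p in positions:
        arr[p] = sub[arr[p]]
    return "".join(arr)


class TestMapReads:
    def test_exact_substring_scores_one(self, rng):
        centroid = random_sequence(400, rng)
        ref = _ref([centroid, random_sequence(400, rng)])
        result = rm.map_reads([_read(centroid[100:250])], ref)
        assert len(result.events) == 1
        ev = result.events[0]
        assert ev.cluster_id == "c0"
        assert ev.score == 1.0

    def test_35_substitutions_unmapped(self, rng):
        centroid = random_sequence(150, rng)
        read_seq = _flip(centroid, list(range(0, 150, 4))[:35])
        ref = _ref([centroid])
        result = rm.map_reads([_read(read_seq)], ref, prefilter_k=None)
        assert result.events == []
        assert result.n_unmapped == 1
        # 115/150 = 0.7667 sits just under the 0.8 gate
        assert sliding_matches(read_seq, centroid) == 115

    def test_equidistant_homologs_two_events(self, rng):
        base = random_sequence(150, rng)
        h1 = _flip(base, [10, 40, 70, 100, 130])
        h2 = _flip(base, [20, 50, 80, 110, 140])
        ref = _ref([h1, h2])
        result = rm.map_reads([_read(base)], ref)
        assert len(result.events) == 2
        assert {e.cluster_id for e in result.events} == {"c0", "c1"}
        assert all(e.score == pytest.approx(145 / 150) for e in result.events)

    def test_joined_read_pools_half_matches(self, rng):
        frag = random_sequence(400, rng)
        joined_centroid = frag[:150] + SPACER + frag[250:]
        ref = _ref([joined_centroid])
        read = _read(joined_centroid, origin=JOINED)
        result = rm.map_reads([read], ref)
        (ev,) = result.events
        # both 150-nt halves match fully; the 10 Ns count against the denominator
        assert ev.score == pytest.approx(300 / 310)

    def test_max_hits_discards_repeats(self, rng):
        seq = random_sequence(200, rng)
        ref = _ref([seq] * 5)  # five identical centroids
        result = rm.map_reads([_read(seq[:150])], ref, max_hits=3)
        assert result.events == []
        assert result.n_discarded_repeats == 1

    def test_prefilter_matches_exhaustive(self, rng):
        centroids = []
        for _ in range(30):
            base = random_sequence(int(rng.integers(200, 350)), rng)
            centroids.append(base)
            if rng.random() < 0.4:
                centroids.append(mutate(base, 0.05, rng))
        ref = _ref(centroids)
        reads = [
            _read(mutate(centroids[int(rng.integers(len(centroids)))][:160],
                         rng.uniform(0, 0.02), rng), read_id=f"r{i}")
            for i in range(150)
        ]
        fast = rm.map_reads(reads, ref, prefilter_k=16)
        slow = rm.map_reads(reads, ref, prefilter_k=None)
        assert sorted(fast.events) == sorted(slow.events)
        assert fast.n_unmapped == slow.n_unmapped

    def test_score_min_monotonicity(self, rng):
        centroids = [random_sequence(250, rng) for _ in range(10)]
        ref = _ref(centroids)
        reads = [
            _read(mutate(centroids[i % 10][:150], 0.1, rng), read_id=f"r{i}")
            for i in range(60)
        ]
        lo = rm.build_count_matrix(rm.map_reads(reads, ref, score_min=0.8).events)
        hi = rm.build_count_matrix(rm.map_reads(reads, ref, score_min=0.9).events)
        hi_full = hi.weights.reindex_like(lo.weights).fillna(0.0)
        assert (hi_full.to_numpy() <= lo.weights.to_numpy() + 1e-12).all()


class TestBuildCountMatrix:
    def test_unique_mapping_weight_one(self):
        events = [rm.MappingEvent("r1", "s1", "c1", 1.0)]
        m = rm.build_count_matrix(events)
        assert m.weights.at["c1", "s1"] == 1.0
        assert m.raw.at["c1", "s1"] == 1

    def test_multimapper_split_mass_conserved(self):
        events = [
            rm.MappingEvent("r1", "s1", "c1", 0.95),
            rm.MappingEvent("r1", "s1", "c2", 0.95),
        ]
        m = rm.build_count_matrix(events)
        assert m.weights.at["c1", "s1"] == 0.5
        assert m.weights.at["c2", "s1"] == 0.5
        assert m.column_sums()["s1"] == 1.0

    def test_toy_fixture_matches_enumeration(self):
        # 3 samples, 3 clusters, hand-enumerated expectation
        events = [
            rm.MappingEvent("a1", "s1", "c1", 1.0),
            rm.MappingEvent("a2", "s1", "c1", 1.0),
            rm.MappingEvent("a3", "s1", "c2", 1.0),
            rm.MappingEvent("b1", "s2", "c1", 0.9),
            rm.MappingEvent("b1", "s2", "c2", 0.9),
            rm.MappingEvent("b1", "s2", "c3", 0.9),
            rm.MappingEvent("c1", "s3", "c3", 1.0),
            rm.MappingEvent("c2", "s3", "c3", 1.0),
            rm.MappingEvent("c2", "s3", "c2", 1.0),
        ]
        m = rm.build_count_matrix(events)
        expect = {
            ("c1", "s1"): 2.0,
            ("c2", "s1"): 1.0,
            ("c1", "s2"): 1 / 3,
            ("c2", "s2"): 1 / 3,
            ("c3", "s2"): 1 / 3,
            ("c3", "s3"): 1.5,
            ("c2", "s3"): 0.5,
        }
        for (cid, sid), val in expect.items():
            assert m.weights.at[cid, sid] == pytest.approx(val)
        assert m.column_sums().to_dict() == pytest.approx(
            {"s1": 3.0, "s2": 1.0, "s3": 2.0}
        )

    def test_mass_conservation_random(self, rng):
        events = []
        for r in range(100):
            k = int(rng.integers(1, 5))
            for c in rng.choice(20, size=k, replace=False):
                events.append(rm.MappingEvent(f"r{r}", "s1", f"c{c}", 1.0))
        m = rm.build_count_matrix(events)
        assert m.column_sums()["s1"] == pytest.approx(100.0)


class TestExcludeLowReadSamples:
    def _matrix(self, col_sums):
        import pandas as pd

        w = pd.DataFrame({s: [v] for s, v in col_sums.items()}, index=["c1"])
        return rm.CountMatrix(weights=w, raw=(w > 0).astype(int))

    def _designs(self, roles):
        out = []
        for sid, role in roles.items():
            cells = {"A": 10} if role != "calibration" else {"A": 10, "B": 10}
            out.append(SampleDesign(sid, role, cells))
        return out

    def test_boundary_2999_excluded_3000_retained(self):
        m = self._matrix({"m1": 2999.0, "m2": 3000.0})
        designs = self._designs({"m1": "mock", "m2": "mock"})
        kept, report = rm.exclude_low_read_samples(m, designs)
        assert kept.sample_ids == ["m2"]
        assert report == [("m1", 2999.0)]

    def test_two_of_25_mocks_excluded(self):
        sums = {f"mock{i:02d}": 5000.0 for i in range(1, 26)}
        sums["mock01"] = 120.0
        sums["mock11"] = 80.0
        m = self._matrix(sums)
        designs = self._designs({s: "mock" for s in sums})
        kept, report = rm.exclude_low_read_samples(m, designs)
        assert len(kept.sample_ids) == 23
        assert sorted(s for s, _ in report) == ["mock01", "mock11"]

    def test_monoclonals_never_dropped(self):
        m = self._matrix({"mono": 10.0, "mock": 10.0})
        designs = self._designs({"mono": "monoclonal", "mock": "mock"})
        kept, report = rm.exclude_low_read_samples(m, designs)
        assert kept.sample_ids == ["mono"]

    def test_all_calibration_dropped_is_fatal(self):
        m = self._matrix({"cal1": 10.0, "cal2": 20.0})
        designs = self._designs({"cal1": "calibration", "cal2": "calibration"})
        with pytest.raises(ValueError, match="calibration"):
            rm.exclude_low_read_samples(m, designs)
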