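"""Strand-specific mapping, phase-grid geometry and cluster detection."""

import numpy as np
import pytest

from natphase.antisense_search import revcomp
from natphase.duplex_validation import PerfectSegment
from natphase.fixtures import FixtureSpec, make_fixture
from natphase.phasing import (
    MappedSRNA,
    PhasingParams,
    cross_coordinate,
    enumerate_phase_runs,
    map_srnas,
    read_bowtie_map,
)
from natphase.seqio import ShortRead

from .conftest import run_fixture
from .oracles import brute_force_phase_runs, naive_occurrences


def _read(seq, lib="L", rid="r", count=1):
    return ShortRead(id=rid, seq=seq, count=count, library=lib)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestMapSrnas:
    def test_substring_maps_once(self):
        rng = np.random.default_rng(0)
        t = _rand(rng, 100)
        (h,) = map_srnas([_read(t[9:30])], {"t": t})
        assert (h.transcript_id, h.start, h.end) == ("t", 10, 30)

    def test_reverse_complement_is_not_a_sense_hit(self):
        rng = np.random.default_rng(1)
        t = _rand(rng, 100)
        assert map_srnas([_read(revcomp(t[9:30]))], {"t": t}) == []

    def test_repeated_occurrence_reported_twice(self):
        rng = np.random.default_rng(2)
        unit = _rand(rng, 21)
        t = unit + _rand(rng, 30) + unit
        hits = map_srnas([_read(unit)], {"t": t})
        assert [h.start for h in hits] == naive_occurrences(unit, t) == [1, 52]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = {f"t{i}": _rand(rng, 200) for i in range(3)}
        reads = []
        for i in range(10):
            src = transcripts[f"t{int(rng.integers(0, 3))}"]
            p = int(rng.integers(0, 180))
            reads.append(_read(src[p : p + 20], rid=f"r{i}"))
        hits = map_srnas(reads, transcripts)
        expected = sorted(
            (tid, s, r.id)
            for r in reads
            for tid, t in transcripts.items()
            for s in naive_occurrences(r.seq, t)
        )
        assert sorted((h.transcript_id, h.start, h.read.id) for h in hits) == expected


class TestCrossCoordinate:
    def test_boundaries_and_example(self):
        seg = PerfectSegment(a_start=101, a_end=200, b_start=1, b_end=100)
        assert cross_coordinate(101, seg) == 100
        assert cross_coordinate(200, seg) == 1
        assert cross_coordinate(150, seg) == 51

    def test_involution(self):
        seg = PerfectSegment(a_start=101, a_end=200, b_start=1, b_end=100)
        mirror = PerfectSegment(a_start=1, a_end=100, b_start=101, b_end=200)
        for x in (101, 137, 200):
            assert cross_coordinate(cross_coordinate(x, seg), mirror) == x

    def test_outside_segment_rejected(self):
        seg = PerfectSegment(a_start=101, a_end=200, b_start=1, b_end=100)
        with pytest.raises(ValueError):
            cross_coordinate(100, seg)


def _grid_inputs(seg, n, sense_starts, anti_starts, lib="L"):
    hits_a = [
        MappedSRNA(read=_read("A" * n, rid=f"s{i}", lib=lib), transcript_id="A",
                   start=s, end=s + n - 1)
        for i, s in enumerate(sense_starts)
    ]
    hits_b = [
        MappedSRNA(read=_read("C" * n, rid=f"a{i}", lib=lib), transcript_id="B",
                   start=s, end=s + n - 1)
        for i, s in enumerate(anti_starts)
    ]
    return hits_a, hits_b


class TestEnumeratePhaseRuns:
    SEG = PerfectSegment(a_start=101, a_end=300, b_start=1, b_end=200)

    def test_sense_only_run_detected(self):
        n = 21
        starts = [110 + t * n for t in range(4)]
        hits_a, _ = _grid_inputs(self.SEG, n, starts, [])
        (c,) = enumerate_phase_runs(self.SEG, hits_a, [], n)
        assert c.n_phases == 4 and c.register == 9
        assert [s.sense_start for s in c.slots] == starts

    def test_three_slots_is_below_default_minimum(self):
        n = 21
        hits_a, _ = _grid_inputs(self.SEG, n, [110 + t * n for t in range(3)], [])
        assert enumerate_phase_runs(self.SEG, hits_a, [], n) == []

    def test_antisense_partner_five_prime_offset(self):
        """A slot [i, i+20] is evidenced by a partner whose B 5′ end maps to
        sense coordinate i+18 (2-nt 3′ overhangs on both ends)."""
        n = 21
        starts = [110 + t * n for t in range(4)]
        anti = [cross_coordinate(i + n - 3, self.SEG) for i in starts]
        _, hits_b = _grid_inputs(self.SEG, n, [], anti)
        (c,) = enumerate_phase_runs(self.SEG, [], hits_b, n)
        assert c.n_phases == 4
        for slot, b5 in zip(c.slots, anti):
            assert slot.antisense_hits and slot.antisense_hits[0].start == b5
            # footprint in sense coordinates is [i-2, i+18]
            assert slot.antisense_interval == (
                slot.sense_start - 2,
                slot.sense_start + n - 3,
            )

    def test_mixed_strand_evidence_counts_per_slot(self):
        n = 21
        starts = [110 + t * n for t in range(4)]
        hits_a, hits_b = _grid_inputs(
            self.SEG, n, starts[::2],
            [cross_coordinate(i + n - 3, self.SEG) for i in starts[1::2]],
        )
        (c,) = enumerate_phase_runs(self.SEG, hits_a, hits_b, n)
        assert c.n_phases == 4

    def test_both_strands_mode_is_stricter(self):
        n = 21
        starts = [110 + t * n for t in range(4)]
        hits_a, hits_b = _grid_inputs(
            self.SEG, n, starts,
            [cross_coordinate(i + n - 3, self.SEG) for i in starts[:3]],
        )
        params = PhasingParams(require_both_strands=True)
        assert enumerate_phase_runs(self.SEG, hits_a, hits_b, n, params) == []
        hits_a2, hits_b2 = _grid_inputs(
            self.SEG, n, starts,
            [cross_coordinate(i + n - 3, self.SEG) for i in starts],
        )
        (c,) = enumerate_phase_runs(self.SEG, hits_a2, hits_b2, n, params)
        assert c.n_phases == 4

    @pytest.mark.parametrize("length,expect", [(80, 0), (81, 1)])
    def test_region_length_boundary_is_strictly_above_80(self, length, expect):
        n = 19  # 4 x 19 = 76 fits in both 80 and 81
        seg = PerfectSegment(a_start=1, a_end=length, b_start=1, b_end=length)
        starts = [1 + t * n for t in range(4)]
        hits_a, _ = _grid_inputs(seg, n, starts, [])
        assert len(enumerate_phase_runs(seg, hits_a, [], n)) == expect

    def test_register_shift_moves_with_the_reads(self):
        n = 21
        for shift in (0, 1):
            starts = [110 + shift + t * n for t in range(4)]
            hits_a, _ = _grid_inputs(self.SEG, n, starts, [])
            (c,) = enumerate_phase_runs(self.SEG, hits_a, [], n)
            assert c.register == (9 + shift) % n
            assert c.n_phases == 4

    def test_off_phase_read_does_not_evidence_a_slot(self):
        n = 21
        starts = [110 + t * n for t in range(4)]
        starts_shifted = starts[:3] + [starts[3] + 1]  # last read off by one
        hits_a, _ = _grid_inputs(self.SEG, n, starts_shifted, [])
        assert enumerate_phase_runs(self.SEG, hits_a, [], n) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        """Detection equals enumerate-everything on random segments <=200 nt
        with random evidence patterns, including maximality."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(81, 201))
        seg = PerfectSegment(a_start=51, a_end=50 + length, b_start=11, b_end=10 + length)
        n = int(rng.choice([21, 24]))
        sense = {
            int(rng.integers(seg.a_start, seg.a_end - n + 2))
            for _ in range(int(rng.integers(0, 25)))
        }
        # bias toward one register so long runs actually occur
        r = int(rng.integers(0, n))
        sense |= {
            seg.a_start + r + t * n
            for t in range(int(rng.integers(0, 9)))
            if seg.a_start + r + t * n + n - 1 <= seg.a_end
            and rng.random() < 0.8
        }
        anti = {
            int(rng.integers(seg.b_start, seg.b_end - n + 2))
            for _ in range(int(rng.integers(0, 10)))
        }
        hits_a, hits_b = _grid_inputs(seg, n, sorted(sense), sorted(anti))
        clusters = enumerate_phase_runs(seg, hits_a, hits_b, n)
        got = {(c.register, c.slots[0].sense_start, c.n_phases) for c in clusters}
        expected = brute_force_phase_runs(
            seg.a_start, seg.a_end, seg.b_start, seg.b_end, sense, anti, n
        )
        assert got == expected

    def test_clusters_within_a_register_do_not_overlap(self):
        n = 21
        starts = [110 + t * n for t in range(9) if t != 4]  # two runs of 4
        hits_a, _ = _grid_inputs(self.SEG, n, starts, [])
        clusters = enumerate_phase_runs(self.SEG, hits_a, [], n)
        assert len(clusters) == 2
        ends = [(c.slots[0].sense_start, c.slots[-1].sense_start) for c in clusters]
        assert ends[0][1] < ends[1][0]


class TestEndToEndGeometry:
    def test_fig_layout_eight_srnas_four_phases(self, fig1b_fixture):
        result = run_fixture(fig1b_fixture)
        (c,) = result.clusters
        assert c.n_phases == 4 and c.n_srnas == 8
        assert all(s.evidenced_sense and s.evidenced_antisense for s in c.slots)

    def test_consecutive_sense_five_primes_are_n_apart(self, fig1b_fixture):
        result = run_fixture(fig1b_fixture)
        (c,) = result.clusters
        starts = [s.sense_start for s in c.slots]
        assert all(b - a == c.srna_len for a, b in zip(starts, starts[1:]))

    def test_per_library_presence_and_rpm_recorded(self, fig1b_fixture):
        result = run_fixture(fig1b_fixture)
        (c,) = result.clusters
        assert set(c.per_library_presence) == set(fig1b_fixture.spec.libraries)
        total = fig1b_fixture.truth.library_totals["lib1"]
        for read in fig1b_fixture.srna_reads:
            if read.seq in c.srna_rpm:
                assert c.srna_rpm[read.seq]["lib1"] == pytest.approx(
                    read.count / total * 1e6
                )


def test_read_bowtie_map_keeps_sense_records(tmp_path):
    fx = make_fixture(FixtureSpec(seed=13))
    a = fx.transcripts[0]
    read = fx.srna_reads[0]
    bowtie = tmp_path / "map.bwt"
    bowtie.write_text(
        f"{read.id}_x{read.count}\t+\t{a.id}\t63\t{read.seq}\n"
        f"{read.id}_x{read.count}\t-\t{a.id}\t10\t{read.seq}\n"
    )
    hits = read_bowtie_map(bowtie, {read.id: read})
    assert len(hits) == 1 and hits[0].start == 64
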