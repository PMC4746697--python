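"""Duplex-structure prediction, retention criteria and cis flagging."""

import numpy as np
import pytest

from natphase.antisense_search import ComplementaryMatch, find_complementary_pairs, revcomp
from natphase.duplex_validation import (
    Bubble,
    DuplexParams,
    DuplexStructure,
    PerfectSegment,
    base_pairs,
    build_nat_pairs,
    flag_cis_candidate,
    parse_rnaplex_line,
    predict_duplex,
    retention_filter,
)
from natphase.fixtures import FixtureSpec, make_nat_pair
from natphase.seqio import Transcript

from .oracles import duplex_dag_score, duplex_enumerate_score


def _duplex_for(spec: FixtureSpec):
    a, b, truth = make_nat_pair(spec)
    ts = [Transcript("a", a.seq), Transcript("b", b.seq)]
    (m,) = find_complementary_pairs(ts)
    return predict_duplex(a.seq, b.seq, m, DuplexParams()), truth, m


class TestPredictDuplex:
    def test_perfect_antisense_gives_one_full_segment(self):
        duplex, truth, _ = _duplex_for(FixtureSpec(seed=4, region_len=120))
        assert duplex.n_perfect_segments == 1
        assert duplex.bubbles == []
        seg = duplex.perfect_segments[0]
        assert seg.length == 120
        assert (seg.a_start, seg.a_end) == (truth.match["a_start"], truth.match["a_end"])

    def test_six_nt_insertion_in_a_gives_one_size6_bubble(self):
        # six unpaired bases on A at the region midpoint
        duplex, truth, _ = _duplex_for(
            FixtureSpec(seed=5, region_len=120, bubble=(60, 6, 0))
        )
        assert duplex.n_perfect_segments == 2
        (bub,) = duplex.bubbles
        assert (bub.a_gap_len, bub.b_gap_len, bub.size) == (6, 0, 6)

    def test_single_central_mismatch_is_a_size1_bubble(self):
        duplex, _, _ = _duplex_for(FixtureSpec(seed=6, region_len=120, mismatches=(60,)))
        assert duplex.n_perfect_segments == 2
        (bub,) = duplex.bubbles
        assert (bub.a_gap_len, bub.b_gap_len, bub.size) == (1, 1, 1)

    def test_gu_wobble_pairs_when_enabled(self):
        # A carries G where B carries T: pairs under wobble, bubble without
        a = "CCAACCGACCAA"
        b = revcomp(a).replace("C", "T", 1)  # first C (pairing the G) -> T
        m = ComplementaryMatch(
            id_a="a", id_b="b", a_start=1, a_end=12, b_start=1, b_end=12,
            aln_len=12, identity=1.0, longest_contig_block=12,
            longest_perfect_block=12, score=12,
        )
        with_gu = predict_duplex(a, b, m, DuplexParams(allow_gu=True, pad=0))
        without = predict_duplex(a, b, m, DuplexParams(allow_gu=False, pad=0))
        assert with_gu.n_perfect_segments == 1 and not with_gu.bubbles
        assert without.bubbles and without.bubbles[0].size == 1

    def test_window_outside_sequence_is_an_error(self):
        m = ComplementaryMatch(
            id_a="a", id_b="b", a_start=20, a_end=25, b_start=1, b_end=4,
            aln_len=6, identity=1.0, longest_contig_block=6,
            longest_perfect_block=6, score=6,
        )
        with pytest.raises(ValueError, match="empty duplex window"):
            predict_duplex("ACGT", "ACGT", m, DuplexParams(pad=0))

    def test_region_tiling_conservation(self):
        """Paired columns plus bubble gaps tile the annealed region on each
        strand."""
        duplex, _, _ = _duplex_for(
            FixtureSpec(seed=8, region_len=140, mismatches=(40,), bubble=(70, 3, 0))
        )
        a_len = duplex.a_region[1] - duplex.a_region[0] + 1
        b_len = duplex.b_region[1] - duplex.b_region[0] + 1
        n_pairs = len(duplex.pairs)
        assert n_pairs + sum(b.a_gap_len for b in duplex.bubbles) == a_len
        assert n_pairs + sum(b.b_gap_len for b in duplex.bubbles) == b_len
        assert sum(s.length for s in duplex.perfect_segments) == n_pairs


def _window_match(la, lb):
    return ComplementaryMatch(
        id_a="a", id_b="b", a_start=1, a_end=la, b_start=1, b_end=lb,
        aln_len=max(la, lb), identity=1.0, longest_contig_block=1,
        longest_perfect_block=1, score=1,
    )


class TestDpOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration_on_tiny_toys(self, seed):
        rng = np.random.default_rng(seed)
        la, lb = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=la))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=lb))
        duplex = predict_duplex(a, b, _window_match(la, lb), DuplexParams(pad=0))
        got = duplex.score if duplex else 0.0
        assert got == duplex_enumerate_score(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_equals_dag_longest_path_up_to_40nt(self, seed):
        rng = np.random.default_rng(100 + seed)
        la, lb = int(rng.integers(10, 41)), int(rng.integers(10, 41))
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=la))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=lb))
        for allow_gu in (True, False):
            duplex = predict_duplex(
                a, b, _window_match(la, lb), DuplexParams(pad=0, allow_gu=allow_gu)
            )
            got = duplex.score if duplex else 0.0
            assert got == duplex_dag_score(a, b, allow_gu=allow_gu)


def _structure(region_len=100, bubbles=(), a_region=(1, 100)):
    segs = [PerfectSegment(a_start=a_region[0], a_end=a_region[1],
                           b_start=1, b_end=a_region[1] - a_region[0] + 1)]
    return DuplexStructure(
        id_a="a",
        id_b="b",
        a_region=a_region,
        b_region=(1, region_len),
        pairs=[],
        bubbles=list(bubbles),
        perfect_segments=segs,
        score=0.0,
    )


def _match_interval(a_start, a_end, b_start=1, b_end=100):
    return ComplementaryMatch(
        id_a="a", id_b="b", a_start=a_start, a_end=a_end,
        b_start=b_start, b_end=b_end, aln_len=a_end - a_start + 1,
        identity=1.0, longest_contig_block=1, longest_perfect_block=1, score=1,
    )


class TestRetentionFilter:
    def test_exact_concordance_retained(self):
        assert retention_filter(_match_interval(1, 100), _structure())

    @pytest.mark.parametrize("size,keep", [(10, True), (11, False)])
    def test_bubble_boundary_ten_percent(self, size, keep):
        s = _structure(bubbles=[Bubble(a_gap_len=size, b_gap_len=0)])
        assert retention_filter(_match_interval(1, 100), s) is keep

    def test_bubble_sweep_flips_at_ten(self):
        for size in range(1, 21):
            s = _structure(bubbles=[Bubble(a_gap_len=size, b_gap_len=0)])
            assert retention_filter(_match_interval(1, 100), s) is (size <= 10)

    def test_overlap_boundary_eighty_percent(self):
        # match covers only the first 79 / 80 columns of the annealed region
        assert not retention_filter(_match_interval(1, 79), _structure())
        assert retention_filter(_match_interval(1, 80), _structure())

    def test_overlap_sweep(self):
        for cov in range(1, 101):
            keep = retention_filter(_match_interval(1, cov), _structure())
            assert keep is (cov >= 80)

    def test_pure_predicate_order_independent(self):
        structs = [
            _structure(bubbles=[Bubble(a_gap_len=s, b_gap_len=0)]) for s in (3, 12, 9)
        ]
        m = _match_interval(1, 100)
        results = [retention_filter(m, s) for s in structs]
        assert [retention_filter(m, s) for s in reversed(structs)] == results[::-1]

    def test_max_gap_strand_denominator_option(self):
        # bubble of 11 on B while the B region is 110 long: 11 <= 10% of 110
        segs = [PerfectSegment(a_start=1, a_end=100, b_start=1, b_end=100)]
        s = DuplexStructure(
            id_a="a", id_b="b", a_region=(1, 100), b_region=(1, 110),
            pairs=[], bubbles=[Bubble(a_gap_len=0, b_gap_len=11)],
            perfect_segments=segs, score=0.0,
        )
        m = _match_interval(1, 100, b_end=110)
        assert not retention_filter(m, s, bubble_denominator="strand_a")
        assert retention_filter(m, s, bubble_denominator="max_gap_strand")


class TestCisCandidates:
    def test_perfect_duplex_is_cis_candidate(self):
        duplex, _, _ = _duplex_for(FixtureSpec(seed=9, region_len=200))
        assert flag_cis_candidate(duplex)

    def test_bubbled_duplex_is_not(self):
        duplex, _, _ = _duplex_for(FixtureSpec(seed=10, region_len=120, mismatches=(60,)))
        assert not flag_cis_candidate(duplex)

    def test_two_validated_regions_revoke_cis_status(self):
        rng = np.random.default_rng(12)
        core1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=90))
        core2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        # spacers long enough that bridging them costs more than a core gains
        spacer_a = "".join("AC"[i] for i in rng.integers(0, 2, size=150))
        spacer_b = "".join("AC"[i] for i in rng.integers(0, 2, size=140))
        a = core1 + spacer_a + core2
        b = revcomp(core2) + spacer_b + revcomp(core1)
        ts = [Transcript("a", a), Transcript("b", b)]
        matches = find_complementary_pairs(ts)
        for m in matches:
            m.nat_class = "NT100"
        nats = build_nat_pairs({"a": a, "b": b}, matches)
        assert len(nats) == 2
        assert all(not n.is_cis_candidate for n in nats)
        # each region on its own is perfectly annealed
        assert all(flag_cis_candidate(n.duplex) for n in nats)


def test_parse_rnaplex_line_reconstructs_bubbles():
    # query 1..8 pairs target 11..17 with one unpaired query base (bulge)
    line = "(((.((((&)))))))  1,8 : 11,17  (-9.30)"
    d = parse_rnaplex_line(line, "a", "b")
    assert d.a_region == (1, 8) and d.b_region == (11, 17)
    assert len(d.pairs) == 7
    (bub,) = d.bubbles
    assert (bub.a_gap_len, bub.b_gap_len) == (1, 0)
    assert d.n_perfect_segments == 2


def test_base_pairs_table():
    assert base_pairs("A", "T") and base_pairs("C", "G")
    assert base_pairs("G", "T") and base_pairs("T", "G")
    assert not base_pairs("G", "T", allow_gu=False)
    assert not base_pairs("N", "N") and not base_pairs("A", "C")
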