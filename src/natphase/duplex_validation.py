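"""Structure-level validation of candidate NAT pairs.

The alignment stage only proves sequence complementarity; this stage checks
that the two regions can actually anneal into an RNA duplex and describes
that duplex: which positions pair, where the *bubbles* (unpaired interior
stretches — bulges and internal loops) sit, and the maximal *perfectly
annealed segments* between them.

The duplex model is combinatorial base-pair maximization: over all
non-crossing, monotone inter-molecular pairings of the two windows, maximize

    (# paired columns)  -  lambda * (# unpaired bubble columns)

with Watson-Crick pairs (and, by default, G·U wobble) allowed.  A mismatch
cannot occupy an aligned column; it necessarily becomes a 1+1 bubble (one
unpaired base on each strand, bubble size 1).  This keeps the stage exactly
testable; it deliberately does not model nearest-neighbour thermodynamics.

Two retention criteria then decide whether a candidate survives:

1. the structure-predicted annealed region must overlap the
   alignment-predicted complementary region at 80% or more (on both
   transcripts);
2. no bubble inside the annealed region may exceed 10% of the region length.

A retained pair whose single annealed region is one perfect segment with no
bubbles is flagged as a cis-NAT candidate: perfect annealing is the
signature of two transcripts read off the same locus on opposite strands,
which is the best available proxy when no reference genome exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .antisense_search import ComplementaryMatch

__all__ = [
    "DuplexParams",
    "Bubble",
    "PerfectSegment",
    "DuplexStructure",
    "NatPair",
    "base_pairs",
    "predict_duplex",
    "retention_filter",
    "flag_cis_candidate",
    "build_nat_pairs",
    "parse_rnaplex_line",
]

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def base_pairs(p: str, q: str, allow_gu: bool = True) -> bool:
    """Can a base on strand A pair with a base on strand B?  N never pairs."""
    if (p, q) in _WC:
        return True
    return allow_gu and (p, q) in _GU


@dataclass(frozen=True)
class DuplexParams:
    """``lam`` is the per-column bubble penalty of the DP objective; ``pad``
    widens the alignment-stage window before structure prediction so the
    annealed region may extend slightly beyond the seed alignment."""

    lam: float = 1.0
    allow_gu: bool = True
    pad: int = 10

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


@dataclass(frozen=True)
class Bubble:
    """An unpaired interior stretch; ``a_gap_len``/``b_gap_len`` count the
    unpaired bases on each strand between two consecutive paired columns."""

    a_gap_len: int
    b_gap_len: int

    def __post_init__(self) -> None:
        if self.a_gap_len < 0 or self.b_gap_len < 0:
            raise ValueError("gap lengths must be >= 0")
        if self.a_gap_len + self.b_gap_len < 1:
            raise ValueError("a bubble has at least one unpaired base")

    @property
    def size(self) -> int:
        return max(self.a_gap_len, self.b_gap_len)


@dataclass(frozen=True)
class PerfectSegment:
    """A maximal gap-free, mismatch-free annealed stretch (1-based
    inclusive on both forward strands; b runs antiparallel to a)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("segment strand lengths differ")
        if self.a_start > self.a_end:
            raise ValueError("inverted segment")

    @property
    def length(self) -> int:
        return self.a_end - self.a_start + 1


@dataclass
class DuplexStructure:
    """Predicted annealed region between two transcripts.

    ``pairs`` lists the paired columns as (pos_a, pos_b), pos_a ascending and
    pos_b descending (antiparallel annealing).  ``bubbles`` are the interior
    unpaired stretches in the same order; ``perfect_segments`` the maximal
    perfect stretches.  ``score`` is the DP objective value.
    """

    id_a: str
    id_b: str
    a_region: tuple[int, int]
    b_region: tuple[int, int]
    pairs: list[tuple[int, int]]
    bubbles: list[Bubble]
    perfect_segments: list[PerfectSegment]
    score: float

    @property
    def n_perfect_segments(self) -> int:
        return len(self.perfect_segments)

    @property
    def a_region_len(self) -> int:
        return self.a_region[1] - self.a_region[0] + 1

    @property
    def b_region_len(self) -> int:
        return self.b_region[1] - self.b_region[0] + 1


def _duplex_dp(
    xa: str, xb_rev: str, lam: float, allow_gu: bool
) -> tuple[float, list[tuple[int, int]]]:
    """Local DP over A-window (5'→3') vs B-window traversed 3'→5'.

    Returns the best score and the paired columns as (i, j) 0-based indices
    into ``xa`` and ``xb_rev``.  Deterministic tie-break: pair > gap-in-B >
    gap-in-A, latest cell on ties of the global maximum.
    """
    n, m = len(xa), len(xb_rev)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        ca = xa[i - 1]
        for j in range(1, m + 1):
            diag = (
                prev[j - 1] + 1.0 if base_pairs(ca, xb_rev[j - 1], allow_gu) else NEG
            )
            up = prev[j] - lam
            left = row[j - 1] - lam
            h = max(0.0, diag, up, left)
            row[j] = h
            # strict > keeps the earliest/shortest optimum: net-zero tail
            # extensions (a pair bought with an equal bubble cost) are noise
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return 0.0, []

    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0.0:
        h = H[i][j]
        ca = xa[i - 1]
        if base_pairs(ca, xb_rev[j - 1], allow_gu) and h == H[i - 1][j - 1] + 1.0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] - lam:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return best, pairs


def predict_duplex(
    a_seq: str,
    b_seq: str,
    match: ComplementaryMatch,
    params: DuplexParams | None = None,
) -> DuplexStructure | None:
    """Predict the duplex structure for one alignment-stage candidate.

    The windows are the matched intervals padded by ``params.pad`` nt and
    clipped to the transcript ends.  Returns ``None`` when no base pair can
    form at all (the candidate then simply fails retention).
    """
    params = params or DuplexParams()
    a_lo = max(1, match.a_start - params.pad)
    a_hi = min(len(a_seq), match.a_end + params.pad)
    b_lo = max(1, match.b_start - params.pad)
    b_hi = min(len(b_seq), match.b_end + params.pad)
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("empty duplex window")

    xa = a_seq[a_lo - 1 : a_hi]
    # traverse the B window 3'→5' so both strands advance together
    xb_rev = b_seq[b_lo - 1 : b_hi][::-1]
    score, idx_pairs = _duplex_dp(xa, xb_rev, params.lam, params.allow_gu)
    if not idx_pairs:
        return None

    # map DP indices to transcript coordinates (1-based forward strands)
    pairs = [(a_lo + i, b_hi - j) for i, j in idx_pairs]

    bubbles: list[Bubble] = []
    segments: list[PerfectSegment] = []
    seg_start = 0
    for k in range(1, len(pairs)):
        a_gap = pairs[k][0] - pairs[k - 1][0] - 1
        b_gap = pairs[k - 1][1] - pairs[k][1] - 1
        if a_gap or b_gap:
            bubbles.append(Bubble(a_gap_len=a_gap, b_gap_len=b_gap))
            segments.append(
                PerfectSegment(
                    a_start=pairs[seg_start][0],
                    a_end=pairs[k - 1][0],
                    b_start=pairs[k - 1][1],
                    b_end=pairs[seg_start][1],
                )
            )
            seg_start = k
    segments.append(
        PerfectSegment(
            a_start=pairs[seg_start][0],
            a_end=pairs[-1][0],
            b_start=pairs[-1][1],
            b_end=pairs[seg_start][1],
        )
    )

    return DuplexStructure(
        id_a=match.id_a,
        id_b=match.id_b,
        a_region=(pairs[0][0], pairs[-1][0]),
        b_region=(pairs[-1][1], pairs[0][1]),
        pairs=pairs,
        bubbles=bubbles,
        perfect_segments=segments,
        score=score,
    )


def _overlap_len(iv1: tuple[int, int], iv2: tuple[int, int]) -> int:
    return max(0, min(iv1[1], iv2[1]) - max(iv1[0], iv2[0]) + 1)


def retention_filter(
    match: ComplementaryMatch,
    duplex: DuplexStructure,
    overlap_min: float = 0.8,
    bubble_max_frac: float = 0.10,
    bubble_denominator: str = "strand_a",
) -> bool:
    """Apply the two retention criteria to one candidate region.

    Criterion 1: the fraction of the structure-predicted annealed region
    covered by the alignment-predicted complementary region must be
    ``overlap_min`` or more, on both transcripts.  Criterion 2: every bubble
    size must be no larger than ``bubble_max_frac`` of the annealed-region
    length (strand-A length by default; ``bubble_denominator="max_gap_strand"``
    uses, per bubble, the region length on the strand with the larger gap).
    """
    cov_a = _overlap_len(duplex.a_region, (match.a_start, match.a_end)) / duplex.a_region_len
    cov_b = _overlap_len(duplex.b_region, (match.b_start, match.b_end)) / duplex.b_region_len
    if cov_a < overlap_min or cov_b < overlap_min:
        return False
    for bub in duplex.bubbles:
        if bubble_denominator == "max_gap_strand":
            denom = (
                duplex.a_region_len
                if bub.a_gap_len >= bub.b_gap_len
                else duplex.b_region_len
            )
        else:
            denom = duplex.a_region_len
        if bub.size > bubble_max_frac * denom:
            return False
    return True


def flag_cis_candidate(duplex: DuplexStructure) -> bool:
    """A region is cis-like when it is one single perfect segment spanning
    the whole annealed region, with no bubbles."""
    if duplex.bubbles or duplex.n_perfect_segments != 1:
        return False
    seg = duplex.perfect_segments[0]
    return (seg.a_start, seg.a_end) == duplex.a_region and (
        seg.b_start,
        seg.b_end,
    ) == duplex.b_region


@dataclass
class NatPair:
    """One retained annealed region of a validated NAT pair.

    A transcript pair with several disjoint validated regions yields several
    records; ``is_cis_candidate`` is true only when the pair has exactly one
    retained region and that region is perfectly annealed.
    """

    id_a: str
    id_b: str
    match: ComplementaryMatch
    duplex: DuplexStructure
    is_cis_candidate: bool = False

    @property
    def perfect_segments(self) -> list[PerfectSegment]:
        return self.duplex.perfect_segments


def build_nat_pairs(
    transcripts: dict[str, str],
    matches: Sequence[ComplementaryMatch],
    params: DuplexParams | None = None,
    overlap_min: float = 0.8,
    bubble_max_frac: float = 0.10,
    bubble_denominator: str = "strand_a",
) -> list[NatPair]:
    """Validate alignment-stage candidates and assemble the NAT list.

    ``transcripts`` maps transcript ID to sequence.  Candidates classified
    ``none`` are dropped before structure prediction; survivors of both
    retention criteria become :class:`NatPair` records with pair-level
    cis-candidate flags.
    """
    params = params or DuplexParams()
    retained: list[NatPair] = []
    for m in matches:
        if m.nat_class == "none":
            continue
        duplex = predict_duplex(transcripts[m.id_a], transcripts[m.id_b], m, params)
        if duplex is None:
            continue
        if not retention_filter(
            m, duplex, overlap_min, bubble_max_frac, bubble_denominator
        ):
            continue
        retained.append(NatPair(id_a=m.id_a, id_b=m.id_b, match=m, duplex=duplex))

    regions_per_pair: dict[tuple[str, str], int] = {}
    for nat in retained:
        regions_per_pair[(nat.id_a, nat.id_b)] = (
            regions_per_pair.get((nat.id_a, nat.id_b), 0) + 1
        )
    for nat in retained:
        nat.is_cis_candidate = regions_per_pair[
            (nat.id_a, nat.id_b)
        ] == 1 and flag_cis_candidate(nat.duplex)
    retained.sort(key=lambda n: (n.id_a, n.id_b, n.duplex.a_region))
    return retained


_RNAPLEX_RE = re.compile(
    r"^(?P<struct>[.()&]+)\s+(?P<i>\d+),(?P<j>\d+)\s*:\s*(?P<k>\d+),(?P<l>\d+)"
)


def parse_rnaplex_line(line: str, id_a: str, id_b: str) -> DuplexStructure:
    """Build a :class:`DuplexStructure` from one RNAplex duplex line.

    Expected shape: ``((..((&)).))  i,j : k,l  (energy)`` where the part
    before ``&`` describes the query (transcript A, interval i..j) and the
    part after describes the target (transcript B, interval k..l).  Supplied
    for users who prefer real thermodynamic predictions; the pairing is
    reconstructed by matching brackets outside-in.
    """
    m = _RNAPLEX_RE.match(line.strip())
    if not m:
        raise ValueError(f"unparseable RNAplex line: {line!r}")
    sa, sb = m.group("struct").split("&")
    i, j = int(m.group("i")), int(m.group("j"))
    k, l = int(m.group("k")), int(m.group("l"))
    a_positions = [i + off for off, c in enumerate(sa) if c == "("]
    b_positions = [k + off for off, c in enumerate(sb) if c == ")"]
    if len(a_positions) != len(b_positions):
        raise ValueError("unbalanced RNAplex structure")
    # intermolecular duplex: first '(' pairs the last ')'
    pairs = list(zip(a_positions, reversed(b_positions)))

    bubbles: list[Bubble] = []
    segments: list[PerfectSegment] = []
    seg_start = 0
    for idx in range(1, len(pairs)):
        a_gap = pairs[idx][0] - pairs[idx - 1][0] - 1
        b_gap = pairs[idx - 1][1] - pairs[idx][1] - 1
        if a_gap or b_gap:
            bubbles.append(Bubble(a_gap_len=a_gap, b_gap_len=b_gap))
            segments.append(
                PerfectSegment(
                    a_start=pairs[seg_start][0],
                    a_end=pairs[idx - 1][0],
                    b_start=pairs[idx - 1][1],
                    b_end=pairs[seg_start][1],
                )
            )
            seg_start = idx
    segments.append(
        PerfectSegment(
            a_start=pairs[seg_start][0],
            a_end=pairs[-1][0],
            b_start=pairs[-1][1],
            b_end=pairs[seg_start][1],
        )
    )
    return DuplexStructure(
        id_a=id_a,
        id_b=id_b,
        a_region=(pairs[0][0], pairs[-1][0]),
        b_region=(pairs[-1][1], pairs[0][1]),
        pairs=pairs,
        bubbles=bubbles,
        perfect_segments=segments,
        score=float(len(pairs)),
    )
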