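"""Find highly complementary transcript pairs and classify them.

The first discovery stage aligns each transcript A against the reverse
complement of each candidate partner B with a seed-gated gapped local
alignment (exact k-mer seeds, then optimal local DP with affine gaps).  A hit
means a region of A can anneal to a region of B in antisense orientation.

Retained pairs are classified in the two conventional NAT classes:

* ``HC`` (high coverage) — the complementary region spans more than half of
  at least one transcript of the pair;
* ``NT100`` — the longest gap-free aligned block is at least 100 nt,
  mismatches allowed (trans-NAT pairs typically anneal with mismatches, so a
  mismatch does not break a "consecutive" complementary region; set
  ``nt100_perfect`` for the stricter reading).

Coordinates are 1-based inclusive and always reported on each transcript's
forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .seqio import Transcript

__all__ = [
    "AlignerParams",
    "ClassifyParams",
    "ComplementaryMatch",
    "revcomp",
    "find_complementary_pairs",
    "classify_match",
    "read_blast_tab",
]

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet (N stays N)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignerParams:
    """Scoring for the antisense local aligner.

    Defaults approximate blastn-style behaviour: +1 match, -2 mismatch,
    affine gaps costing ``gap_open + (L - 1) * gap_extend`` for a gap of
    length L.  ``min_score`` doubles as a minimum alignment length bound
    (a score of s requires at least s matched columns).
    """

    seed_len: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 60
    max_regions_per_pair: int | None = None

    def __post_init__(self) -> None:
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass(frozen=True)
class ClassifyParams:
    hc_fraction: float = 0.5
    hc_mode: str = "any_transcript"  # or "both_transcripts"
    nt100_min_len: int = 100
    nt100_perfect: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.hc_fraction < 1.0:
            raise ValueError("hc_fraction must be in (0, 1)")
        if self.nt100_min_len < 1:
            raise ValueError("nt100_min_len must be >= 1")
        if self.hc_mode not in ("any_transcript", "both_transcripts"):
            raise ValueError(f"unknown hc_mode {self.hc_mode!r}")


@dataclass
class ComplementaryMatch:
    """One antisense alignment region between two transcripts.

    ``identity`` is the fraction of aligned columns that are complementary
    base pairs; ``longest_contig_block`` is the longest gap-free stretch;
    ``longest_perfect_block`` additionally forbids mismatches.  Pairs are
    canonical: ``id_a < id_b``.
    """

    id_a: str
    id_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aln_len: int
    identity: float
    longest_contig_block: int
    longest_perfect_block: int
    score: int
    nat_class: str = "none"  # HC | NT100 | both | none

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("matches must be canonical (id_a < id_b)")
        if self.a_start > self.a_end or self.b_start > self.b_end:
            raise ValueError("inverted interval")

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_start + 1

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_start + 1


# --- alignment internals ---------------------------------------------------

_ALPHABET = NucleotideSequence("ACGTN").alphabet


def _substitution_matrix(params: AlignerParams) -> SubstitutionMatrix:
    n = len(_ALPHABET)
    m = np.full((n, n), params.mismatch, dtype=np.int32)
    for i, c in enumerate(_ALPHABET):
        if c in "ACGT":  # N never scores as a match
            m[i, i] = params.match
    return SubstitutionMatrix(_ALPHABET, _ALPHABET, m)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def _column_stats(trace: np.ndarray, x: str, y: str) -> tuple[int, int, int, int]:
    """(n_match, longest_contig_block, longest_perfect_block, aln_len)."""
    n_match = 0
    contig = best_contig = 0
    perfect = best_perfect = 0
    for i, j in trace:
        if i >= 0 and j >= 0:
            contig += 1
            if x[i] == y[j] and x[i] != "N":
                n_match += 1
                perfect += 1
            else:
                best_perfect = max(best_perfect, perfect)
                perfect = 0
        else:
            best_contig = max(best_contig, contig)
            best_perfect = max(best_perfect, perfect)
            contig = perfect = 0
    best_contig = max(best_contig, contig)
    best_perfect = max(best_perfect, perfect)
    return n_match, best_contig, best_perfect, len(trace)


def _align_region(
    a_sub: str,
    rb: str,
    matrix: SubstitutionMatrix,
    params: AlignerParams,
) -> tuple[int, int, int, int, int, tuple[int, int, int, int]] | None:
    """Best local alignment of ``a_sub`` vs ``rb`` (both plain strings).

    Returns (score, a0, a1, rb0, rb1, stats) with 0-based inclusive ends on
    the two input strings, or None if below ``min_score``.
    """
    alns = align_optimal(
        NucleotideSequence(a_sub),
        NucleotideSequence(rb),
        matrix,
        gap_penalty=(params.gap_open, params.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns:
        return None
    aln = alns[0]
    if aln.score < params.min_score:
        return None
    trace = aln.trace
    a_cols = trace[:, 0][trace[:, 0] >= 0]
    b_cols = trace[:, 1][trace[:, 1] >= 0]
    stats = _column_stats(trace, a_sub, rb)
    return (
        int(aln.score),
        int(a_cols.min()),
        int(a_cols.max()),
        int(b_cols.min()),
        int(b_cols.max()),
        stats,
    )


def _pair_regions(
    a_seq: str, b_seq: str, matrix: SubstitutionMatrix, params: AlignerParams
) -> list[tuple[int, int, int, int, int, tuple[int, int, int, int]]]:
    """All accepted non-overlapping (on A) antisense regions for one pair.

    After each accepted alignment, the flanks of A to its left and right are
    realigned recursively against the full reverse complement of B, so
    additional regions never overlap on A.
    """
    rb = revcomp(b_seq)
    out: list[tuple[int, int, int, int, int, tuple]] = []

    def recurse(lo: int, hi: int) -> None:  # A window [lo, hi) 0-based
        if hi - lo < params.min_score:  # cannot reach min_score
            return
        res = _align_region(a_seq[lo:hi], rb, matrix, params)
        if res is None:
            return
        score, a0, a1, rb0, rb1, stats = res
        out.append((score, lo + a0, lo + a1, rb0, rb1, stats))
        recurse(lo, lo + a0)
        recurse(lo + a1 + 1, hi)

    recurse(0, len(a_seq))
    out.sort(key=lambda r: r[1])
    if params.max_regions_per_pair is not None:
        out = sorted(out, key=lambda r: -r[0])[: params.max_regions_per_pair]
        out.sort(key=lambda r: r[1])
    return out


def find_complementary_pairs(
    transcripts: Sequence[Transcript],
    params: AlignerParams | None = None,
) -> list[ComplementaryMatch]:
    """Scan all transcript pairs for antisense complementarity.

    A pair is aligned only when transcript A and the reverse complement of B
    share at least one exact ``seed_len``-mer (the seed gate); the gapped
    extension is an optimal local alignment, so whenever a seed lies inside
    the optimal local alignment the reported score equals the full
    dynamic-programming score.  Self-pairs are excluded; each unordered pair
    is processed once in canonical (lexicographic) order and may yield
    several disjoint regions.
    """
    params = params or AlignerParams()
    matrix = _substitution_matrix(params)

    usable: list[Transcript] = []
    for t in transcripts:
        if t.length < params.seed_len:
            logger.info("transcript %s shorter than seed_len; skipped", t.id)
            continue
        usable.append(t)
    usable = sorted(usable, key=lambda t: t.id)

    fwd_kmers = {t.id: _kmers(t.seq, params.seed_len) for t in usable}
    rc_kmers = {t.id: _kmers(revcomp(t.seq), params.seed_len) for t in usable}

    matches: list[ComplementaryMatch] = []
    for ia in range(len(usable)):
        a = usable[ia]
        for ib in range(ia + 1, len(usable)):
            b = usable[ib]
            if not (fwd_kmers[a.id] & rc_kmers[b.id]):
                continue
            for score, a0, a1, rb0, rb1, stats in _pair_regions(
                a.seq, b.seq, matrix, params
            ):
                n_match, contig, perfect, aln_len = stats
                # map revcomp(B) coords back to B's forward strand
                b_start = b.length - 1 - rb1
                b_end = b.length - 1 - rb0
                matches.append(
                    ComplementaryMatch(
                        id_a=a.id,
                        id_b=b.id,
                        a_start=a0 + 1,
                        a_end=a1 + 1,
                        b_start=b_start + 1,
                        b_end=b_end + 1,
                        aln_len=aln_len,
                        identity=n_match / aln_len,
                        longest_contig_block=contig,
                        longest_perfect_block=perfect,
                        score=score,
                    )
                )
    return matches


def classify_match(
    m: ComplementaryMatch,
    len_a: int,
    len_b: int,
    params: ClassifyParams | None = None,
) -> str:
    """Assign the HC / NT100 / both / none class label.

    HC: the complementary-region span exceeds ``hc_fraction`` of one
    transcript's length (or of both, with ``hc_mode="both_transcripts"``).
    NT100: the longest contiguous aligned block reaches ``nt100_min_len``.
    """
    params = params or ClassifyParams()
    frac_a = m.a_span > params.hc_fraction * len_a
    frac_b = m.b_span > params.hc_fraction * len_b
    hc = (frac_a or frac_b) if params.hc_mode == "any_transcript" else (frac_a and frac_b)
    block = m.longest_perfect_block if params.nt100_perfect else m.longest_contig_block
    nt100 = block >= params.nt100_min_len
    if hc and nt100:
        return "both"
    if hc:
        return "HC"
    if nt100:
        return "NT100"
    return "none"


def read_blast_tab(path: str | Path, min_score: float = 0.0) -> list[ComplementaryMatch]:
    """Parse blastn outfmt-6 lines into :class:`ComplementaryMatch` records.

    Only minus-strand hits (sstart > send) are kept, since antisense
    complementarity is what the pipeline consumes.  ``longest_contig_block``
    is approximated by the aligned length minus gap openings (tabular output
    does not carry per-column detail) and ``longest_perfect_block`` is left
    at 0; use the internal aligner when exact block lengths matter.
    """
    out: list[ComplementaryMatch] = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            f = raw.split("\t")
            qid, sid = f[0], f[1]
            pident, length = float(f[2]), int(f[3])
            gapopen = int(f[5])
            qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            bitscore = float(f[11])
            if sstart <= send:  # plus strand: not antisense
                continue
            if bitscore < min_score or qid == sid:
                continue
            a_id, b_id = qid, sid
            a_iv, b_iv = (qstart, qend), (send, sstart)
            if a_id > b_id:
                a_id, b_id = b_id, a_id
                a_iv, b_iv = b_iv, a_iv
            out.append(
                ComplementaryMatch(
                    id_a=a_id,
                    id_b=b_id,
                    a_start=a_iv[0],
                    a_end=a_iv[1],
                    b_start=b_iv[0],
                    b_end=b_iv[1],
                    aln_len=length,
                    identity=pident / 100.0,
                    longest_contig_block=max(length - gapopen, 0),
                    longest_perfect_block=0,
                    score=int(round(bitscore)),
                )
            )
    return out
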