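"""Phased nat-siRNA detection inside perfectly annealed regions.

Dicer-like (DCL) proteins process the double-stranded region of an annealed
NAT pair processively, releasing successive sRNA duplexes with 2-nt 3′
overhangs.  On the sense strand this leaves sRNA 5′ ends spaced exactly one
sRNA length *n* apart (a fixed phase *register*); each sense sRNA occupying
``[i, i+n-1]`` pairs an antisense partner whose footprint, expressed in sense
coordinates, is ``[i-2, i+n-3]`` — the 2-nt offset at both ends is forced by
the overhang geometry.

Detection is combinatorial, per perfect segment longer than 80 bp and per
sRNA length: reads are mapped exactly and strand-specifically (a read is
evidence for the transcript it matches in sense orientation); for each
register a grid of phase slots is built, a slot counts as *evidenced* when a
read 5′ end sits exactly on the slot's sense 5′ end or on its antisense
partner's 5′ end (evidence on either strand of the duplex suffices — weakly
expressed strands are routinely missing from sRNA libraries), and every
maximal run of at least ``min_duplexes`` consecutive evidenced slots is
reported as a phased cluster.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .duplex_validation import NatPair, PerfectSegment
from .seqio import LibraryStats, ShortRead, rpm

__all__ = [
    "PhasingParams",
    "MappedSRNA",
    "SubstringIndex",
    "map_srnas",
    "cross_coordinate",
    "PhaseSlot",
    "PhasedCluster",
    "enumerate_phase_runs",
    "find_phased_clusters",
    "read_bowtie_map",
]


@dataclass(frozen=True)
class PhasingParams:
    """Detection thresholds.

    ``min_region_len`` is strict-greater-than-80-bp by default (81 is the
    shortest segment searched); ``min_duplexes`` the minimum consecutive
    phases per cluster; ``overhang`` is fixed at 2 nt by Dicer geometry and
    exposed only for clarity.
    """

    min_region_len: int = 81
    min_duplexes: int = 4
    srna_len_set: tuple[int, ...] = (21, 24)
    overhang: int = 2
    require_both_strands: bool = False
    allow_edge_overhang: bool = False
    index_k: int = 12

    def __post_init__(self) -> None:
        if self.min_duplexes < 2:
            raise ValueError("min_duplexes must be >= 2")
        if self.overhang != 2:
            raise ValueError("the 2-nt 3' overhang is fixed by Dicer geometry")
        if self.min_region_len < 1:
            raise ValueError("min_region_len must be >= 1")


@dataclass(frozen=True)
class MappedSRNA:
    """A perfect, sense-orientation placement of a read on a transcript
    (1-based inclusive).  Antisense relationships are represented by the
    same read matching the *partner* transcript in sense orientation."""

    read: ShortRead
    transcript_id: str
    start: int
    end: int

    @property
    def library(self) -> str:
        return self.read.library

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SubstringIndex:
    """Exact-occurrence index over a set of transcripts.

    A k-mer prefix index: every read's first ``k`` bases select candidate
    positions, each verified by full string comparison.  Reads shorter than
    ``k`` fall back to a direct scan.
    """

    def __init__(self, transcripts: Mapping[str, str], k: int = 12):
        self.k = k
        self.transcripts = dict(transcripts)
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid in sorted(self.transcripts):
            seq = self.transcripts[tid]
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((tid, i))

    def occurrences(self, seq: str) -> list[tuple[str, int]]:
        """All (transcript_id, 1-based start) exact sense occurrences."""
        hits: list[tuple[str, int]] = []
        if len(seq) < self.k:
            for tid in sorted(self.transcripts):
                tseq = self.transcripts[tid]
                pos = tseq.find(seq)
                while pos != -1:
                    hits.append((tid, pos + 1))
                    pos = tseq.find(seq, pos + 1)
            return hits
        for tid, i in self._index.get(seq[: self.k], ()):
            if self.transcripts[tid].startswith(seq, i):
                hits.append((tid, i + 1))
        return hits


def map_srnas(
    reads: Iterable[ShortRead],
    transcripts: Mapping[str, str],
    k: int = 12,
) -> list[MappedSRNA]:
    """Map collapsed reads onto transcripts, keeping every perfect
    sense-orientation occurrence (multi-mapping allowed, no weighting)."""
    index = SubstringIndex(transcripts, k=k)
    mapped: list[MappedSRNA] = []
    for read in reads:
        for tid, start in index.occurrences(read.seq):
            mapped.append(
                MappedSRNA(
                    read=read,
                    transcript_id=tid,
                    start=start,
                    end=start + len(read.seq) - 1,
                )
            )
    mapped.sort(key=lambda h: (h.transcript_id, h.start, h.read.library, h.read.id))
    return mapped


def cross_coordinate(x: int, segment: PerfectSegment) -> int:
    """Map a position inside a perfect segment from transcript A to the
    antiparallel position on transcript B (an involution)."""
    if not segment.a_start <= x <= segment.a_end:
        raise ValueError(f"position {x} outside segment {segment}")
    return segment.b_start + (segment.a_end - x)


@dataclass
class PhaseSlot:
    """One phase position of a grid: the sense sRNA interval and its
    antisense partner's footprint, both in transcript-A coordinates."""

    index: int
    sense_start: int
    srna_len: int
    sense_hits: list[MappedSRNA] = field(default_factory=list)
    antisense_hits: list[MappedSRNA] = field(default_factory=list)

    @property
    def sense_interval(self) -> tuple[int, int]:
        return (self.sense_start, self.sense_start + self.srna_len - 1)

    @property
    def antisense_interval(self) -> tuple[int, int]:
        return (self.sense_start - 2, self.sense_start + self.srna_len - 3)

    @property
    def evidenced_sense(self) -> bool:
        return bool(self.sense_hits)

    @property
    def evidenced_antisense(self) -> bool:
        return bool(self.antisense_hits)


@dataclass
class PhasedCluster:
    """A maximal run of consecutive evidenced phase slots.

    ``register`` is the sense 5′-end offset of the grid within the segment
    (``(slot_start - segment.a_start) mod srna_len``); ``slots`` holds only
    the run's slots, in order.  Library presence and per-sRNA RPM values are
    attached by :func:`find_phased_clusters`.
    """

    id_a: str
    id_b: str
    segment: PerfectSegment
    srna_len: int
    register: int
    slots: list[PhaseSlot]
    per_library_presence: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    srna_rpm: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(self.slots)

    @property
    def srna_seqs(self) -> set[str]:
        return {
            h.read.seq for s in self.slots for h in (s.sense_hits + s.antisense_hits)
        }

    @property
    def n_srnas(self) -> int:
        return len(self.srna_seqs)

    @property
    def cluster_id(self) -> str:
        seg = self.segment
        return (
            f"{self.id_a}|{self.id_b}|{seg.a_start}-{seg.a_end}"
            f"|n{self.srna_len}|r{self.register}|p{self.slots[0].sense_start}"
        )

    def hits(self) -> list[MappedSRNA]:
        return [h for s in self.slots for h in (s.sense_hits + s.antisense_hits)]


def enumerate_phase_runs(
    segment: PerfectSegment,
    hits_a: Sequence[MappedSRNA],
    hits_b: Sequence[MappedSRNA],
    n: int,
    params: PhasingParams | None = None,
    id_a: str = "A",
    id_b: str = "B",
) -> list[PhasedCluster]:
    """Detect phased clusters of sRNA length ``n`` inside one perfect segment.

    ``hits_a`` are sense placements on transcript A, ``hits_b`` sense
    placements on transcript B (the antisense strand of the duplex).  For
    each register the slot grid is laid out from ``segment.a_start``; a hit
    evidences a slot only if its 5′ end coincides exactly with the slot's
    sense 5′ end (on A) or with the antisense partner's 5′ end (on B, via the
    antiparallel coordinate map).  Maximal runs of ``min_duplexes`` or more
    consecutive evidenced slots become clusters.
    """
    params = params or PhasingParams()
    if segment.length < params.min_region_len or segment.length < n + 2:
        return []

    # sense evidence: 5' end at slot start, footprint inside the segment
    sense_by_start: dict[int, list[MappedSRNA]] = defaultdict(list)
    for h in hits_a:
        if h.length == n and h.start >= segment.a_start and h.end <= segment.a_end:
            sense_by_start[h.start].append(h)

    # antisense evidence: a sense hit on B whose 5' end maps to the partner
    # 5' end (sense coordinate slot_start + n - 3)
    edge = 2 if params.allow_edge_overhang else 0
    anti_by_slot_start: dict[int, list[MappedSRNA]] = defaultdict(list)
    for h in hits_b:
        if h.length != n:
            continue
        if h.start < segment.b_start or h.end > segment.b_end + edge:
            continue
        x = segment.a_end - (h.start - segment.b_start)  # sense coord of B 5' end
        anti_by_slot_start[x - n + 3].append(h)

    clusters: list[PhasedCluster] = []
    for register in range(n):
        starts = list(
            range(segment.a_start + register, segment.a_end - n + 2, n)
        )
        if not starts:
            continue
        slots = [
            PhaseSlot(
                index=t,
                sense_start=i,
                srna_len=n,
                sense_hits=sense_by_start.get(i, []),
                antisense_hits=anti_by_slot_start.get(i, []),
            )
            for t, i in enumerate(starts)
        ]
        if params.require_both_strands:
            flags = [s.evidenced_sense and s.evidenced_antisense for s in slots]
        else:
            flags = [s.evidenced_sense or s.evidenced_antisense for s in slots]

        t = 0
        while t < len(slots):
            if not flags[t]:
                t += 1
                continue
            u = t
            while u + 1 < len(slots) and flags[u + 1]:
                u += 1
            if u - t + 1 >= params.min_duplexes:
                clusters.append(
                    PhasedCluster(
                        id_a=id_a,
                        id_b=id_b,
                        segment=segment,
                        srna_len=n,
                        register=register,
                        slots=slots[t : u + 1],
                    )
                )
            t = u + 1
    clusters.sort(key=lambda c: (c.register, c.slots[0].sense_start))
    return clusters


def find_phased_clusters(
    nats: Sequence[NatPair],
    mapped: Sequence[MappedSRNA],
    params: PhasingParams | None = None,
    stats: Mapping[str, LibraryStats] | None = None,
) -> list[PhasedCluster]:
    """Run phase detection over every qualifying perfect segment of every
    retained NAT pair, for every sRNA length in ``srna_len_set``.

    Evidence is the union across libraries; per-library presence and RPM
    values are recorded on each cluster for reporting.
    """
    params = params or PhasingParams()
    by_transcript: dict[str, list[MappedSRNA]] = defaultdict(list)
    for h in mapped:
        by_transcript[h.transcript_id].append(h)

    clusters: list[PhasedCluster] = []
    for nat in nats:
        for seg in nat.perfect_segments:
            if seg.length < params.min_region_len:
                continue
            hits_a = by_transcript.get(nat.id_a, [])
            hits_b = by_transcript.get(nat.id_b, [])
            for n in sorted(params.srna_len_set):
                clusters.extend(
                    enumerate_phase_runs(
                        seg, hits_a, hits_b, n, params, id_a=nat.id_a, id_b=nat.id_b
                    )
                )

    for c in clusters:
        presence: dict[str, list[tuple[int, str]]] = defaultdict(list)
        rpm_map: dict[str, dict[str, float]] = defaultdict(dict)
        for slot in c.slots:
            for strand, hits in (("sense", slot.sense_hits), ("antisense", slot.antisense_hits)):
                for h in hits:
                    presence[h.library].append((slot.index, strand))
                    if stats and h.library in stats:
                        rpm_map[h.read.seq][h.library] = rpm(
                            h.read.count, stats[h.library]
                        )
        c.per_library_presence = {k: sorted(set(v)) for k, v in sorted(presence.items())}
        c.srna_rpm = {k: dict(v) for k, v in rpm_map.items()}

    clusters.sort(
        key=lambda c: (c.id_a, c.id_b, c.segment.a_start, c.srna_len, c.register,
                       c.slots[0].sense_start)
    )
    return clusters


def read_bowtie_map(
    path: str,
    reads_by_id: Mapping[str, ShortRead],
) -> list[MappedSRNA]:
    """Convert Bowtie legacy map output to :class:`MappedSRNA` records.

    Columns: read id, strand (+/-), reference, 0-based offset, sequence, …
    Only plus-strand (sense) records are kept, matching the pipeline's
    strand-specific contract.  Read IDs must resolve via ``reads_by_id``
    (the collapsed-library records), so counts and libraries are preserved.
    """
    mapped: list[MappedSRNA] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or f[1] != "+":
                continue
            rid, ref, off, seq = f[0], f[2], int(f[3]), f[4]
            base_id = rid.rsplit("_x", 1)[0] if "_x" in rid else rid
            read = reads_by_id.get(base_id)
            if read is None or read.seq != seq.upper().replace("U", "T"):
                continue
            mapped.append(
                MappedSRNA(
                    read=read, transcript_id=ref, start=off + 1, end=off + len(seq)
                )
            )
    mapped.sort(key=lambda h: (h.transcript_id, h.start, h.read.library, h.read.id))
    return mapped
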