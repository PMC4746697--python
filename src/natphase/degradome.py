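"""Degradome (PARE) evidence for phased nat-siRNA processing.

Degradome sequencing captures the 5′ ends of uncapped RNA fragments,
including the poly(A)-tailed remnants left behind while Dicer works along a
double-stranded precursor.  A degradome tag therefore supports a phased
nat-siRNA locus when, after perfect strand-specific mapping, its 5′ end
falls exactly on

* the 5′ end of one of the cluster's phased siRNAs (on either strand), or
* the nucleotide immediately 3′ of the last phased siRNA of the cluster on
  a strand (the expected next cleavage position).

Note most degradome libraries are built from poly(A)-tailed RNA, so
processing signals from non-Pol-II transcripts are invisible; reports carry
this caveat as a footnote.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .phasing import MappedSRNA, PhasedCluster, cross_coordinate, map_srnas
from .seqio import LibraryStats, ShortRead, rpm

__all__ = [
    "DegradomeEvidence",
    "map_degradome",
    "assign_evidence",
    "summarize_support",
]

POLYA_CAVEAT = (
    "Degradome libraries prepared from poly(A)-tailed RNA cannot report "
    "processing signals from non-Pol II transcripts."
)


@dataclass(frozen=True)
class DegradomeEvidence:
    """One degradome tag supporting one phased cluster.

    ``slot_index`` is the supported slot within the cluster's run, or
    ``None`` for terminus evidence (5′ end just past the last phased siRNA).
    ``strand`` is "sense" (transcript A of the pair) or "antisense"
    (transcript B); ``five_prime_pos`` is in that transcript's own 1-based
    coordinates.
    """

    tag: ShortRead
    transcript_id: str
    five_prime_pos: int
    cluster_id: str
    slot_index: int | None
    strand: str
    rpm: float | None = None

    @property
    def is_terminus(self) -> bool:
        return self.slot_index is None

    @property
    def library(self) -> str:
        return self.tag.library

    @property
    def count(self) -> int:
        return self.tag.count


def map_degradome(
    tags: Iterable[ShortRead],
    transcripts: Mapping[str, str],
    clusters: Sequence[PhasedCluster],
    k: int = 12,
) -> list[MappedSRNA]:
    """Map degradome tags perfectly and strand-specifically, restricted to
    transcripts that carry at least one phased cluster."""
    with_clusters = {c.id_a for c in clusters} | {c.id_b for c in clusters}
    sub = {tid: seq for tid, seq in transcripts.items() if tid in with_clusters}
    return map_srnas(tags, sub, k=k)


def _cluster_anchor_positions(
    cluster: PhasedCluster,
) -> tuple[dict[int, int], dict[int, int], int, int]:
    """5′-end anchors of one cluster.

    Returns (sense anchors, antisense anchors, sense terminus, antisense
    terminus): anchors map slot index → 5′-end position in the respective
    transcript's coordinates; the termini are the positions immediately 3′
    of the last phased siRNA on each strand.
    """
    n = cluster.srna_len
    seg = cluster.segment
    sense: dict[int, int] = {}
    anti: dict[int, int] = {}
    for slot in cluster.slots:
        sense[slot.index] = slot.sense_start
        # antisense 5' end sits at sense coordinate slot_start + n - 3
        anti[slot.index] = cross_coordinate(slot.sense_start + n - 3, seg)
    first = cluster.slots[0].sense_start
    last = cluster.slots[-1].sense_start
    sense_terminus = last + n  # one past the last sense siRNA's 3' end
    # the most-3' antisense siRNA (in B coordinates) partners the FIRST slot;
    # its 3' end maps from sense coordinate first - 2
    anti_terminus = cross_coordinate(max(first - 2, seg.a_start), seg) + 1
    if first - 2 < seg.a_start:
        # partner footprint exits the segment: place the terminus just past
        # the mapped 3'-most position actually inside the segment
        anti_terminus = seg.b_end + (seg.a_start - (first - 2)) + 1
    return sense, anti, sense_terminus, anti_terminus


def assign_evidence(
    mapped_tags: Sequence[MappedSRNA],
    clusters: Sequence[PhasedCluster],
    stats: Mapping[str, LibraryStats] | None = None,
    window: int = 0,
) -> list[DegradomeEvidence]:
    """Attach degradome tags to the clusters they support.

    A tag supports slot *k* of a cluster when its 5′ end equals the slot's
    siRNA 5′ end on that strand, and the cluster terminus when it equals the
    last phased siRNA's 3′ end + 1 (checked on both strands).  ``window``
    widens the match to ±window nt (default 0: exact).  One tag may support
    several clusters.
    """
    by_pos: dict[tuple[str, int], list[MappedSRNA]] = defaultdict(list)
    for h in mapped_tags:
        by_pos[(h.transcript_id, h.start)].append(h)

    def tags_at(tid: str, pos: int) -> list[MappedSRNA]:
        out: list[MappedSRNA] = []
        for p in range(pos - window, pos + window + 1):
            out.extend(by_pos.get((tid, p), ()))
        return out

    evidence: list[DegradomeEvidence] = []
    for cluster in clusters:
        sense, anti, sense_term, anti_term = _cluster_anchor_positions(cluster)
        targets: list[tuple[str, int, int | None, str]] = []
        for idx, pos in sense.items():
            targets.append((cluster.id_a, pos, idx, "sense"))
        for idx, pos in anti.items():
            targets.append((cluster.id_b, pos, idx, "antisense"))
        targets.append((cluster.id_a, sense_term, None, "sense"))
        targets.append((cluster.id_b, anti_term, None, "antisense"))

        for tid, pos, slot_idx, strand in targets:
            for h in tags_at(tid, pos):
                ev_rpm = (
                    rpm(h.read.count, stats[h.library])
                    if stats and h.library in stats
                    else None
                )
                evidence.append(
                    DegradomeEvidence(
                        tag=h.read,
                        transcript_id=tid,
                        five_prime_pos=h.start,
                        cluster_id=cluster.cluster_id,
                        slot_index=slot_idx,
                        strand=strand,
                        rpm=ev_rpm,
                    )
                )
    evidence.sort(
        key=lambda e: (e.cluster_id, e.strand, e.slot_index is None,
                       e.slot_index or 0, e.transcript_id, e.five_prime_pos,
                       e.library, e.tag.id)
    )
    return evidence


def summarize_support(
    clusters: Sequence[PhasedCluster],
    evidence: Sequence[DegradomeEvidence],
) -> dict[str, int]:
    """Count degradome-supported siRNAs and clusters.

    A phased siRNA (a distinct mapped sRNA sequence on one strand of one
    cluster) is supported when its (cluster, slot, strand) has at least one
    5′-end evidence record.  Counts are cluster-assigned, mirroring how
    phased siRNAs themselves are counted.
    """
    supported_slots: dict[str, set[tuple[int, str]]] = defaultdict(set)
    for e in evidence:
        if e.slot_index is not None:
            supported_slots[e.cluster_id].add((e.slot_index, e.strand))

    n_phased = 0
    n_supported = 0
    supported_clusters: set[str] = set()
    for c in clusters:
        phased_seqs: set[str] = set()
        supported_seqs: set[str] = set()
        slots_hit = supported_slots.get(c.cluster_id, set())
        for slot in c.slots:
            for strand, hits in (
                ("sense", slot.sense_hits),
                ("antisense", slot.antisense_hits),
            ):
                for h in hits:
                    phased_seqs.add(h.read.seq)
                    if (slot.index, strand) in slots_hit:
                        supported_seqs.add(h.read.seq)
        n_phased += len(phased_seqs)
        n_supported += len(supported_seqs)
        if c.cluster_id in {e.cluster_id for e in evidence}:
            supported_clusters.add(c.cluster_id)
    return {
        "phased_srnas": n_phased,
        "supported_srnas": n_supported,
        "clusters": len(clusters),
        "supported_clusters": len(supported_clusters),
    }
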