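"""Orchestration of the discovery stages and report generation.

The workflow has two separable halves, run in order as data allows:

1. *NAT prediction* — antisense alignment, classification, duplex-structure
   validation, retention filtering, cis-candidate flagging.  Requires only
   the assembled transcripts.
2. *Phased-siRNA search* — strand-specific exact read mapping, phase-grid
   cluster detection, and (when degradome libraries are given) 5′-end
   processing evidence.

Outputs are deterministic TSV tables (summary + per-entity detail), a
human-readable plain-text report, and a YAML copy of the effective
configuration for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import degradome as degradome_mod
from .antisense_search import (
    AlignerParams,
    ClassifyParams,
    ComplementaryMatch,
    classify_match,
    find_complementary_pairs,
)
from .degradome import DegradomeEvidence, POLYA_CAVEAT
from .duplex_validation import DuplexParams, NatPair, build_nat_pairs
from .phasing import (
    MappedSRNA,
    PhasedCluster,
    PhasingParams,
    find_phased_clusters,
    map_srnas,
)
from .seqio import LibraryStats, ShortRead, Transcript, read_collapsed_reads, read_fasta

__all__ = ["RunConfig", "RunResult", "run", "run_files", "write_reports"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; validated up front, serialized alongside
    the outputs.  ``srna_libraries`` / ``degradome_libraries`` map library
    name → collapsed-FASTA path; either may be empty (NAT prediction then
    runs alone)."""

    transcripts: str | Path | None = None
    srna_libraries: dict[str, str] = field(default_factory=dict)
    degradome_libraries: dict[str, str] = field(default_factory=dict)
    outdir: str | Path | None = None
    aligner: AlignerParams = field(default_factory=AlignerParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    duplex: DuplexParams = field(default_factory=DuplexParams)
    overlap_min: float = 0.8
    bubble_max_frac: float = 0.10
    bubble_denominator: str = "strand_a"
    phasing: PhasingParams = field(default_factory=PhasingParams)
    degradome_window: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.transcripts is None:
            problems.append("no transcript FASTA given")
        elif not Path(self.transcripts).is_file():
            problems.append(f"transcript file not found: {self.transcripts}")
        for name, path in {**self.srna_libraries, **self.degradome_libraries}.items():
            if not Path(path).is_file():
                problems.append(f"library {name!r}: file not found: {path}")
        if not 0 < self.overlap_min <= 1:
            problems.append("overlap_min must be in (0, 1]")
        if not 0 < self.bubble_max_frac < 1:
            problems.append("bubble_max_frac must be in (0, 1)")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


@dataclass
class RunResult:
    transcripts: list[Transcript]
    matches: list[ComplementaryMatch]
    nat_pairs: list[NatPair]
    mapped_srnas: list[MappedSRNA]
    clusters: list[PhasedCluster]
    evidence: list[DegradomeEvidence]
    library_stats: dict[str, LibraryStats]
    summary: dict[str, int]


def run(
    transcripts: list[Transcript],
    srna_reads: list[ShortRead] | None = None,
    degradome_tags: list[ShortRead] | None = None,
    library_stats: dict[str, LibraryStats] | None = None,
    config: RunConfig | None = None,
) -> RunResult:
    """Run the workflow on in-memory records (the library-level entry point).

    ``srna_reads`` and ``degradome_tags`` are optional: without sRNA data
    only the NAT-prediction half runs; degradome evidence additionally
    requires detected clusters.
    """
    config = config or RunConfig()
    srna_reads = srna_reads or []
    degradome_tags = degradome_tags or []
    library_stats = library_stats or {}
    seqs = {t.id: t.seq for t in transcripts}
    lengths = {t.id: t.length for t in transcripts}

    matches = find_complementary_pairs(transcripts, config.aligner)
    for m in matches:
        m.nat_class = classify_match(m, lengths[m.id_a], lengths[m.id_b], config.classify)
    logger.info("alignment stage: %d complementary regions", len(matches))

    nat_pairs = build_nat_pairs(
        seqs,
        matches,
        config.duplex,
        overlap_min=config.overlap_min,
        bubble_max_frac=config.bubble_max_frac,
        bubble_denominator=config.bubble_denominator,
    )
    logger.info("structure stage: %d regions retained", len(nat_pairs))

    mapped: list[MappedSRNA] = []
    clusters: list[PhasedCluster] = []
    if srna_reads:
        searched_ids = {
            tid
            for nat in nat_pairs
            for seg in nat.perfect_segments
            if seg.length >= config.phasing.min_region_len
            for tid in (nat.id_a, nat.id_b)
        }
        mapped = map_srnas(
            srna_reads,
            {tid: seqs[tid] for tid in searched_ids},
            k=config.phasing.index_k,
        )
        clusters = find_phased_clusters(
            nat_pairs, mapped, config.phasing, stats=library_stats
        )
        logger.info("phasing stage: %d clusters", len(clusters))

    evidence: list[DegradomeEvidence] = []
    if degradome_tags and clusters:
        mapped_tags = degradome_mod.map_degradome(
            degradome_tags, seqs, clusters, k=config.phasing.index_k
        )
        evidence = degradome_mod.assign_evidence(
            mapped_tags, clusters, stats=library_stats, window=config.degradome_window
        )
        logger.info("degradome stage: %d evidence records", len(evidence))

    summary = _summarize(transcripts, matches, nat_pairs, clusters, evidence, config)
    return RunResult(
        transcripts=transcripts,
        matches=matches,
        nat_pairs=nat_pairs,
        mapped_srnas=mapped,
        clusters=clusters,
        evidence=evidence,
        library_stats=library_stats,
        summary=summary,
    )


def run_files(config: RunConfig) -> RunResult:
    """File-level entry point: read inputs per ``config``, run, and (when
    ``config.outdir`` is set) write the reports."""
    config.validate()
    transcripts = read_fasta(config.transcripts)

    srna_reads: list[ShortRead] = []
    degradome_tags: list[ShortRead] = []
    stats: dict[str, LibraryStats] = {}
    for lib, path in sorted(config.srna_libraries.items()):
        reads, st = read_collapsed_reads(path, library=lib, kind="srna")
        srna_reads.extend(reads)
        stats[lib] = st
    for lib, path in sorted(config.degradome_libraries.items()):
        reads, st = read_collapsed_reads(path, library=lib, kind="degradome")
        degradome_tags.extend(reads)
        stats[lib] = st

    result = run(transcripts, srna_reads, degradome_tags, stats, config)
    if config.outdir is not None:
        write_reports(result, config.outdir, config)
    return result


def _summarize(
    transcripts: list[Transcript],
    matches: list[ComplementaryMatch],
    nat_pairs: list[NatPair],
    clusters: list[PhasedCluster],
    evidence: list[DegradomeEvidence],
    config: RunConfig,
) -> dict[str, int]:
    pair_key = lambda m: (m.id_a, m.id_b)
    all_pairs = {pair_key(m) for m in matches if m.nat_class != "none"}
    hc_pairs = {pair_key(m) for m in matches if m.nat_class in ("HC", "both")}
    nt100_pairs = {pair_key(m) for m in matches if m.nat_class in ("NT100", "both")}

    searched_regions = sum(
        1
        for nat in nat_pairs
        for seg in nat.perfect_segments
        if seg.length >= config.phasing.min_region_len
    )
    searched_pairs = {
        (nat.id_a, nat.id_b)
        for nat in nat_pairs
        if any(s.length >= config.phasing.min_region_len for s in nat.perfect_segments)
    }
    support = degradome_mod.summarize_support(clusters, evidence)

    cluster_regions = {(c.id_a, c.id_b, c.segment.a_start, c.segment.a_end) for c in clusters}
    cluster_pairs = {(c.id_a, c.id_b) for c in clusters}
    return {
        "transcripts": len(transcripts),
        "complementary_pairs": len(all_pairs),
        "hc_pairs": len(hc_pairs),
        "nt100_pairs": len(nt100_pairs),
        "retained_regions": len(nat_pairs),
        "retained_pairs": len({(n.id_a, n.id_b) for n in nat_pairs}),
        "cis_candidate_pairs": len(
            {(n.id_a, n.id_b) for n in nat_pairs if n.is_cis_candidate}
        ),
        "regions_searched": searched_regions,
        "pairs_searched": len(searched_pairs),
        "clusters": support["clusters"],
        "regions_with_clusters": len(cluster_regions),
        "pairs_with_clusters": len(cluster_pairs),
        "phased_srnas": support["phased_srnas"],
        "supported_srnas": support["supported_srnas"],
        "supported_clusters": support["supported_clusters"],
    }


# --- report writers --------------------------------------------------------


def _nat_table(nat_pairs: list[NatPair]) -> pd.DataFrame:
    rows = []
    for nat in nat_pairs:
        d = nat.duplex
        m = nat.match
        rows.append(
            {
                "transcript_a": nat.id_a,
                "transcript_b": nat.id_b,
                "nat_class": m.nat_class,
                "a_region_start": d.a_region[0],
                "a_region_end": d.a_region[1],
                "b_region_start": d.b_region[0],
                "b_region_end": d.b_region[1],
                "aln_score": m.score,
                "identity": round(m.identity, 4),
                "n_perfect_segments": d.n_perfect_segments,
                "longest_perfect_segment": max(s.length for s in d.perfect_segments),
                "n_bubbles": len(d.bubbles),
                "max_bubble_size": max((b.size for b in d.bubbles), default=0),
                "cis_candidate": nat.is_cis_candidate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_a", "transcript_b", "nat_class",
            "a_region_start", "a_region_end", "b_region_start", "b_region_end",
            "aln_score", "identity", "n_perfect_segments",
            "longest_perfect_segment", "n_bubbles", "max_bubble_size",
            "cis_candidate",
        ],
    )


def _cluster_table(clusters: list[PhasedCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "transcript_a": c.id_a,
                "transcript_b": c.id_b,
                "segment_a_start": c.segment.a_start,
                "segment_a_end": c.segment.a_end,
                "segment_b_start": c.segment.b_start,
                "segment_b_end": c.segment.b_end,
                "srna_len": c.srna_len,
                "register": c.register,
                "first_slot_start": c.slots[0].sense_start,
                "n_phases": c.n_phases,
                "n_srnas": c.n_srnas,
                "libraries": ",".join(sorted(c.per_library_presence)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "transcript_a", "transcript_b",
            "segment_a_start", "segment_a_end", "segment_b_start", "segment_b_end",
            "srna_len", "register", "first_slot_start", "n_phases", "n_srnas",
            "libraries",
        ],
    )


def _srna_table(clusters: list[PhasedCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for slot in c.slots:
            for strand, hits in (
                ("sense", slot.sense_hits),
                ("antisense", slot.antisense_hits),
            ):
                for h in hits:
                    rows.append(
                        {
                            "cluster_id": c.cluster_id,
                            "slot_index": slot.index,
                            "strand": strand,
                            "transcript": h.transcript_id,
                            "start": h.start,
                            "end": h.end,
                            "read_id": h.read.id,
                            "library": h.library,
                            "count": h.read.count,
                            "rpm": round(
                                c.srna_rpm.get(h.read.seq, {}).get(h.library, float("nan")),
                                3,
                            ),
                            "seq": h.read.seq,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "slot_index", "strand", "transcript", "start", "end",
            "read_id", "library", "count", "rpm", "seq",
        ],
    )


def _evidence_table(evidence: list[DegradomeEvidence]) -> pd.DataFrame:
    rows = []
    for e in evidence:
        rows.append(
            {
                "cluster_id": e.cluster_id,
                "target": "terminus" if e.is_terminus else f"slot_{e.slot_index}",
                "strand": e.strand,
                "transcript": e.transcript_id,
                "five_prime_pos": e.five_prime_pos,
                "tag_id": e.tag.id,
                "library": e.library,
                "count": e.count,
                "rpm": round(e.rpm, 3) if e.rpm is not None else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "target", "strand", "transcript", "five_prime_pos",
            "tag_id", "library", "count", "rpm",
        ],
    )


def render_text_report(result: RunResult) -> str:
    """Human-readable report: one numbered block per NAT pair with phased
    clusters, in the style of a result summary for manual inspection."""
    lines: list[str] = ["# NAT / phased nat-siRNA discovery report", ""]
    lines.append("## Summary")
    for key, val in result.summary.items():
        lines.append(f"  {key}: {val}")
    lines.append("")

    by_pair: dict[tuple[str, str], list[PhasedCluster]] = {}
    for c in result.clusters:
        by_pair.setdefault((c.id_a, c.id_b), []).append(c)
    ev_by_cluster: dict[str, list[DegradomeEvidence]] = {}
    for e in result.evidence:
        ev_by_cluster.setdefault(e.cluster_id, []).append(e)

    nat_by_pair: dict[tuple[str, str], list[NatPair]] = {}
    for nat in result.nat_pairs:
        nat_by_pair.setdefault((nat.id_a, nat.id_b), []).append(nat)

    for idx, ((id_a, id_b), clusters) in enumerate(sorted(by_pair.items()), 1):
        lines.append(f"## Pair {idx}: {id_a} / {id_b}")
        for nat in nat_by_pair.get((id_a, id_b), []):
            d = nat.duplex
            lines.append(
                f"  (1) annealed region: {id_a} from {d.a_region[0]:,}th to "
                f"{d.a_region[1]:,}th nucleotide; {id_b} from {d.b_region[0]:,}th "
                f"to {d.b_region[1]:,}th nucleotide"
                + ("  [cis-NAT candidate]" if nat.is_cis_candidate else "")
            )
        for c in clusters:
            libs = ", ".join(sorted(c.per_library_presence)) or "-"
            lines.append(
                f"  (2) cluster {c.cluster_id}: {c.n_srnas} nat-siRNAs assigned "
                f"to {c.n_phases} consecutive phases ({c.srna_len}-nt register "
                f"{c.register}); libraries: {libs}"
            )
            for e in ev_by_cluster.get(c.cluster_id, []):
                target = "terminus" if e.is_terminus else f"slot {e.slot_index}"
                rpm_txt = f"{e.rpm:.2f} RPM" if e.rpm is not None else f"{e.count} reads"
                lines.append(
                    f"  (3) degradome tag {e.tag.id} ({e.library}, {rpm_txt}) "
                    f"supports {target} [{e.strand}] at position {e.five_prime_pos:,} "
                    f"of {e.transcript_id}"
                )
        lines.append("")
    if result.evidence or result.clusters:
        lines.append(f"Note: {POLYA_CAVEAT}")
        lines.append("")
    return "\n".join(lines)


def write_reports(result: RunResult, outdir: str | Path, config: RunConfig) -> None:
    """Write the TSV tables, the text report and the provenance config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        sorted(result.summary.items()), columns=["metric", "value"]
    ).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    _nat_table(result.nat_pairs).to_csv(outdir / "nat_pairs.tsv", sep="\t", index=False)
    _cluster_table(result.clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    _srna_table(result.clusters).to_csv(outdir / "cluster_srnas.tsv", sep="\t", index=False)
    _evidence_table(result.evidence).to_csv(
        outdir / "degradome_evidence.tsv", sep="\t", index=False
    )
    (outdir / "report.txt").write_text(render_text_report(result))

    cfg = {
        "transcripts": str(config.transcripts),
        "srna_libraries": {k: str(v) for k, v in config.srna_libraries.items()},
        "degradome_libraries": {
            k: str(v) for k, v in config.degradome_libraries.items()
        },
        "aligner": vars(config.aligner).copy(),
        "classify": vars(config.classify).copy(),
        "duplex": vars(config.duplex).copy(),
        "overlap_min": config.overlap_min,
        "bubble_max_frac": config.bubble_max_frac,
        "bubble_denominator": config.bubble_denominator,
        "phasing": {
            **vars(config.phasing),
            "srna_len_set": list(config.phasing.srna_len_set),
        },
        "degradome_window": config.degradome_window,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
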