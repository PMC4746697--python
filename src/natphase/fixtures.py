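"""Deterministic synthetic NAT fixtures with exact ground truth.

The generator emulates the inputs of the discovery workflow on a desk
scale: one planted NAT pair (transcript A carrying a complementary *core*
that transcript B contains in reverse complement, optionally damaged by
mismatches and one bubble), decoy transcripts, phased sRNA libraries cut
from the two strands with exact 2-nt 3′-overhang duplex geometry, and
degradome tags placed on siRNA 5′ ends and on the position just past the
last phased siRNA.

Every random draw comes from one integer seed, so the same spec always
produces byte-identical files.  The construction is adversarial-free by
design, which is what makes the ground truth exact rather than approximate:

* decoys are rejection-sampled until they share no k-mer with any other
  transcript in either orientation, so they can neither seed an antisense
  alignment nor receive a read;
* the bases flanking the planted core are forced to be non-pairing on the
  extension diagonal, so the optimal local alignment covers exactly the
  core;
* defect positions keep safety margins from the core ends and from each
  other, defect-adjacent bases are resampled until the optimal bubble
  placement is unique, and every planted read / tag sequence is verified to
  occur exactly once across the transcript set (the construction is retried
  under a fresh substream otherwise).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .antisense_search import revcomp
from .seqio import ShortRead, Transcript, write_collapsed_reads, write_fasta

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "Fixture",
    "make_nat_pair",
    "make_decoys",
    "make_phased_reads",
    "make_fixture",
    "write_fixture",
    "random_fixture_spec",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic NAT scenario.

    ``mismatches`` are 1-based core positions; ``bubble`` is
    ``(core_pos, a_len, b_len)``: ``a_len`` bases of the core left unpaired
    (their complements deleted from B's copy) and ``b_len`` foreign bases
    inserted into B at the same junction.  ``register_offset`` places the
    first phased slot that many nt into the longest perfect segment.
    ``drop_sense`` / ``drop_antisense`` remove planted reads per slot index
    to exercise the either-strand evidence rule.
    """

    seed: int = 0
    region_len: int = 120
    srna_len: int = 21
    n_duplex: int = 4
    register_offset: int = 3
    mismatches: tuple[int, ...] = ()
    bubble: tuple[int, int, int] | None = None
    n_decoys: int = 5
    decoy_len: int = 220
    flank_a: tuple[int, int] = (60, 60)
    flank_b: tuple[int, int] = (40, 40)
    libraries: tuple[str, ...] = ("lib1",)
    degradome_libraries: tuple[str, ...] = ("deg1",)
    max_count: int = 50
    drop_sense: tuple[int, ...] = ()
    drop_antisense: tuple[int, ...] = ()
    degradome_slots: tuple[int, ...] = (0,)
    degradome_antisense_slots: tuple[int, ...] = ()
    degradome_terminus: bool = True
    degradome_antisense_terminus: bool = False
    n_noise_reads: int = 2
    seed_len: int = 12

    def __post_init__(self) -> None:
        if self.region_len <= self.srna_len + 2:
            raise ValueError("region_len must exceed srna_len + 2")
        if self.n_duplex < 1:
            raise ValueError("n_duplex must be >= 1")
        if not 0 <= self.register_offset < self.srna_len:
            raise ValueError("register_offset must lie in [0, srna_len)")
        for p in self.mismatches:
            if not 16 <= p <= self.region_len - 15:
                raise ValueError(
                    "mismatch positions must keep a 15-nt margin from core ends"
                )
        if self.bubble is not None:
            pos, a_len, b_len = self.bubble
            if a_len < 0 or b_len < 0 or a_len + b_len < 1:
                raise ValueError("bubble needs at least one unpaired base")
            if a_len > 0 and b_len > 0:
                raise ValueError(
                    "mixed-gap bubbles leave the alignment-stage optimum "
                    "ambiguous (gap columns trade against substitutions at "
                    "equal score); plant a pure deletion or pure insertion"
                )
            if not 21 <= pos <= self.region_len - 20 - a_len:
                raise ValueError("bubble must keep a 20-nt margin from core ends")
            for p in self.mismatches:
                if pos - 3 <= p <= pos + a_len + 2:
                    raise ValueError("mismatch too close to bubble")
        defects = sorted(self.mismatches)
        for p, q in zip(defects, defects[1:]):
            if q - p < 3:
                raise ValueError("mismatches must be >= 3 nt apart")
        overlap = set(self.drop_sense) & set(self.drop_antisense)
        if overlap:
            raise ValueError(f"slots {sorted(overlap)} dropped on both strands")
        if self.register_offset < 2:
            if 0 not in self.drop_antisense:
                raise ValueError(
                    "register_offset < 2 pushes slot 0's antisense partner out "
                    "of the segment; drop slot 0's antisense read"
                )


@dataclass
class FixtureTruth:
    """Ground truth of one fixture, in pipeline output terms."""

    id_a: str
    id_b: str
    match: dict
    nat_class_inputs: dict  # spans, lengths, longest block — classification inputs
    segments: list[dict]
    bubbles: list[dict]
    retained: bool
    is_cis: bool
    cluster: dict | None = None
    evidence: list[dict] = field(default_factory=list)
    decoy_ids: list[str] = field(default_factory=list)
    library_totals: dict = field(default_factory=dict)


@dataclass
class Fixture:
    spec: FixtureSpec
    transcripts: list[Transcript]
    srna_reads: list[ShortRead]
    degradome_tags: list[ShortRead]
    truth: FixtureTruth


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _rand_ac(rng: np.random.Generator, n: int) -> str:
    """An A/C-only sequence: inert against any A/C partner under both
    Watson-Crick and G·U pairing rules."""
    return "".join("AC"[i] for i in rng.integers(0, 2, size=n))


def _swap_tie(x: str, y: str) -> bool:
    """True when base ``x`` can pair the complement of base ``y`` (so a
    duplex alignment could swap a canonical pair for (x, comp(y)) at equal
    score).  Holds for x == y (Watson-Crick) and the two wobble relations."""
    return x == y or (x, y) == ("G", "A") or (x, y) == ("T", "C")


def _gap_cost(length: int, open_: int = 5, extend: int = 2) -> int:
    return 0 if length == 0 else open_ + extend * (length - 1)


def make_nat_pair(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[Transcript, Transcript, FixtureTruth]:
    """Build the planted NAT pair and its alignment/structure ground truth."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 0])
    R = spec.region_len
    core = list(_rand_seq(rng, R))

    bub_pos, bub_a, bub_b = spec.bubble if spec.bubble else (0, 0, 0)
    deleted = set(range(bub_pos, bub_pos + bub_a)) if bub_a else set()
    mismatch_set = set(spec.mismatches)

    # Make the defect neighbourhoods pairing-inert so the optimal duplex is
    # unique (no equal-score re-pairings via Watson-Crick repeats or wobble):
    # deleted blocks are all-C and their windows C-free; foreign bases (the
    # mismatched / inserted ones on B) are all-A and their windows T-free.
    def resample(idx0: int, forbidden: set[str]) -> None:
        allowed = [b for b in _BASES if b not in forbidden]
        core[idx0] = allowed[int(rng.integers(0, len(allowed)))]

    if bub_a:
        for d in deleted:
            core[d - 1] = "C"
        window = [
            y
            for y in range(bub_pos - 3, bub_pos + bub_a + 3)
            if 1 <= y <= R and y not in deleted
        ]
        forbidden = {"C", "T"} if bub_b else {"C"}
        for y in window:
            if core[y - 1] in forbidden:
                resample(y - 1, forbidden)
        # forbid equal-score swap-pairs across the junction
        xs = [x for x in (bub_pos - 2, bub_pos - 1) if x >= 1]
        ys = [y for y in (bub_pos + bub_a, bub_pos + bub_a + 1) if y <= R]
        for _try in range(200):
            if not any(_swap_tie(core[x - 1], core[y - 1]) for x in xs for y in ys):
                break
            for z in xs + ys:
                resample(z - 1, forbidden)
        else:  # pragma: no cover
            raise RuntimeError("could not de-tie the bubble junction")
    if bub_b and not bub_a:
        for y in range(bub_pos - 3, bub_pos + 3):
            if 1 <= y <= R and core[y - 1] == "T":
                resample(y - 1, {"T"})
    for p in mismatch_set:
        for y in range(p - 3, p + 4):
            if 1 <= y <= R and y not in deleted and core[y - 1] == "T":
                resample(y - 1, {"T"})

    # flanks are A/C-only on both transcripts: no flank column can ever pair,
    # so both alignment stages stop exactly at the core boundaries
    fa_l = list(_rand_ac(rng, spec.flank_a[0]))
    fa_r = list(_rand_ac(rng, spec.flank_a[1]))
    fb_l = list(_rand_ac(rng, spec.flank_b[0]))
    fb_r = list(_rand_ac(rng, spec.flank_b[1]))

    # B's copy of the core, walked 3'→5' so b_core reads 5'→3'
    b_core: list[str] = []
    b_index_of: dict[int, int] = {}  # core position -> 0-based index in b_core
    for p in range(R, 0, -1):
        if p in deleted:
            if p == bub_pos + bub_a - 1:  # junction reached: b-side insertion
                b_core.extend("A" * bub_b)
            continue
        if bub_a == 0 and bub_b and p == bub_pos - 1:
            # pure insertion sits between core positions bub_pos-1 and bub_pos
            b_core.extend("A" * bub_b)
        if p in mismatch_set:
            b_core.append("A")
        else:
            b_core.append(_COMP[core[p - 1]])
        b_index_of[p] = len(b_core) - 1

    a_seq = "".join(fa_l) + "".join(core) + "".join(fa_r)
    b_seq = "".join(fb_l) + "".join(b_core) + "".join(fb_r)
    La, Lb = len(fa_l), len(fb_l)
    id_a, id_b = "nat_a", "nat_b"

    # --- alignment-stage truth (A vs revcomp(B)) ---------------------------
    n_mism = len(mismatch_set)
    n_pairs = R - n_mism - bub_a
    aln_len = n_pairs + n_mism + bub_a + bub_b
    score = n_pairs - 2 * n_mism - _gap_cost(bub_a) - _gap_cost(bub_b)

    # longest gap-free aligned block (mismatches allowed inside)
    blocks: list[int] = []
    run = 0
    for p in range(1, R + 1):
        if p in deleted or (bub_a == 0 and bub_b and p == bub_pos):
            if run:
                blocks.append(run)
            run = 0
            if p in deleted:
                continue
        run += 1
    if run:
        blocks.append(run)
    longest_block = max(blocks)

    match_truth = {
        "a_start": La + 1,
        "a_end": La + R,
        "b_start": Lb + 1,
        "b_end": Lb + len(b_core),
        "score": score,
        "aln_len": aln_len,
        "identity": n_pairs / aln_len,
        "longest_contig_block": longest_block,
    }

    # --- structure-stage truth: perfect segments & bubbles -----------------
    breakpoints = sorted(mismatch_set | deleted)
    seg_bounds: list[tuple[int, int]] = []
    start = 1
    for p in breakpoints:
        if p > start:
            seg_bounds.append((start, p - 1))
        start = p + 1
    if start <= R:
        seg_bounds.append((start, R))
    if bub_a == 0 and bub_b:  # a pure insertion also splits its run
        split: list[tuple[int, int]] = []
        for s, e in seg_bounds:
            if s < bub_pos <= e:
                split.extend([(s, bub_pos - 1), (bub_pos, e)])
            else:
                split.append((s, e))
        seg_bounds = split

    segments = [
        {
            "a_start": La + s,
            "a_end": La + e,
            "b_start": Lb + 1 + b_index_of[e],
            "b_end": Lb + 1 + b_index_of[s],
            "length": e - s + 1,
        }
        for s, e in seg_bounds
    ]

    defect_records: list[tuple[int, dict]] = []
    for p in sorted(mismatch_set):
        defect_records.append((p, {"a_gap_len": 1, "b_gap_len": 1, "size": 1}))
    if spec.bubble:
        defect_records.append(
            (bub_pos, {"a_gap_len": bub_a, "b_gap_len": bub_b, "size": max(bub_a, bub_b)})
        )
    defect_records.sort(key=lambda t: t[0])
    bubbles = [d for _, d in defect_records]

    retained = all(b["size"] <= 0.10 * R for b in bubbles)
    is_cis = retained and not bubbles

    truth = FixtureTruth(
        id_a=id_a,
        id_b=id_b,
        match=match_truth,
        nat_class_inputs={
            "len_a": len(a_seq),
            "len_b": len(b_seq),
            "a_span": R,
            "b_span": len(b_core),
            "longest_contig_block": longest_block,
        },
        segments=segments,
        bubbles=bubbles,
        retained=retained,
        is_cis=is_cis,
    )
    return Transcript(id=id_a, seq=a_seq), Transcript(id=id_b, seq=b_seq), truth


def make_decoys(
    spec: FixtureSpec,
    existing: list[Transcript],
    rng: np.random.Generator | None = None,
) -> list[Transcript]:
    """Decoy transcripts sharing no ``seed_len``-mer with any transcript in
    either orientation (rejection sampling), so they can neither align nor
    receive reads."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 1])
    k = spec.seed_len

    def kmers(s: str) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    forbidden: set[str] = set()
    for t in existing:
        forbidden |= kmers(t.seq) | kmers(revcomp(t.seq))

    decoys: list[Transcript] = []
    for d in range(spec.n_decoys):
        for _attempt in range(200):
            seq = _rand_seq(rng, spec.decoy_len)
            own = kmers(seq) | kmers(revcomp(seq))
            if not (own & forbidden):
                forbidden |= own
                decoys.append(Transcript(id=f"decoy_{d + 1}", seq=seq))
                break
        else:  # pragma: no cover - probability ~0 at these sizes
            raise RuntimeError("could not sample a seed-free decoy")
    return decoys


def make_phased_reads(
    a: Transcript,
    b: Transcript,
    truth: FixtureTruth,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[ShortRead], list[ShortRead]]:
    """Cut phased sRNA duplexes and degradome tags from the planted pair.

    Reads are laid into the longest perfect segment with exact 2-nt
    3′-overhang geometry; the truth record is extended in place with the
    expected cluster and degradome evidence.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 2])
    n = spec.srna_len
    seg = max(truth.segments, key=lambda s: s["length"])
    a_start, a_end = seg["a_start"], seg["a_end"]
    b_start, b_end = seg["b_start"], seg["b_end"]
    if spec.register_offset + spec.n_duplex * n > seg["length"]:
        raise ValueError("phased duplexes do not fit in the longest segment")

    def cross(x: int) -> int:
        return b_start + (a_end - x)

    i0 = a_start + spec.register_offset
    slot_starts = [i0 + t * n for t in range(spec.n_duplex)]

    srna_seqs: list[tuple[int, str, str]] = []  # (slot, strand, seq)
    for t, i in enumerate(slot_starts):
        if t not in spec.drop_sense:
            srna_seqs.append((t, "sense", a.seq[i - 1 : i + n - 1]))
        if t not in spec.drop_antisense:
            b5 = cross(i + n - 3)
            srna_seqs.append((t, "antisense", b.seq[b5 - 1 : b5 + n - 1]))

    # degradome tags: 5' ends on siRNA 5' ends and one past the final 3' end
    tag_targets: list[tuple[str, int, int | None, str]] = []
    for t in spec.degradome_slots:
        tag_targets.append((a.id, slot_starts[t], t, "sense"))
    for t in spec.degradome_antisense_slots:
        tag_targets.append((b.id, cross(slot_starts[t] + n - 3), t, "antisense"))
    if spec.degradome_terminus:
        tag_targets.append((a.id, slot_starts[-1] + n, None, "sense"))
    if spec.degradome_antisense_terminus:
        tag_targets.append((b.id, cross(slot_starts[0] - 2) + 1, None, "antisense"))

    tag_records: list[tuple[str, int, int | None, str, str]] = []
    for tid, pos, slot, strand in tag_targets:
        length = int(rng.integers(18, 26))
        src = a.seq if tid == a.id else b.seq
        seq = src[pos - 1 : pos + length - 1]
        tag_records.append((tid, pos, slot, strand, seq))

    # global uniqueness: every planted sequence occurs exactly once
    haystack = [a.seq, b.seq]
    all_seqs = [s for _, _, s in srna_seqs] + [s for *_, s in tag_records]
    if len(set(all_seqs)) != len(all_seqs) or any(
        sum(h.count(s) for h in haystack) != 1 for s in all_seqs
    ):
        raise ValueError("planted read sequences are not globally unique")

    srna_reads: list[ShortRead] = []
    lib_totals: dict[str, int] = {}
    for lib in spec.libraries:
        total = 0
        for t, strand, seq in srna_seqs:
            count = int(rng.integers(1, spec.max_count + 1))
            total += count
            srna_reads.append(
                ShortRead(
                    id=f"{lib}_s{t}{strand[0]}",
                    seq=seq,
                    count=count,
                    library=lib,
                    kind="srna",
                )
            )
        for j in range(spec.n_noise_reads):
            seq = ""
            for _attempt in range(100):
                seq = _rand_seq(rng, n)
                if all(seq not in h for h in haystack) and seq not in {
                    r.seq for r in srna_reads
                }:
                    break
            count = int(rng.integers(1, spec.max_count + 1))
            total += count
            srna_reads.append(
                ShortRead(
                    id=f"{lib}_noise{j}", seq=seq, count=count, library=lib, kind="srna"
                )
            )
        lib_totals[lib] = total

    degradome_tags: list[ShortRead] = []
    for lib in spec.degradome_libraries:
        total = 0
        for j, (tid, pos, slot, strand, seq) in enumerate(tag_records):
            count = int(rng.integers(1, spec.max_count + 1))
            total += count
            degradome_tags.append(
                ShortRead(
                    id=f"{lib}_t{j}", seq=seq, count=count, library=lib, kind="degradome"
                )
            )
        if total:
            lib_totals[lib] = total

    # truth describes the outcome under default detector settings: regions
    # of 81+ bp are searched and runs of 4+ consecutive duplexes reported
    searched = seg["length"] >= 81
    if truth.retained and searched and spec.n_duplex >= 4:
        truth.cluster = {
            "srna_len": n,
            "register": spec.register_offset % n,
            "slot_starts": slot_starts,
            "n_phases": spec.n_duplex,
            "n_srnas": len(srna_seqs),
            "segment": {
                "a_start": a_start,
                "a_end": a_end,
                "b_start": b_start,
                "b_end": b_end,
            },
        }
        for j, (tid, pos, slot, strand, seq) in enumerate(tag_records):
            for lib in spec.degradome_libraries:
                truth.evidence.append(
                    {
                        "transcript_id": tid,
                        "five_prime_pos": pos,
                        "slot_index": slot,
                        "strand": strand,
                        "tag_id": f"{lib}_t{j}",
                        "library": lib,
                    }
                )
    truth.library_totals = lib_totals
    return srna_reads, degradome_tags


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Assemble the full fixture: NAT pair, decoys, reads, tags, truth.

    Sequence collisions (a planted read occurring twice by chance) trigger a
    retry under a fresh deterministic substream; everything stays a pure
    function of the spec.
    """
    last: Exception | None = None
    for retry in range(20):
        try:
            a, b, truth = make_nat_pair(
                spec, np.random.default_rng([spec.seed, retry, 0])
            )
            srna, tags = make_phased_reads(
                a, b, truth, spec, np.random.default_rng([spec.seed, retry, 2])
            )
            decoys = make_decoys(
                spec, [a, b], np.random.default_rng([spec.seed, retry, 1])
            )
            truth.decoy_ids = [d.id for d in decoys]
            return Fixture(
                spec=spec,
                transcripts=[a, b] + decoys,
                srna_reads=srna,
                degradome_tags=tags,
                truth=truth,
            )
        except ValueError as exc:
            if "globally unique" not in str(exc):
                raise
            last = exc
    raise RuntimeError(f"could not build a collision-free fixture: {last}")


def write_fixture(outdir: str | Path, fixture: Fixture) -> dict[str, Path]:
    """Write a fixture in the formats the pipeline reads; truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["transcripts"] = outdir / "transcripts.fa"
    write_fasta(paths["transcripts"], fixture.transcripts)

    for lib in fixture.spec.libraries:
        p = outdir / f"srna_{lib}.fa"
        write_collapsed_reads(p, [r for r in fixture.srna_reads if r.library == lib])
        paths[f"srna_{lib}"] = p
    for lib in fixture.spec.degradome_libraries:
        reads = [r for r in fixture.degradome_tags if r.library == lib]
        if reads:
            p = outdir / f"degradome_{lib}.fa"
            write_collapsed_reads(p, reads)
            paths[f"degradome_{lib}"] = p

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"spec": asdict(fixture.spec), "truth": asdict(fixture.truth)},
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def random_fixture_spec(rng: np.random.Generator, seed: int) -> FixtureSpec:
    """Sample a plausible fixture scenario for integration sweeps.

    Regions host 21- or 24-nt phased duplexes in a tail segment of at least
    100 nt (so the 100-nt class always applies); roughly 40% of scenarios
    are perfect (cis-like), the rest carry head-positioned mismatches or
    one bubble.  Evidence dropout exercises the either-strand rule.
    """
    srna_len = int(rng.choice([21, 24]))
    n_duplex = int(rng.integers(4, 7))
    register_offset = int(rng.integers(2, srna_len))
    tail_needed = max(100, register_offset + n_duplex * srna_len)

    kind = rng.random()
    mismatches: tuple[int, ...] = ()
    bubble = None
    head = 0
    if kind < 0.40:
        pass  # perfect pair
    elif kind < 0.70:
        n_mm = int(rng.integers(1, 3))
        positions = sorted(
            int(p) for p in rng.choice(np.arange(16, 40, 4), size=n_mm, replace=False)
        )
        mismatches = tuple(positions)
        head = max(mismatches)
    else:
        a_len = int(rng.integers(0, 7))
        b_len = int(rng.integers(1, 7)) if a_len == 0 else 0
        # the head segment must outweigh the bubble's affine gap cost, or the
        # optimal local alignment would trim it off
        lo = max(21, _gap_cost(a_len) + _gap_cost(b_len) + 4)
        pos = int(rng.integers(lo, lo + 12))
        bubble = (pos, a_len, b_len)
        head = pos + a_len

    region_len = head + tail_needed + int(rng.integers(0, 30))

    n_slots = n_duplex
    drop_sense: tuple[int, ...] = ()
    drop_antisense: tuple[int, ...] = ()
    mode = rng.random()
    if mode < 0.3:
        drop_antisense = tuple(range(n_slots))  # sense-only evidence
    elif mode < 0.6:
        keep = rng.random(n_slots)
        drop_sense = tuple(t for t in range(n_slots) if keep[t] < 0.3)
        drop_antisense = tuple(
            t for t in range(n_slots) if keep[t] >= 0.7 and t not in drop_sense
        )

    deg_slots = tuple(
        sorted(int(t) for t in rng.choice(n_slots, size=min(2, n_slots), replace=False))
    )
    return FixtureSpec(
        seed=seed,
        region_len=region_len,
        srna_len=srna_len,
        n_duplex=n_duplex,
        register_offset=register_offset,
        mismatches=mismatches,
        bubble=bubble,
        n_decoys=int(rng.integers(2, 5)),
        flank_a=(int(rng.integers(30, 70)), int(rng.integers(30, 70))),
        flank_b=(int(rng.integers(25, 60)), int(rng.integers(25, 60))),
        libraries=("root", "leaf")[: int(rng.integers(1, 3))],
        drop_sense=drop_sense,
        drop_antisense=drop_antisense,
        degradome_slots=deg_slots,
        degradome_antisense_slots=(int(rng.integers(0, n_slots)),),
        degradome_terminus=True,
        degradome_antisense_terminus=bool(rng.random() < 0.5),
    )
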