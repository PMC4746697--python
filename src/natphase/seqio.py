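"""Sequence records and file formats shared by every pipeline stage.

Two external formats are handled here:

* plain FASTA for assembled transcripts;
* "collapsed-read" FASTA for small-RNA and degradome libraries, where each
  record is a unique sequence and the header carries its abundance as an
  ``_x{count}`` suffix (``>read1_x523``), the dominant community convention
  for deduplicated sRNA data.

All sequences are folded to the DNA alphabet (U→T, upper case) on input so a
single alphabet serves alignment and read mapping downstream.  ``N`` is legal
in transcripts but never base-pairs with anything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "ShortRead",
    "LibraryStats",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_collapsed_reads",
    "write_collapsed_reads",
    "rpm",
]

_VALID_CHARS = frozenset("ACGTN")
_COUNT_SUFFIX = re.compile(r"^(?P<id>.*)_x(?P<count>[1-9][0-9]*)$")

ReadKind = Literal["srna", "degradome"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, empty or invalid
    sequence, duplicate ID).  Carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript stored on its forward strand, DNA alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ShortRead:
    """A collapsed high-throughput sequencing read (unique sequence plus
    abundance) from one library.

    ``kind`` distinguishes small-RNA reads from degradome tags; the two are
    parsed identically but flow into different stages.
    """

    id: str
    seq: str
    count: int
    library: str
    kind: ReadKind = "srna"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read {self.id!r}: count must be >= 1")
        if not self.seq or set(self.seq) - _VALID_CHARS:
            raise ValueError(f"read {self.id!r}: invalid sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LibraryStats:
    """Per-library totals; ``total_reads`` is the RPM denominator."""

    library: str
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError(f"library {self.library!r}: total_reads must be >= 1")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _header_line(path: Path, record_id: str, occurrence: int = 1) -> int | None:
    """Locate the 1-based line number of the ``occurrence``-th header for
    ``record_id`` (best effort, used only for error messages)."""
    seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0:1] == [record_id]:
                seen += 1
                if seen == occurrence:
                    return lineno
    return None


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read assembled transcripts from a FASTA file.

    U is folded to T and case to upper.  Duplicate IDs, empty sequences and
    invalid characters raise :class:`FastaParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = next((ln for ln in fh if ln.strip()), None)
    if first is None:
        return []
    if not first.startswith(">"):
        raise FastaParseError(f"{path}: not a FASTA file (no '>' header)", line=1)

    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(
                f"{path}: duplicate transcript ID {rec.id!r}",
                line=_header_line(path, rec.id, occurrence=2),
            )
        seen.add(rec.id)
        seq = _normalize(str(rec.seq))
        try:
            transcripts.append(Transcript(id=rec.id, seq=seq))
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: {exc}", line=_header_line(path, rec.id)
            ) from exc
    return transcripts


def write_fasta(path: str | Path, transcripts: Iterable[Transcript], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_collapsed_reads(
    path: str | Path,
    library: str,
    kind: ReadKind = "srna",
    min_len: int = 15,
    max_len: int = 35,
) -> tuple[list[ShortRead], LibraryStats]:
    """Read a collapsed-read FASTA library (``>{id}_x{count}`` headers).

    For ``kind="srna"`` reads outside ``[min_len, max_len]`` are dropped (and
    excluded from the library total); degradome tags are kept at any length.
    Returns the reads plus :class:`LibraryStats` with the RPM denominator.
    """
    path = Path(path)
    reads: list[ShortRead] = []
    total = 0
    seen_seqs: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_SUFFIX.match(rec.id)
        if not m:
            raise FastaParseError(
                f"{path}: header {rec.id!r} lacks the _x{{count}} abundance suffix",
                line=_header_line(path, rec.id),
            )
        seq = _normalize(str(rec.seq))
        if kind == "srna" and not (min_len <= len(seq) <= max_len):
            continue
        if seq in seen_seqs:
            raise FastaParseError(
                f"{path}: sequence of {rec.id!r} duplicated in library {library!r}",
                line=_header_line(path, rec.id),
            )
        seen_seqs.add(seq)
        count = int(m.group("count"))
        try:
            reads.append(
                ShortRead(id=m.group("id"), seq=seq, count=count, library=library, kind=kind)
            )
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: {exc}", line=_header_line(path, rec.id)
            ) from exc
        total += count
    if total == 0:
        raise FastaParseError(f"{path}: library {library!r} contains no usable reads")
    return reads, LibraryStats(library=library, total_reads=total)


def write_collapsed_reads(path: str | Path, reads: Iterable[ShortRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}_x{r.count}\n{r.seq}\n")


def rpm(count: int, stats: LibraryStats) -> float:
    """Reads per million: ``count / total_reads * 1e6``."""
    if stats.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count / stats.total_reads * 1_000_000.0
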