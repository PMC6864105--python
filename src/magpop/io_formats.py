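"""Strict readers/writers for the plain-text formats the pipeline touches.

Three dialects are supported:

* multi-record FASTA (uppercase ``ACGTN`` on ingest),
* 12-column tab-separated read alignments (the classic BLAST ``-outfmt 6``
  layout, no header line),
* 4-column BedGraph (no track lines, 0-based half-open intervals).

Parsing is total and order-preserving: every input row becomes exactly one
record or raises :class:`FormatError` carrying the offending line/row number.
Subject coordinates of alignments are kept 1-based inclusive at the file
boundary (``sstart > send`` meaning minus strand) and exposed normalized to
0-based half-open plus a strand flag for internal interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "SequenceRecord",
    "TabularAlignment",
    "DepthTrack",
    "read_fasta",
    "write_fasta",
    "read_tabular_alignments",
    "write_tabular_alignments",
    "read_bedgraph",
    "write_bedgraph",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the dialect this package reads/writes."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence (e.g. a MAG contig) over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record id must be non-empty")
        if any(c.isspace() for c in self.id):
            raise FormatError(f"sequence record id contains whitespace: {self.id!r}")
        if len(self.sequence) < 1:
            raise FormatError(f"sequence of record {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularAlignment:
    """One read-to-contig alignment row in the outfmt-6 dialect.

    ``sstart``/``send`` are 1-based inclusive as printed by BLAST; a row with
    ``sstart > send`` is a minus-strand match.  :attr:`subject_start` /
    :attr:`subject_end` give the normalized 0-based half-open subject interval
    regardless of strand.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(f"pident outside [0, 100]: {self.pident}")
        if self.length < 1:
            raise FormatError(f"aligned length < 1: {self.length}")
        if self.mismatch < 0 or self.gapopen < 0:
            raise FormatError("mismatch/gapopen must be non-negative")
        if min(self.qstart, self.qend, self.sstart, self.send) < 1:
            raise FormatError("alignment coordinates must be >= 1")

    @property
    def is_reverse(self) -> bool:
        return self.sstart > self.send

    @property
    def subject_start(self) -> int:
        """0-based inclusive start on the subject, strand-normalized."""
        return min(self.sstart, self.send) - 1

    @property
    def subject_end(self) -> int:
        """0-based exclusive end on the subject, strand-normalized."""
        return max(self.sstart, self.send)

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start


@dataclass(frozen=True)
class DepthTrack:
    """One BedGraph interval: per-base depth is constant on [start, end)."""

    contig: str
    start: int
    end: int
    depth: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative interval start: {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"empty or inverted interval on {self.contig}: [{self.start}, {self.end})"
            )
        if self.depth < 0:
            raise FormatError(f"negative depth on {self.contig}: {self.depth}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Sequences are uppercased on ingest.  Malformed headers, empty sequences,
    illegal characters and duplicate ids raise :class:`FormatError` naming the
    offending line.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}: record at line {header_line} has an empty sequence")
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise FormatError(
                f"{path}: duplicate sequence id {rid!r} at line {header_line} "
                f"(first seen at line {seen[rid]})"
            )
        seen[rid] = header_line
        try:
            records.append(SequenceRecord(id=rid, sequence=seq, description=desc))
        except FormatError as exc:
            raise FormatError(f"{path}: line {header_line}: {exc}") from exc
        header, chunks = None, []

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {line_no}")
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {line_no}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
        _flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# outfmt-6 tabular alignments

_TAB_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_tabular_alignments(path: str | Path) -> list[TabularAlignment]:
    """Parse a 12-column tab-separated alignment file (BLAST outfmt-6 dialect)."""
    out: list[TabularAlignment] = []
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: row {row_no}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                vals = [typ(p) for typ, p in zip(_TAB_TYPES, parts)]
            except ValueError as exc:
                raise FormatError(f"{path}: row {row_no}: {exc}") from exc
            try:
                out.append(TabularAlignment(*vals))
            except FormatError as exc:
                raise FormatError(f"{path}: row {row_no}: {exc}") from exc
    return out


def _fmt_float(x: float) -> str:
    return format(x, "g")


def write_tabular_alignments(alignments: Iterable[TabularAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    [
                        a.qseqid,
                        a.sseqid,
                        _fmt_float(a.pident),
                        str(a.length),
                        str(a.mismatch),
                        str(a.gapopen),
                        str(a.qstart),
                        str(a.qend),
                        str(a.sstart),
                        str(a.send),
                        _fmt_float(a.evalue),
                        _fmt_float(a.bitscore),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BedGraph


def read_bedgraph(path: str | Path) -> list[DepthTrack]:
    """Parse a 4-column BedGraph file; intervals per contig must be sorted and disjoint."""
    tracks: list[DepthTrack] = []
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for row_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}: row {row_no}: expected 4 tab-separated columns, got {len(parts)}"
                )
            contig = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                depth = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}: row {row_no}: {exc}") from exc
            try:
                track = DepthTrack(contig, start, end, depth)
            except FormatError as exc:
                raise FormatError(f"{path}: row {row_no}: {exc}") from exc
            if contig in last_end and start < last_end[contig]:
                raise FormatError(
                    f"{path}: row {row_no}: interval [{start}, {end}) on {contig} overlaps "
                    f"or precedes an earlier interval ending at {last_end[contig]}"
                )
            last_end[contig] = end
            tracks.append(track)
    return tracks


def _fmt_depth(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_bedgraph(tracks: Sequence[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{_fmt_depth(t.depth)}\n")
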