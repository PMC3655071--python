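"""Sequence-format I/O: FASTQ (4-line, Phred+33), FASTA, and TSV tables.

Parsing is delegated to Biopython's low-level iterators; records are
re-packaged into the pipeline's own lightweight types so that downstream
modules never touch format details. Quality encoding is fixed to Phred+33
(the modern Illumina convention); there is no offset autodetection.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

Source = Union[str, Path, TextIO]


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record; the message names the record index."""


@dataclass
class ReadRecord:
    """A single sequenced read with per-base Phred qualities.

    ``mate_flag`` is 1 or 2 for the members of a pair and the string
    ``"unpaired"`` for orphan reads (e.g. the salvaged good mate of a
    mixed-quality pair).
    """

    id: str
    sequence: str
    qualities: list[int] = field(repr=False)
    mate_flag: Union[int, str] = "unpaired"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """Two mates sequenced from the same fragment."""

    r1: ReadRecord
    r2: ReadRecord

    def __iter__(self) -> Iterator[ReadRecord]:
        yield self.r1
        yield self.r2


ReadUnit = Union[ReadRecord, ReadPair]


def unit_reads(unit: ReadUnit) -> tuple[ReadRecord, ...]:
    """The individual reads in a pair-or-single unit."""
    return tuple(unit) if isinstance(unit, ReadPair) else (unit,)


def decode_qualities(qual_string: str) -> list[int]:
    scores = [ord(c) - PHRED_OFFSET for c in qual_string]
    if any(q < 0 for q in scores):
        bad = min(scores)
        raise FastqParseError(f"quality character below '!' (Phred {bad})")
    return scores


def encode_qualities(scores: Sequence[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def _open(source: Source, mode: str = "rt"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


def _strip_mate_suffix(read_id: str) -> tuple[str, Union[int, str]]:
    if read_id.endswith("/1"):
        return read_id[:-2], 1
    if read_id.endswith("/2"):
        return read_id[:-2], 2
    return read_id, "unpaired"


def read_fastq(source: Source, mate_flag: Union[int, str, None] = None) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from a 4-line FASTQ file, preserving order.

    ``mate_flag`` overrides the flag inferred from a ``/1`` / ``/2`` id
    suffix. Malformed records raise :class:`FastqParseError` naming the
    0-based record index.
    """
    handle, close = _open(source)
    try:
        index = -1
        try:
            for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                read_id = title.split()[0] if title else ""
                inferred_id, inferred_flag = _strip_mate_suffix(read_id)
                flag = mate_flag if mate_flag is not None else inferred_flag
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"record {index}: sequence/quality length mismatch"
                    )
                yield ReadRecord(read_id if flag == "unpaired" else inferred_id,
                                 seq.upper(), decode_qualities(qual), flag)
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"record {index + 1}: {exc}") from exc
    finally:
        if close:
            handle.close()


def read_fastq_paired(source1: Source, source2: Source) -> Iterator[ReadPair]:
    """Pair two FASTQ files positionally; unequal record counts are fatal."""
    it1 = read_fastq(source1, mate_flag=1)
    it2 = read_fastq(source2, mate_flag=2)
    sentinel = object()
    index = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            raise FastqParseError(
                f"paired files differ in record count at pair index {index}"
            )
        yield ReadPair(a, b)
        index += 1


def write_fastq(records: Iterable[ReadRecord], dest: Source,
                mate_suffix: bool = False) -> None:
    handle, close = _open(dest, "wt")
    try:
        for rec in records:
            name = rec.id
            if mate_suffix and rec.mate_flag in (1, 2):
                name = f"{rec.id}/{rec.mate_flag}"
            handle.write(f"@{name}\n{rec.sequence}\n+\n{encode_qualities(rec.qualities)}\n")
    finally:
        if close:
            handle.close()


def read_fasta(source: Source) -> list[tuple[str, str]]:
    """Return ``(id, sequence)`` pairs; the id is the header up to whitespace.

    Multi-line sequences are concatenated; an empty file yields an empty
    list; duplicate ids trigger a warning (not an error).
    """
    handle, close = _open(source)
    try:
        out: list[tuple[str, str]] = []
        seen: set[str] = set()
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0] if title.split() else ""
            if name in seen:
                warnings.warn(f"duplicate FASTA id {name!r}", stacklevel=2)
            seen.add(name)
            out.append((name, seq.upper()))
        return out
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[tuple[str, str]], dest: Source,
                width: int = 70) -> None:
    handle, close = _open(dest, "wt")
    try:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


def write_tsv(rows: Iterable[dict], dest: Source) -> None:
    """Write dict rows as a TSV with a header taken from the first row."""
    handle, close = _open(dest, "wt")
    try:
        rows = iter(rows)
        first = next(rows, None)
        if first is None:
            return
        cols = list(first)
        handle.write("\t".join(cols) + "\n")
        for row in [first, *rows]:
            handle.write("\t".join(str(row[c]) for c in cols) + "\n")
    finally:
        if close:
            handle.close()
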