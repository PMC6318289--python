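"""Sequence I/O and read collapsing.

Readers for the two formats the pipeline consumes (FASTA references,
FASTQ amplicon reads) plus the collapse step that turns raw reads into
counted unique sequences and the frequency filter applied before any
classification. Parsing is delegated to :mod:`Bio.SeqIO`; this module
adds strict alphabet validation and error messages that point at the
offending line or record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

from Bio import SeqIO

logger = logging.getLogger("ampedit.io")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement of an upper-case nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, either nucleotide (A/C/G/T/N) or protein.

    Protein sequences may contain the 20 standard residues plus ``*``
    (stop) and ``X`` (unknown).
    """

    id: str
    seq: str
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.kind} symbol(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadGroup:
    """A unique read sequence together with its exact-duplicate count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("ReadGroup count must be >= 1")
        if not self.seq:
            raise ValueError("ReadGroup sequence must be non-empty")


def read_fasta(path: str | Path, kind: str = "nucleotide") -> List[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased; record order is preserved. Raises
    :class:`FormatError` naming the line when the file does not start
    with a ``>`` header or a record has an empty sequence.
    """
    path = Path(path)
    header_lines = []  # line number of each record header, for error messages
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not header_lines and not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>' as first "
                    f"non-blank line, got {line.strip()[:30]!r}"
                )
            if line.startswith(">"):
                header_lines.append(lineno)
    records: List[SequenceRecord] = []
    with open(path) as handle:
        for idx, rec in enumerate(SeqIO.parse(handle, "fasta")):
            seq = str(rec.seq).upper()
            lineno = header_lines[idx] if idx < len(header_lines) else "?"
            if not rec.id:
                raise FormatError(f"{path}: line {lineno}: malformed FASTA header")
            if not seq:
                raise FormatError(
                    f"{path}: line {lineno}: record {rec.id!r} has an empty sequence"
                )
            try:
                records.append(SequenceRecord(id=rec.id, seq=seq, kind=kind))
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: {err}") from err
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, one sequence per line."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def read_fastq(path: str | Path) -> List[SequenceRecord]:
    """Read a 4-line-per-record FASTQ file (Sanger/Phred+33).

    Quality strings are parsed (their length is checked against the
    sequence) and then discarded: the downstream analysis filters by
    exact-sequence frequency, not base quality. Raises
    :class:`FormatError` with the record index on malformed records.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    with open(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as err:
                raise FormatError(f"{path}: record {index}: {err}") from err
            try:
                records.append(
                    SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
                )
            except ValueError as err:
                raise FormatError(f"{path}: record {index}: {err}") from err
            index += 1
    return records


def collapse_reads(
    reads: Sequence[SequenceRecord], drop_ambiguous: bool = True
) -> List[ReadGroup]:
    """Collapse reads into counted unique sequences.

    Returns one :class:`ReadGroup` per distinct sequence, sorted by
    count descending with ties broken lexicographically by sequence.
    When ``drop_ambiguous`` is set (the default), reads containing N are
    removed before counting; the number dropped is logged.
    """
    counts: dict[str, int] = {}
    dropped = 0
    for rec in reads:
        if rec.kind != "nucleotide":
            raise ValueError(f"record {rec.id!r} is not a nucleotide sequence")
        if drop_ambiguous and "N" in rec.seq:
            dropped += 1
            continue
        counts[rec.seq] = counts.get(rec.seq, 0) + 1
    if dropped:
        logger.info(
            "collapse_reads: dropped %d/%d reads containing N", dropped, len(reads)
        )
    groups = [ReadGroup(seq=s, count=c) for s, c in counts.items()]
    groups.sort(key=lambda g: (-g.count, g.seq))
    return groups


def filter_low_frequency(
    groups: Sequence[ReadGroup], min_count: int
) -> List[ReadGroup]:
    """Drop groups seen fewer than ``min_count`` times.

    Strict "less than" semantics: a group with ``count == min_count`` is
    retained. Order is preserved.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [g for g in groups if g.count >= min_count]


def write_groups_tsv(groups: Iterable[ReadGroup], path: str | Path) -> None:
    """Write read groups as a two-column TSV (``sequence<TAB>count``)."""
    with open(path, "w") as handle:
        handle.write("sequence\tcount\n")
        for g in groups:
            handle.write(f"{g.seq}\t{g.count}\n")
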