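"""Readers and writers for the sequence formats the simulator touches.

Conventions used throughout the package:

* Coordinates are 0-based, half-open.  Conversion to and from SAM's
  1-based ``POS`` happens only inside this module.
* Quality scores live in memory as plain PHRED integers in ``[0, 62]``;
  the ASCII offset (33 or 64) applies only when FASTQ text is read or
  written.
* Sequences are uppercase strings over ``{A, C, G, T, N}``; ``U`` is
  mapped to ``T`` and every other ambiguity code collapses to ``N`` on
  input, which keeps the 4-letter substitution model well-defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeDB",
    "ReadRecord",
    "AlignmentRecord",
    "revcomp",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "read_sam",
    "read_composition_table",
    "write_composition_table",
]

MAX_PHRED = 62

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume bases of the read (query)
QUERY_OPS = frozenset("MIS=X")
# CIGAR operations that consume reference bases
REF_OPS = frozenset("MDN=X")


class FormatError(ValueError):
    """A file violated the expectations of its format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeDB:
    """Named reference sequences: the universe reads are simulated from.

    ``entries`` preserves insertion order; each FASTA record is its own
    sequence (multi-replicon genomes are not concatenated).
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for gid, seq in self.entries.items():
            if not gid:
                raise FormatError("empty genome identifier")
            if not seq:
                raise FormatError(f"genome {gid!r} has an empty sequence")

    def size(self, genome_id: str) -> int:
        return len(self.entries[genome_id])

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)


@dataclass
class ReadRecord:
    """One sequencing read; carrier for FASTQ records."""

    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id!r}: {len(self.qualities)} qualities "
                    f"for {len(self.sequence)} bases"
                )
            for q in self.qualities:
                if not 0 <= q <= MAX_PHRED:
                    raise ValueError(
                        f"read {self.read_id!r}: quality {q} outside [0, {MAX_PHRED}]"
                    )


@dataclass
class AlignmentRecord:
    """One alignment line (SAM), in 0-based coordinates.

    ``sequence`` is kept when present in the SAM line because the MD walk
    needs the read base at each mismatch column to identify substitution
    pairs.
    """

    read_id: str
    genome_id: Optional[str]
    start: int
    cigar: list[tuple[str, int]] = field(default_factory=list)
    md: Optional[str] = None
    nm: Optional[int] = None
    is_mapped: bool = True
    sequence: Optional[str] = None

    def query_length(self) -> int:
        """Read length implied by the query-consuming CIGAR operations."""
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_OPS)


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    return _NON_ACGTN.sub("N", seq)


def read_fasta(path: str | Path) -> GenomeDB:
    """Load a genome database from a FASTA file or a directory of FASTA files.

    Sequences are uppercased, U is mapped to T and any other ambiguity
    code becomes N.  Duplicate record ids and empty sequences are format
    errors naming the offending record.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".fa", ".fasta", ".fna"}
        )
        if not files:
            raise FormatError(f"no FASTA files found in directory {path}")
    else:
        files = [path]

    entries: dict[str, str] = {}
    for f in files:
        for rec in SeqIO.parse(str(f), "fasta"):
            if not rec.id:
                raise FormatError(f"{f}: FASTA record with empty identifier")
            if rec.id in entries:
                raise FormatError(f"{f}: duplicate FASTA record id {rec.id!r}")
            seq = _clean_sequence(str(rec.seq))
            if not seq:
                raise FormatError(f"{f}: record {rec.id!r} has an empty sequence")
            entries[rec.id] = seq
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeDB(entries)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path, quality_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream FASTQ records, decoding qualities at the given ASCII offset."""
    if quality_offset not in (33, 64):
        raise ValueError(f"quality offset must be 33 or 64, got {quality_offset}")
    fmt = "fastq" if quality_offset == 33 else "fastq-illumina"
    for rec in SeqIO.parse(str(path), fmt):
        yield ReadRecord(
            read_id=rec.description or rec.id,
            sequence=_clean_sequence(str(rec.seq)),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(
    reads: Iterable[ReadRecord], path: str | Path, quality_offset: int = 33
) -> int:
    """Write 4-line FASTQ; returns the number of records written.

    Quality characters are ``chr(q + offset)``; a combination outside the
    printable ASCII range [33, 126] is an encoding error.
    """
    if quality_offset not in (33, 64):
        raise ValueError(f"quality offset must be 33 or 64, got {quality_offset}")
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if read.qualities is None:
                raise ValueError(f"read {read.read_id!r} has no qualities")
            chars = []
            for q in read.qualities:
                c = q + quality_offset
                if not 33 <= c <= 126:
                    raise ValueError(
                        f"read {read.read_id!r}: quality {q} + offset "
                        f"{quality_offset} is outside printable ASCII"
                    )
                chars.append(chr(c))
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{''.join(chars)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM


def _parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise FormatError(f"malformed CIGAR string {text!r}")
    return ops


def _check_lengths(rec: AlignmentRecord, where: str) -> None:
    if rec.is_mapped and rec.sequence and rec.cigar:
        qlen = rec.query_length()
        if qlen != len(rec.sequence):
            raise FormatError(
                f"{where}: CIGAR consumes {qlen} query bases but the "
                f"sequence has {len(rec.sequence)} (read {rec.read_id!r})"
            )


def _read_sam_fallback(path: Path) -> Iterator[AlignmentRecord]:
    """Minimal parser for headerless SAM text (htslib needs @SQ lines)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: fewer than 11 SAM fields")
            flag = int(fields[1])
            mapped = not flag & 0x4
            seq = fields[9] if fields[9] != "*" else None
            nm = None
            md = None
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
                elif tag.startswith("MD:Z:"):
                    md = tag[5:]
            rec = AlignmentRecord(
                read_id=fields[0],
                genome_id=fields[2] if mapped else None,
                start=int(fields[3]) - 1 if mapped else -1,
                cigar=_parse_cigar(fields[5]) if mapped else [],
                md=md,
                nm=nm,
                is_mapped=mapped,
                sequence=_clean_sequence(seq) if seq else None,
            )
            _check_lengths(rec, f"{path}:{lineno}")
            yield rec


_CIGAR_CODES = "MIDNSHP=XB"


def _sam_has_sq_header(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                return False
            if line.startswith("@SQ"):
                return True
    return False


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignments from SAM text or BAM.

    Secondary alignments are included; unmapped records are yielded with
    ``is_mapped=False``.  SAM's 1-based POS becomes a 0-based ``start``.
    Headerless SAM text is accepted.
    """
    path = Path(path)
    is_bam = path.suffix.lower() == ".bam"
    if not is_bam and not _sam_has_sq_header(path):
        yield from _read_sam_fallback(path)
        return

    mode = "rb" if is_bam else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for i, aln in enumerate(fh, start=1):
            mapped = not aln.is_unmapped
            cigar = (
                [(_CIGAR_CODES[op], n) for op, n in aln.cigartuples]
                if aln.cigartuples
                else []
            )
            seq = aln.query_sequence
            rec = AlignmentRecord(
                read_id=aln.query_name,
                genome_id=aln.reference_name if mapped else None,
                start=aln.reference_start if mapped else -1,
                cigar=cigar,
                md=aln.get_tag("MD") if aln.has_tag("MD") else None,
                nm=aln.get_tag("NM") if aln.has_tag("NM") else None,
                is_mapped=mapped,
                sequence=_clean_sequence(seq) if seq else None,
            )
            _check_lengths(rec, f"{path}: record {i}")
            yield rec


# ---------------------------------------------------------------------------
# Composition tables


def read_composition_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``genome_id<TAB>abundance``; '#' starts a comment."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'genome_id<TAB>abundance'"
                )
            gid, value = parts
            if gid in table:
                raise FormatError(f"{path}:{lineno}: duplicate genome {gid!r}")
            table[gid] = float(value)
    if not table:
        raise FormatError(f"{path}: empty composition table")
    return table


def write_composition_table(table: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome_id\tabundance\n")
        for gid, value in table.items():
            fh.write(f"{gid}\t{float(value)!r}\n")
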