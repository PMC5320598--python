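"""Sequence records and FASTA/FASTQ input/output.

Every stage of the pipeline exchanges plain :class:`SeqRecord` and
:class:`ReadPair` objects.  Sequences are uppercase DNA over ``{A,C,G,T,N}``;
ambiguity codes other than ``N`` are rejected so that downstream k-mer logic
stays unambiguous.  Parsing and formatting of the on-disk formats is delegated
to Biopython; this module only adds validation and the pairing logic for
paired-end FASTQ files.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import SeqIO as _SeqIO
from Bio.Seq import Seq as _Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "ReadPair",
    "FormatError",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_fastq_pairs",
    "write_fastq_pairs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A sequence file violates the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """An identified DNA sequence with optional per-base qualities.

    Invariants: the sequence is non-empty uppercase ``{A,C,G,T,N}``; the id is
    non-empty and contains no whitespace; qualities, when present, have the
    same length as the sequence (Sanger Phred+33 encoding).
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if not set(self.seq) <= _VALID_BASES:
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {bad}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        qual = self.qual[::-1] if self.qual is not None else None
        return SeqRecord(self.id, revcomp(self.seq), qual)


@dataclass(frozen=True)
class ReadPair:
    """A forward/reverse read pair sequenced from the two ends of one fragment."""

    fwd: SeqRecord
    rev: SeqRecord
    pair_id: str

    def __post_init__(self) -> None:
        if not self.pair_id:
            raise ValueError("pair_id must be non-empty")


def _open(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _fold(raw: str, record_id: str, what: str) -> str:
    seq = raw.upper()
    if not seq:
        raise FormatError(f"{what} record {record_id!r} has an empty sequence")
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise FormatError(
            f"{what} record {record_id!r} contains characters outside ACGTN: {bad}"
        )
    return seq


def read_fasta(path: PathLike) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord` in file order.

    Multi-line sequences are concatenated and lowercase is folded to
    uppercase.  Raises :class:`FormatError` for records with empty sequences
    or characters outside the ``ACGTN`` alphabet.
    """
    records: list[SeqRecord] = []
    with _open(path) as handle:
        for rec in _SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            records.append(SeqRecord(rec.id, _fold(str(rec.seq), rec.id, "FASTA")))
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: PathLike, line_width: int = 60
) -> Path:
    """Write records as wrapped FASTA; returns the path written.

    Round-trips with :func:`read_fasta` (qualities are dropped).
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with _open(path, "wt") as handle:
        writer = _SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(
            _BioSeqRecord(_Seq(r.seq), id=r.id, description="") for r in records
        )
    return path


def _iter_fastq(path: PathLike) -> Iterator[SeqRecord]:
    with _open(path) as handle:
        for rec in _SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            qual = "".join(chr(q + 33) for q in quals)
            yield SeqRecord(rec.id, _fold(str(rec.seq), rec.id, "FASTQ"), qual)


def read_fastq(path: PathLike) -> list[SeqRecord]:
    """Read a single FASTQ file (Sanger Phred+33) into records in file order."""
    return list(_iter_fastq(path))


def write_fastq(records: Iterable[SeqRecord], path: PathLike) -> Path:
    path = Path(path)
    with _open(path, "wt") as handle:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
    return path


def strip_pair_suffix(read_id: str) -> str:
    """Derive the fragment (pair) id from a read id.

    Drops anything after the first whitespace (Casava 1.8 style ``@id 1:N:0:``
    headers) and a trailing ``/1`` or ``/2`` mate suffix.
    """
    base = read_id.split()[0] if read_id else read_id
    if base.endswith(("/1", "/2")):
        base = base[:-2]
    return base


def read_fastq_pairs(path_fwd: PathLike, path_rev: PathLike) -> list[ReadPair]:
    """Read two matched FASTQ files into read pairs.

    Pairing is positional (record *i* of each file forms pair *i*), which is
    what paired FASTQ files guarantee; a mismatch between the stripped ids of
    the two mates is reported as a warning, not an error, to accommodate the
    common FASTQ id dialects.  A record-count mismatch is an error.
    """
    pairs: list[ReadPair] = []
    it_fwd = _iter_fastq(path_fwd)
    it_rev = _iter_fastq(path_rev)
    index = 0
    while True:
        fwd = next(it_fwd, None)
        rev = next(it_rev, None)
        if fwd is None and rev is None:
            break
        if fwd is None or rev is None:
            longer = path_rev if fwd is None else path_fwd
            raise FormatError(
                f"paired FASTQ files differ in record count at record {index}: "
                f"{longer} has extra records"
            )
        pid_f = strip_pair_suffix(fwd.id)
        pid_r = strip_pair_suffix(rev.id)
        if pid_f != pid_r:
            warnings.warn(
                f"read ids disagree at record {index}: {fwd.id!r} vs {rev.id!r}; "
                "pairing positionally",
                stacklevel=2,
            )
        pairs.append(ReadPair(fwd, rev, pid_f))
        index += 1
    return pairs


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path_fwd: PathLike, path_rev: PathLike
) -> tuple[Path, Path]:
    pairs = list(pairs)
    write_fastq((p.fwd for p in pairs), path_fwd)
    write_fastq((p.rev for p in pairs), path_rev)
    return Path(path_fwd), Path(path_rev)
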