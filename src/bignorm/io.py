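"""Streaming FASTQ(.gz) / FASTA readers and writers, Sanger phred+33 only.

FASTQ records are strictly four lines (multi-line FASTQ is rejected);
the ``+`` separator line's content is ignored on read and written bare,
and a trailing newline is always written, so round trips are
byte-identical for well-formed input in that form. Quality strings are
decoded as ASCII − 33. Files whose first record's quality characters
all exceed ``'J'`` (phred 41 under +33) are rejected as likely
phred+64-encoded rather than silently mis-decoded.

Ground-truth read origins travel in a BED-like sidecar TSV
(``reference_id  start  end  read_id  strand``, 0-based half-open)
instead of being embedded in read ids.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "ReadRecord",
    "FastqParseError",
    "PairingError",
    "read_fastq",
    "read_paired",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_truth",
    "read_truth",
]

PHRED_OFFSET = 33
_MAX_SANE_QUAL_CHAR = ord("J")  # phred 41, Illumina 1.8+ ceiling


class FastqParseError(ValueError):
    """Malformed FASTQ input; message carries the offending record/line."""


class PairingError(ValueError):
    """Paired files with unequal record counts."""


@dataclass
class ReadRecord:
    """One sequencing read.

    ``truth`` optionally carries the simulator origin interval as
    ``(reference_id, start, end, strand)``.
    """

    id: str
    bases: str
    phreds: np.ndarray
    mate_index: int | None = None
    truth: tuple[str, int, int, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.phreds = np.asarray(self.phreds, dtype=np.int16)
        if len(self.bases) != len(self.phreds):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases, "
                f"{len(self.phreds)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def quality_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.phreds)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_quality(qual: str, read_id: str, line_no: int) -> np.ndarray:
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
    if arr.size and (arr.min() < PHRED_OFFSET or arr.max() > 126):
        raise FastqParseError(
            f"line {line_no}: quality string of {read_id!r} contains "
            "characters outside the Sanger phred+33 range (!..~)"
        )
    return arr - PHRED_OFFSET


def read_fastq(source: str | Path | IO[str]) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` from a FASTQ file or text stream.

    Accepts plain or gzip-compressed paths. Raises
    :class:`FastqParseError` on truncated records, sequence/quality
    length mismatches, bad separators, or likely phred+64 encoding.
    """
    if isinstance(source, (str, Path)):
        with _open_text(source) as fh:
            yield from read_fastq(fh)
        return

    first = True
    record_idx = 0
    line_no = 0
    while True:
        header = source.readline()
        line_no += 1
        if header == "":
            return
        header = header.rstrip("\n")
        if header == "" :
            # tolerate a single trailing blank line
            if source.readline() == "":
                return
            raise FastqParseError(f"line {line_no}: blank line inside FASTQ")
        if not header.startswith("@"):
            raise FastqParseError(
                f"line {line_no}: record {record_idx} does not start with '@' "
                f"(multi-line FASTQ is not supported)"
            )
        lines = [source.readline() for _ in range(3)]
        if any(l == "" for l in lines):
            raise FastqParseError(
                f"file ends mid-record in record {record_idx} "
                f"(header at line {line_no})"
            )
        seq, sep, qual = (l.rstrip("\n") for l in lines)
        if not sep.startswith("+"):
            raise FastqParseError(
                f"line {line_no + 2}: record {record_idx} separator is "
                f"{sep!r}, expected '+' (multi-line FASTQ is not supported)"
            )
        if len(seq) != len(qual):
            raise FastqParseError(
                f"line {line_no + 3}: record {record_idx} has {len(seq)} bases "
                f"but {len(qual)} quality characters"
            )
        _tokens = header[1:].split()
        rid = _tokens[0] if _tokens else ""
        phreds = _decode_quality(qual, rid, line_no + 3)
        if first and len(phreds) and phreds.min() + PHRED_OFFSET > _MAX_SANE_QUAL_CHAR:
            raise FastqParseError(
                "all quality characters of the first record exceed 'J' "
                "(phred 41): input looks phred+64-encoded; only Sanger "
                "phred+33 is supported"
            )
        first = False
        yield ReadRecord(id=rid, bases=seq, phreds=phreds)
        record_idx += 1
        line_no += 3


def read_paired(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Yield aligned mate pairs; raise :class:`PairingError` on count mismatch."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if (r1 is None) != (r2 is None):
            longer = str(path1 if r2 is None else path2)
            raise PairingError(
                f"paired files differ in record count: {longer} has extra "
                f"records after pair {n}"
            )
        r1.mate_index, r2.mate_index = 0, 1
        yield r1, r2
        n += 1


def write_fastq(
    records: Iterable[ReadRecord],
    dest: str | Path | IO[str],
    compress: bool | None = None,
) -> int:
    """Write records as 4-line phred+33 FASTQ; returns the count written.

    ``compress=None`` infers gzip from a ``.gz`` suffix.
    """
    if isinstance(dest, (str, Path)):
        path = Path(dest)
        gz = compress if compress is not None else path.suffix == ".gz"
        opener = gzip.open if gz else open
        with opener(path, "wt") as fh:
            return write_fastq(records, fh)
    n = 0
    for rec in records:
        dest.write(f"@{rec.id}\n{rec.bases}\n+\n{rec.quality_string}\n")
        n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-line) FASTA file as ``[(id, sequence), ...]``."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(
    entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(
    records: Iterable[tuple[str, int, int, str, str]], path: str | Path
) -> int:
    """Write truth intervals as TSV rows (ref_id, start, end, read_id, strand)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for ref, start, end, read_id, strand in records:
            fh.write(f"{ref}\t{start}\t{end}\t{read_id}\t{strand}\n")
            n += 1
    return n


def read_truth(path: str | Path) -> dict[str, tuple[str, int, int, str]]:
    """Load a truth TSV as ``{read_id: (ref_id, start, end, strand)}``."""
    out: dict[str, tuple[str, int, int, str]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"truth TSV line {ln}: expected 5 columns")
            ref, start, end, read_id, strand = parts
            out[read_id] = (ref, int(start), int(end), strand)
    return out
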