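"""FASTQ collection I/O: scanning, reads-stream extraction, sampling, fingerprints.

Only the sequence lines ("reads stream") of a FASTQ file are ever compressed;
headers and quality strings are carried through pre-compression sampling but
never restored. Restored output is one read per line in ``F_i.reads`` files.

Files may be plain text or gzip-compressed; compression is detected from the
magic bytes, not the file name. Records must be strict 4-line FASTQ: a
multi-line-sequence dialect is rejected, not coerced.
"""

from __future__ import annotations

import gzip
import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

from .errors import MalformedFastqError

__all__ = [
    "ReadsFile",
    "ReadsStream",
    "Fingerprint",
    "scan_fastq",
    "extract_reads_stream",
    "sample_record_groups",
    "fingerprint",
    "write_reads_file",
    "read_reads_file",
]

def _norm_byte(b: int) -> int:
    if b in b"ACGTN":
        return b
    if b in b"acgtn":
        return b - 32
    return ord("N")


# Uppercase everything, then map any byte outside {A,C,G,T,N} to N.
_NORMALIZE = bytes.maketrans(bytes(range(256)), bytes(map(_norm_byte, range(256))))


@dataclass(frozen=True)
class ReadsFile:
    """Identity and size summary of one FASTQ file in a collection.

    ``n_records`` is the number of 4-line records (line count / 4);
    ``mean_read_length`` is ``total_bases / n_records`` for non-empty files.
    """

    index: int
    path: Path
    n_records: int
    total_bases: int

    @property
    def mean_read_length(self) -> float:
        if self.n_records == 0:
            return 0.0
        return self.total_bases / self.n_records


@dataclass(frozen=True)
class ReadsStream:
    """Ordered normalized sequence lines of one file, alphabet {A,C,G,T,N}."""

    file_index: int
    reads: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Fingerprint:
    """SHA-256 digest of a newline-joined reads stream (hex)."""

    file_index: int
    digest: str


def _open_text(path: Path) -> IO[bytes]:
    """Open plain or gzip file for binary streaming, sniffing the gzip magic."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(raw, "rb")  # type: ignore[return-value]
    return raw


def _iter_records(path: Path) -> Iterator[tuple[int, bytes, bytes, bytes, bytes]]:
    """Yield (record_index, header, seq, plus, qual) with strict validation.

    Raises :class:`MalformedFastqError` naming the first offending 1-based
    line when the file is not a well-formed 4-line FASTQ.
    """
    with _open_text(path) as fh:
        lineno = 0
        rec = 0
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                break
            n_present = sum(1 for ln in lines if ln)
            if n_present < 4:
                raise MalformedFastqError(
                    f"{path}: truncated record at line {lineno + n_present}: "
                    f"line count is not a multiple of 4"
                )
            header, seq, plus, qual = (ln.rstrip(b"\r\n") for ln in lines)
            if not header.startswith(b"@"):
                raise MalformedFastqError(
                    f"{path}: line {lineno + 1}: record header must start with '@'"
                )
            if not plus.startswith(b"+"):
                raise MalformedFastqError(
                    f"{path}: line {lineno + 3}: separator line must start with '+' "
                    f"(multi-line sequences are not supported)"
                )
            if len(qual) != len(seq):
                raise MalformedFastqError(
                    f"{path}: line {lineno + 4}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            yield rec, header, seq, plus, qual
            rec += 1
            lineno += 4


def scan_fastq(path: Path | str, index: int = 0) -> ReadsFile:
    """Stream through a FASTQ file counting records and bases.

    Does not retain reads in memory. Malformed files raise
    :class:`MalformedFastqError`; they are never silently truncated.
    """
    path = Path(path)
    n_records = 0
    total_bases = 0
    for _, _, seq, _, _ in _iter_records(path):
        n_records += 1
        total_bases += len(seq)
    return ReadsFile(index=index, path=path, n_records=n_records, total_bases=total_bases)


def extract_reads_stream(path: Path | str, file_index: int = 0) -> ReadsStream:
    """Extract normalized sequence lines in record order.

    Sequences are uppercased; characters outside {A,C,G,T,N} become N.
    Headers and quality lines are discarded.
    """
    path = Path(path)
    reads = tuple(
        seq.translate(_NORMALIZE).decode("ascii")
        for _, _, seq, _, _ in _iter_records(path)
    )
    return ReadsStream(file_index=file_index, reads=reads)


def sample_record_groups(
    files: Sequence[ReadsFile],
    x: int,
    seed: int,
    out_path: Path | str,
) -> Path:
    """Build a pre-compression probe FASTQ of x records sampled from each file.

    Each sampled group is one complete 4-line record (header, read, separator,
    quality) copied verbatim. Sampling is uniform without replacement when
    ``x <= n_records``, with replacement otherwise; total output record count
    is exactly ``len(files) * x``. Deterministic for a given seed.
    """
    if not files:
        raise ValueError("empty collection: nothing to sample")
    if x < 1:
        raise ValueError(f"x must be >= 1, got {x}")
    for f in files:
        if f.n_records < 1:
            raise ValueError(f"{f.path}: zero records, cannot sample")
    rng = random.Random(seed)
    out_path = Path(out_path)
    with open(out_path, "wb") as out:
        for f in files:
            if x <= f.n_records:
                chosen = sorted(rng.sample(range(f.n_records), x))
                wanted = {i: 1 for i in chosen}
            else:
                wanted: dict[int, int] = {}
                for i in rng.choices(range(f.n_records), k=x):
                    wanted[i] = wanted.get(i, 0) + 1
            for rec, header, seq, plus, qual in _iter_records(f.path):
                times = wanted.get(rec, 0)
                for _ in range(times):
                    out.write(header + b"\n" + seq + b"\n" + plus + b"\n" + qual + b"\n")
    return out_path


def fingerprint(stream: ReadsStream) -> Fingerprint:
    """SHA-256 over the newline-joined normalized reads; platform stable."""
    h = hashlib.sha256("\n".join(stream.reads).encode("ascii"))
    return Fingerprint(file_index=stream.file_index, digest=h.hexdigest())


def write_reads_file(stream: ReadsStream, path: Path | str) -> Path:
    """Write a one-read-per-line ``.reads`` text file."""
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for read in stream.reads:
            fh.write(read)
            fh.write("\n")
    return path


def read_reads_file(path: Path | str, file_index: int = 0) -> ReadsStream:
    """Read a one-read-per-line ``.reads`` file back into a stream."""
    with open(path, "r", encoding="ascii") as fh:
        reads = tuple(line.rstrip("\n") for line in fh)
    return ReadsStream(file_index=file_index, reads=reads)
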