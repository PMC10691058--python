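"""Base-composition feature extraction for reads streams.

Each read is scored by the product of its (count + 1) over the four bases
A, C, G, T, divided by the collection-wide mean read length n:

    feature(read) = [(#A + 1) * (#C + 1) * (#G + 1) * (#T + 1)] / n

N bases (and anything normalized to N) contribute to no count. The integer
numerator ("integer key") depends only on the read's base composition, so two
identical reads — the redundancy the optimizer hunts for — always map to the
same key, and downstream similarity compares keys exactly, with no
floating-point equality hazards.

File-to-worker assignment follows a cyclic division: file i goes to logical
worker i mod Pr. The assignment is recorded for diagnostics but the output is
bitwise identical for every Pr.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .fastq_io import ReadsFile, ReadsStream, extract_reads_stream

__all__ = [
    "FeatureVector",
    "read_feature",
    "file_features",
    "collection_features",
    "collection_mean_read_length",
    "export_feature_summary",
]


@dataclass(frozen=True)
class FeatureVector:
    """Per-read composition scores for one file, in read order."""

    file_index: int
    values: tuple[float, ...]
    integer_keys: tuple[int, ...]
    worker: int = 0

    def __len__(self) -> int:
        return len(self.integer_keys)


def read_feature(read: str, n: float) -> tuple[int, float]:
    """Composition product score of one read.

    Returns ``(integer_key, integer_key / n)`` where the key is the product of
    (base count + 1) over A, C, G, T. An empty read scores key 1.
    """
    if n <= 0:
        raise ValueError(f"mean read length n must be > 0, got {n}")
    key = (
        (read.count("A") + 1)
        * (read.count("C") + 1)
        * (read.count("G") + 1)
        * (read.count("T") + 1)
    )
    return key, key / n


def file_features(stream: ReadsStream, n: float, worker: int = 0) -> FeatureVector:
    """Score every read of one stream, preserving read order."""
    keys = []
    values = []
    for read in stream.reads:
        k, val = read_feature(read, n)
        keys.append(k)
        values.append(val)
    return FeatureVector(
        file_index=stream.file_index,
        values=tuple(values),
        integer_keys=tuple(keys),
        worker=worker,
    )


def collection_mean_read_length(files: Sequence[ReadsFile]) -> float:
    """Collection-wide mean read length n = total bases / total records."""
    total_records = sum(f.n_records for f in files)
    total_bases = sum(f.total_bases for f in files)
    if total_records == 0:
        raise ValueError("collection has zero reads: mean read length undefined")
    return total_bases / total_records


def collection_features(
    files: Sequence[ReadsFile],
    Pr: int = 1,
    streams: Sequence[ReadsStream] | None = None,
) -> list[FeatureVector]:
    """Feature vectors for a whole collection under one shared n.

    File i is handled by logical worker ``i % Pr``; results are merged in
    file-index order so the outcome is independent of Pr and of worker
    scheduling. Streams are extracted from ``files[i].path`` unless
    pre-extracted streams are supplied.
    """
    if Pr < 1:
        raise ValueError(f"Pr must be >= 1, got {Pr}")
    n = collection_mean_read_length(files)
    if streams is None:
        streams = [extract_reads_stream(f.path, f.index) for f in files]
    out: list[FeatureVector] = []
    for i, stream in enumerate(streams):
        out.append(file_features(stream, n, worker=i % Pr))
    return out


def export_feature_summary(
    files: Sequence[ReadsFile],
    vectors: Sequence[FeatureVector],
    path: Path | str,
) -> Path:
    """Write a diagnostic TSV of per-file feature summaries."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("file\tn_records\tmin_value\tmedian_value\tmax_value\n")
        for f, vec in zip(files, vectors):
            if len(vec) == 0:
                fh.write(f"{f.path.name}\t0\tnan\tnan\tnan\n")
                continue
            vals = sorted(vec.values)
            mid = len(vals) // 2
            med = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
            fh.write(
                f"{f.path.name}\t{f.n_records}\t{vals[0]:.6g}\t{med:.6g}\t{vals[-1]:.6g}\n"
            )
    return path
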