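"""End-to-end joint compression and lossless restoration of FASTQ collections.

Compression chain: scan the collection, probe the backend's peak memory on two
sampled workloads, extrapolate full-collection peak memory, derive the
files-level cluster count from the user's memory budget, score pairwise
redundancy, cluster greedily under the per-cluster read budget, merge each
cluster's reads streams, compress each merged stream with the backend (one
cluster at a time, so a single backend instance is in memory at once), and
package everything into a single ``.pmffrc`` archive.

Archive layout (little-endian):

    bytes 0..3   magic "PMFC"
    bytes 4..7   format version (u32)
    bytes 8..15  manifest length in bytes (u64)
    manifest     canonical JSON (sorted keys, UTF-8)
    payloads     concatenated backend-compressed cluster streams

The manifest records per-file identities, record counts and reads-stream
fingerprints, the cluster table, and per-payload offsets (relative to the end
of the manifest) and sizes. Decompression unpacks each payload, splits the
merged stream at the recorded per-member record counts, writes one
``<name>.reads`` file per original input, and verifies every fingerprint.
"""

from __future__ import annotations

import json
import logging
import struct
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .clustering import ClusterPlan, two_level_cluster
from .errors import BackendError, IntegrityError, VerificationError
from .fastq_io import (
    ReadsFile,
    ReadsStream,
    extract_reads_stream,
    fingerprint,
    sample_record_groups,
    scan_fastq,
    write_reads_file,
)
from .features import collection_features
from .memory_model import (
    BackendSpec,
    MemoryEstimate,
    MemoryProbe,
    estimate_cpm,
    files_level_K,
    get_backend,
    measure_peak_memory,
)
from .similarity import pairwise_similarities

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "RunConfig",
    "FileRecord",
    "ArchiveManifest",
    "compress_collection",
    "decompress_archive",
    "verify_archive",
    "compression_metrics",
    "bits_per_base",
    "discover_fastq_files",
]

logger = logging.getLogger(__name__)

MAGIC = b"PMFC"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<4sIQ")

_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a compression run.

    ``u_ram`` is the safe memory threshold in bytes; ``x1``/``x2`` the
    pre-compression sample sizes in records per file; ``Pr`` the logical core
    count for feature/similarity stages; ``T`` the backend thread count.
    """

    backend: BackendSpec
    u_ram: int = 8 << 30
    Pr: int = 1
    T: int = 1
    x1: int = 100
    x2: int = 100_100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u_ram <= 0:
            raise ValueError("u_ram must be > 0")
        if self.Pr < 1 or self.T < 1:
            raise ValueError("Pr and T must be >= 1")
        if not (self.x2 > self.x1 >= 1):
            raise ValueError(f"require x2 > x1 >= 1, got x1={self.x1}, x2={self.x2}")


@dataclass(frozen=True)
class FileRecord:
    """Manifest entry for one original FASTQ file."""

    name: str
    index: int
    n_records: int
    fingerprint: str


@dataclass(frozen=True)
class ArchiveManifest:
    """Everything needed to restore and verify the original reads streams."""

    format_version: int
    backend_name: str
    v: int
    files: tuple[FileRecord, ...]
    clusters: tuple[tuple[int, ...], ...]
    payload_offsets: tuple[int, ...]
    payload_sizes: tuple[int, ...]
    K1: int = 1
    ave: int = 0

    def to_json(self) -> bytes:
        doc = {
            "format_version": self.format_version,
            "backend": self.backend_name,
            "v": self.v,
            "files": [
                {
                    "name": f.name,
                    "index": f.index,
                    "n_records": f.n_records,
                    "fingerprint": f.fingerprint,
                }
                for f in self.files
            ],
            "clusters": [list(c) for c in self.clusters],
            "payload_offsets": list(self.payload_offsets),
            "payload_sizes": list(self.payload_sizes),
            "K1": self.K1,
            "ave": self.ave,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()

    @classmethod
    def from_json(cls, raw: bytes) -> "ArchiveManifest":
        try:
            doc = json.loads(raw)
            return cls(
                format_version=doc["format_version"],
                backend_name=doc["backend"],
                v=doc["v"],
                files=tuple(
                    FileRecord(
                        name=f["name"],
                        index=f["index"],
                        n_records=f["n_records"],
                        fingerprint=f["fingerprint"],
                    )
                    for f in doc["files"]
                ),
                clusters=tuple(tuple(c) for c in doc["clusters"]),
                payload_offsets=tuple(doc["payload_offsets"]),
                payload_sizes=tuple(doc["payload_sizes"]),
                K1=doc.get("K1", 1),
                ave=doc.get("ave", 0),
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise IntegrityError(f"corrupt archive manifest: {exc}")


def discover_fastq_files(input_dir: Path | str) -> list[Path]:
    """FASTQ files of a directory in deterministic (name-sorted) order."""
    input_dir = Path(input_dir)
    paths = sorted(
        p
        for p in input_dir.iterdir()
        if p.is_file() and p.name.lower().endswith(_FASTQ_SUFFIXES)
    )
    if not paths:
        raise ValueError(f"no FASTQ files found in {input_dir}")
    return paths


def _run_backend(backend: BackendSpec, cmd: list[str], what: str) -> None:
    proc = subprocess.run(cmd, capture_output=True)
    if proc.returncode != 0:
        raise BackendError(
            f"backend {backend.name!r} failed while {what} "
            f"(exit {proc.returncode})",
            stderr=proc.stderr.decode(errors="replace"),
        )


def _probe_memory(
    files: Sequence[ReadsFile],
    config: RunConfig,
    tmp: Path,
) -> tuple[MemoryProbe, MemoryEstimate, int]:
    """Run the two pre-compression probes and fit the memory model."""
    total_records = sum(f.n_records for f in files)
    peaks = []
    for which, x in (("x1", config.x1), ("x2", config.x2)):
        probe_fastq = sample_record_groups(
            files, x, seed=config.seed, out_path=tmp / f"probe_{which}.fastq"
        )
        peaks.append(measure_peak_memory(config.backend, probe_fastq, tmp))
        probe_fastq.unlink()
    probe = MemoryProbe(
        x1=config.x1, x2=config.x2, y_peak_1=peaks[0], y_peak_2=peaks[1], v=len(files)
    )
    estimate = estimate_cpm(probe, total_records)
    K1 = files_level_K(estimate, config.u_ram, config.backend.beta)
    logger.info(
        "memory model: y_res=%.1f MiB, slope=%.1f B/read, y_cpm=%.1f MiB, K1=%d",
        estimate.y_res / 2**20,
        estimate.slope_per_read,
        estimate.y_cpm / 2**20,
        K1,
    )
    return probe, estimate, K1


def compress_collection(
    input_dir: Path | str,
    config: RunConfig,
    output_path: Path | str,
) -> ArchiveManifest:
    """Jointly compress every FASTQ file under ``input_dir`` into one archive."""
    input_dir = Path(input_dir).resolve()
    output_path = Path(output_path).resolve()
    paths = discover_fastq_files(input_dir)
    files = [scan_fastq(p, index=i) for i, p in enumerate(paths)]
    streams = [extract_reads_stream(p, file_index=i) for i, p in enumerate(paths)]
    fingerprints = [fingerprint(s) for s in streams]

    try:
        with tempfile.TemporaryDirectory(prefix="pmffrc_", dir=output_path.parent) as td:
            tmp = Path(td)
            _, estimate, K1 = _probe_memory(files, config, tmp)
            plan = _plan_clusters(files, streams, K1, config)
            logger.info(
                "clustering: K1=%d, ave=%d, K=%d, clusters=%s",
                plan.K1, plan.ave, plan.K, plan.clusters,
            )
            payloads: list[bytes] = []
            for k, cluster in enumerate(plan.clusters):
                merged = tmp / f"C_{k}.reads"
                with open(merged, "w", encoding="ascii", newline="\n") as fh:
                    for i in cluster:
                        for read in streams[i].reads:
                            fh.write(read)
                            fh.write("\n")
                compressed = tmp / f"C_{k}.ycom"
                _run_backend(
                    config.backend,
                    config.backend.compress_command(merged, compressed),
                    f"compressing cluster {k}",
                )
                payloads.append(compressed.read_bytes())
                merged.unlink()
                compressed.unlink()

            offsets = []
            pos = 0
            for p in payloads:
                offsets.append(pos)
                pos += len(p)
            manifest = ArchiveManifest(
                format_version=FORMAT_VERSION,
                backend_name=config.backend.name,
                v=len(files),
                files=tuple(
                    FileRecord(
                        name=p.name,
                        index=i,
                        n_records=files[i].n_records,
                        fingerprint=fingerprints[i].digest,
                    )
                    for i, p in enumerate(paths)
                ),
                clusters=plan.clusters,
                payload_offsets=tuple(offsets),
                payload_sizes=tuple(len(p) for p in payloads),
                K1=plan.K1,
                ave=plan.ave,
            )
            _write_archive(output_path, manifest, payloads)
    except BaseException:
        output_path.unlink(missing_ok=True)  # no partial archives
        raise
    return manifest


def _plan_clusters(
    files: Sequence[ReadsFile],
    streams: Sequence[ReadsStream],
    K1: int,
    config: RunConfig,
) -> ClusterPlan:
    counts = [f.n_records for f in files]
    if len(files) < 2:
        return two_level_cluster(None, counts, K1)
    vectors = collection_features(files, Pr=config.Pr, streams=streams)
    sims = pairwise_similarities(vectors, Pr=config.Pr)
    return two_level_cluster(sims, counts, K1)


def _write_archive(
    path: Path, manifest: ArchiveManifest, payloads: Sequence[bytes]
) -> None:
    raw = manifest.to_json()
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, len(raw)))
        fh.write(raw)
        for p in payloads:
            fh.write(p)


def read_manifest(archive: Path | str) -> tuple[ArchiveManifest, int]:
    """Parse and validate an archive header; returns (manifest, payload base)."""
    archive = Path(archive)
    size = archive.stat().st_size
    with open(archive, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise IntegrityError(f"{archive}: too short for an archive header")
        magic, version, mlen = _HEADER.unpack(head)
        if magic != MAGIC:
            raise IntegrityError(f"{archive}: bad magic {magic!r}")
        if version != FORMAT_VERSION:
            raise IntegrityError(f"{archive}: unsupported format version {version}")
        raw = fh.read(mlen)
        if len(raw) != mlen:
            raise IntegrityError(f"{archive}: truncated manifest")
    manifest = ArchiveManifest.from_json(raw)
    base = _HEADER.size + mlen
    for off, sz in zip(manifest.payload_offsets, manifest.payload_sizes):
        if base + off + sz > size:
            raise IntegrityError(
                f"{archive}: payload at offset {off} (size {sz}) exceeds archive size"
            )
    claimed = sorted(i for c in manifest.clusters for i in c)
    if claimed != list(range(manifest.v)):
        raise IntegrityError(f"{archive}: cluster table is not a partition")
    return manifest, base


def decompress_archive(
    archive: Path | str,
    output_dir: Path | str,
    backend: BackendSpec | None = None,
) -> list[Path]:
    """Restore every original reads stream from an archive, verifying fingerprints.

    Writes one ``<original name>.reads`` file (one read per line) per input
    file into ``output_dir`` and returns their paths in file-index order.
    """
    archive = Path(archive).resolve()
    output_dir = Path(output_dir).resolve()
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest, base = read_manifest(archive)
    if backend is None:
        backend = get_backend(manifest.backend_name)
    by_index = {f.index: f for f in manifest.files}
    out_paths: dict[int, Path] = {}
    with tempfile.TemporaryDirectory(prefix="pmffrc_", dir=output_dir) as td, open(
        archive, "rb"
    ) as fh:
        tmp = Path(td)
        for k, cluster in enumerate(manifest.clusters):
            fh.seek(base + manifest.payload_offsets[k])
            payload = fh.read(manifest.payload_sizes[k])
            compressed = tmp / f"C_{k}.ycom"
            compressed.write_bytes(payload)
            merged = tmp / f"C_{k}.reads"
            _run_backend(
                backend,
                backend.decompress_command(compressed, merged),
                f"decompressing cluster {k}",
            )
            with open(merged, "r", encoding="ascii") as mfh:
                for i in cluster:
                    rec = by_index[i]
                    reads = []
                    for _ in range(rec.n_records):
                        line = mfh.readline()
                        if not line:
                            raise IntegrityError(
                                f"cluster {k}: merged stream ended early while "
                                f"splitting out {rec.name}"
                            )
                        reads.append(line.rstrip("\n"))
                    stream = ReadsStream(file_index=i, reads=tuple(reads))
                    got = fingerprint(stream).digest
                    if got != rec.fingerprint:
                        raise VerificationError(
                            f"lossless verification failed for {rec.name}: "
                            f"fingerprint {got[:12]}… != recorded "
                            f"{rec.fingerprint[:12]}…"
                        )
                    out_paths[i] = write_reads_file(
                        stream, output_dir / f"{rec.name}.reads"
                    )
            compressed.unlink()
            merged.unlink()
    return [out_paths[i] for i in sorted(out_paths)]


def verify_archive(
    archive: Path | str,
    input_dir: Path | str,
    backend: BackendSpec | None = None,
) -> bool:
    """Check that an archive losslessly restores the reads of ``input_dir``.

    Decompresses into a scratch directory (verifying recorded fingerprints on
    the way) and additionally compares each recorded fingerprint with one
    recomputed from the original FASTQ files. Raises
    :class:`VerificationError` on any mismatch; returns True otherwise.
    """
    archive = Path(archive)
    input_dir = Path(input_dir)
    manifest, _ = read_manifest(archive)
    by_name = {f.name: f for f in manifest.files}
    for path in discover_fastq_files(input_dir):
        rec = by_name.get(path.name)
        if rec is None:
            raise VerificationError(f"{path.name} is not recorded in the archive")
        got = fingerprint(extract_reads_stream(path, rec.index)).digest
        if got != rec.fingerprint:
            raise VerificationError(
                f"{path.name}: reads differ from the archived fingerprint"
            )
    with tempfile.TemporaryDirectory(prefix="pmffrc_verify_") as td:
        decompress_archive(archive, td, backend=backend)
    return True


def compression_metrics(
    cs_with: float,
    cs_without: float,
    cr_with: float,
    cr_without: float,
) -> tuple[float, float]:
    """Compression-ratio gain and percent storage savings, as fractions.

    ``crg = cr_with / cr_without - 1`` and ``pss = 1 - cs_with / cs_without``,
    with ``cr`` defined as original bytes / compressed bytes (larger is
    better) and ``cs`` the compressed size.
    """
    if cs_without <= 0 or cr_without <= 0:
        raise ValueError("cs_without and cr_without must be > 0")
    crg = cr_with / cr_without - 1.0
    pss = 1.0 - cs_with / cs_without
    return crg, pss


def bits_per_base(compressed_bytes: int, total_bases: int) -> float:
    """Display-parity compression ratio in bits per base (lower is better)."""
    if total_bases <= 0:
        raise ValueError("total_bases must be > 0")
    return 8.0 * compressed_bytes / total_bases
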