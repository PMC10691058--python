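"""Peak-memory modeling of the cascaded compressor and files-level cluster count.

The optimizer never trusts a compressor's documentation for memory usage.
Instead it probes the backend twice on sampled workloads of x1 and x2 records
per file, reads off an affine model

    Y_cpm = Y_res + Y_reads
          = Y_peak1 + |Y_peak2 - Y_peak1| / (v * (x2 - x1)) * total_records

(the intercept Y_peak1 is identified with the backend's resident memory —
dictionaries, hash tables — and the slope with per-read working memory), and
derives the files-level cluster count

    K1 = ceil(beta * Y_reads / (U_ram - Y_res))

where U_ram is the user's safe memory threshold and beta an empirical
correction factor absorbing mild nonlinearity of real compressors.
"""

from __future__ import annotations

import configparser
import math
import shlex
import shutil
import subprocess
import sys
import time
from dataclasses import dataclass, replace
from pathlib import Path

import psutil

from .errors import BackendError, BudgetError, ConfigError

__all__ = [
    "BackendSpec",
    "MemoryProbe",
    "MemoryEstimate",
    "measure_peak_memory",
    "estimate_cpm",
    "files_level_K",
    "builtin_backends",
    "load_backends",
    "get_backend",
]

#: RSS polling period for the child process tree, seconds.
POLL_INTERVAL = 0.05


@dataclass(frozen=True)
class BackendSpec:
    """An external reads compressor invoked per cluster.

    Command templates must contain ``{input}`` and ``{output}`` exactly once
    each and may contain ``{threads}``. ``beta`` is the empirical memory
    correction factor applied in the files-level cluster count.
    """

    name: str
    compress_template: str
    decompress_template: str
    beta: float = 1.0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ConfigError(f"backend {self.name!r}: beta must be > 0, got {self.beta}")
        for which, tpl in (
            ("compress", self.compress_template),
            ("decompress", self.decompress_template),
        ):
            for ph in ("{input}", "{output}"):
                if tpl.count(ph) != 1:
                    raise ConfigError(
                        f"backend {self.name!r}: {which} template must contain "
                        f"{ph} exactly once: {tpl!r}"
                    )

    def compress_command(self, input_path: Path, output_path: Path) -> list[str]:
        return _render(self.compress_template, input_path, output_path, self.threads)

    def decompress_command(self, input_path: Path, output_path: Path) -> list[str]:
        return _render(self.decompress_template, input_path, output_path, self.threads)


def _render(template: str, input_path: Path, output_path: Path, threads: int) -> list[str]:
    return [
        tok.format(input=str(input_path), output=str(output_path), threads=threads)
        for tok in shlex.split(template)
    ]


@dataclass(frozen=True)
class MemoryProbe:
    """Peak RSS observed on the two pre-compression sample workloads."""

    x1: int
    x2: int
    y_peak_1: int
    y_peak_2: int
    v: int

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 >= 1):
            raise ValueError(f"require x2 > x1 >= 1, got x1={self.x1}, x2={self.x2}")
        if self.y_peak_1 < 0 or self.y_peak_2 < 0:
            raise ValueError("peak memory must be >= 0")
        if self.v < 1:
            raise ValueError("collection must contain at least one file")


@dataclass(frozen=True)
class MemoryEstimate:
    """Fitted affine peak-memory model: y_cpm = y_res + slope * total_records."""

    y_res: float
    slope_per_read: float
    y_reads: float
    y_cpm: float
    total_records: int


def measure_peak_memory(
    backend: BackendSpec,
    input_path: Path | str,
    workdir: Path | str,
) -> int:
    """Run the backend's compress command and return its peak RSS in bytes.

    The child process and all descendants are polled at a fixed short interval
    and the maximum summed resident-set size is returned; the compressed
    output is discarded afterwards.
    """
    input_path = Path(input_path).resolve()
    workdir = Path(workdir).resolve()
    workdir.mkdir(parents=True, exist_ok=True)
    out = workdir / (input_path.name + ".probe_out")
    cmd = backend.compress_command(input_path, out)
    if shutil.which(cmd[0]) is None and not Path(cmd[0]).exists():
        raise ConfigError(f"backend {backend.name!r}: binary not found: {cmd[0]}")
    try:
        proc = subprocess.Popen(
            cmd, stdout=subprocess.PIPE, stderr=subprocess.PIPE, cwd=workdir
        )
    except OSError as exc:
        raise ConfigError(f"backend {backend.name!r}: cannot launch {cmd[0]}: {exc}")
    peak = 0
    ps = psutil.Process(proc.pid)
    try:
        while proc.poll() is None:
            peak = max(peak, _tree_rss(ps))
            time.sleep(POLL_INTERVAL)
    finally:
        _, stderr = proc.communicate()
        out.unlink(missing_ok=True)
    if proc.returncode != 0:
        raise BackendError(
            f"backend {backend.name!r} exited with status {proc.returncode} "
            f"while probing {input_path.name}",
            stderr=stderr.decode(errors="replace"),
        )
    return peak


def _tree_rss(ps: psutil.Process) -> int:
    try:
        procs = [ps, *ps.children(recursive=True)]
        return sum(p.memory_info().rss for p in procs)
    except psutil.NoSuchProcess:
        return 0


def estimate_cpm(probe: MemoryProbe, total_records: int) -> MemoryEstimate:
    """Extrapolate full-collection compression peak memory from the two probes.

    Intercept = first-probe peak (resident memory); slope = absolute peak
    difference per additional sampled record across the collection.
    """
    if total_records < 0:
        raise ValueError("total_records must be >= 0")
    y_res = float(probe.y_peak_1)
    slope = abs(probe.y_peak_2 - probe.y_peak_1) / (probe.v * (probe.x2 - probe.x1))
    y_reads = slope * total_records
    return MemoryEstimate(
        y_res=y_res,
        slope_per_read=slope,
        y_reads=y_reads,
        y_cpm=y_res + y_reads,
        total_records=total_records,
    )


def files_level_K(estimate: MemoryEstimate, u_ram: float, beta: float) -> int:
    """Files-level cluster count K1 = ceil(beta * y_reads / (u_ram - y_res)).

    Floored at 1: a zero cluster count (possible for tiny collections) is
    meaningless. A budget at or below the backend's resident memory is
    infeasible regardless of clustering.
    """
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if u_ram <= estimate.y_res:
        raise BudgetError(
            f"memory budget {u_ram / 2**30:.2f} GiB does not exceed the backend's "
            f"resident memory {estimate.y_res / 2**30:.2f} GiB; raise -u"
        )
    k1 = math.ceil(beta * estimate.y_reads / (u_ram - estimate.y_res))
    return max(k1, 1)


# --- backend registry ----------------------------------------------------

def _generic_backend() -> BackendSpec:
    # Child-process LZMA stream compressor shipped with the package: keeps the
    # probe measuring a real subprocess without requiring external tools.
    py = shlex.quote(sys.executable)
    return BackendSpec(
        name="generic",
        compress_template=f"{py} -m pmffrc._xz_backend c {{input}} {{output}}",
        decompress_template=f"{py} -m pmffrc._xz_backend d {{input}} {{output}}",
        beta=1.0,
        threads=1,
    )


def builtin_backends() -> dict[str, BackendSpec]:
    """Backends available without any configuration file."""
    generic = _generic_backend()
    return {
        "generic": generic,
        "zstd": BackendSpec(
            name="zstd",
            compress_template="zstd -q -f -T{threads} {input} -o {output}",
            decompress_template="zstd -d -q -f -T{threads} {input} -o {output}",
            beta=1.0,
            threads=1,
        ),
    }


def load_backends(path: Path | str) -> dict[str, BackendSpec]:
    """Load backend specs from an INI-style text file.

    Each section is a backend name with keys ``compress``, ``decompress`` and
    optional ``beta`` and ``threads``.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read backend configuration {path}")
    specs: dict[str, BackendSpec] = {}
    for name in cp.sections():
        sec = cp[name]
        try:
            specs[name] = BackendSpec(
                name=name,
                compress_template=sec["compress"],
                decompress_template=sec["decompress"],
                beta=sec.getfloat("beta", 1.0),
                threads=sec.getint("threads", 1),
            )
        except KeyError as exc:
            raise ConfigError(f"backend {name!r}: missing key {exc}")
    return specs


def get_backend(
    name: str,
    config_path: Path | str | None = None,
    beta: float | None = None,
    threads: int | None = None,
) -> BackendSpec:
    """Resolve a backend by name from the built-ins plus an optional config file."""
    specs = builtin_backends()
    if config_path is not None:
        specs.update(load_backends(config_path))
    if name not in specs:
        raise ConfigError(f"unknown backend {name!r}; known: {sorted(specs)}")
    spec = specs[name]
    if beta is not None:
        spec = replace(spec, beta=beta)
    if threads is not None:
        spec = replace(spec, threads=threads)
    return spec
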