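import random
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


def write_fastq(path: Path, reads, quals=None, headers=None) -> Path:
    """Write a minimal strict 4-line FASTQ file from a list of read strings."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for j, read in enumerate(reads):
            header = headers[j] if headers else f"@r{j}"
            qual = quals[j] if quals else "I" * len(read)
            fh.write(f"{header}\n{read}\n+\n{qual}\n")
    return path


def random_reads(rng: random.Random, n: int, length: int):
    return ["".join(rng.choice("ACGT") for _ in range(length)) for _ in range(n)]


@pytest.fixture
def fastq_writer(tmp_path):
    def _write(name, reads, **kw):
        return write_fastq(tmp_path / name, reads, **kw)

    return _write
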