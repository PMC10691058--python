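"""Synthetic FASTQ collections with planted cross-file redundancy.

Real multi-file sequencing collections are redundant because files from the
same library, tissue or species share reads. The generator emulates exactly
that structure and nothing more: files are partitioned into redundancy
groups; each group samples a shared read pool once, and each member file
draws a configurable fraction of its records verbatim from that pool, the
remainder being independent uniform-random ACGT reads. Quality lines are a
constant character so the reads stream is the only information-bearing
channel.

Also packaged here is the five-file worked clustering example: per-file
record counts and a similarity list whose printed maxima (0.92 for the pair
(3, 0), 0.90 for (4, 1)) drive the greedy clusterer through seed, rejection
and singleton steps with budget ave = 530.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .similarity import SimilarityEntry, SimilarityList

__all__ = ["SyntheticSpec", "generate_collection", "worked_example_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated collection.

    ``groups`` partitions file indices 0..v-1 into redundancy groups;
    ``shared_fraction`` is the fraction of each file's records drawn from its
    group's shared pool.
    """

    v: int
    records_per_file: tuple[int, ...]
    read_length: int = 100
    groups: tuple[tuple[int, ...], ...] = ()
    shared_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.records_per_file) != self.v:
            raise ValueError("records_per_file must have one entry per file")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in [0, 1]")
        groups = self.groups or tuple((i,) for i in range(self.v))
        object.__setattr__(self, "groups", groups)
        flat = sorted(i for g in self.groups for i in g)
        if flat != list(range(self.v)):
            raise ValueError("groups must partition file indices 0..v-1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def _random_read(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def generate_collection(spec: SyntheticSpec, output_dir: Path | str) -> list[Path]:
    """Write the collection's FASTQ files; deterministic per seed.

    Each group's shared pool is sized at the group's largest file so pool
    draws are near-unique within one file but heavily repeated across the
    group's members.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    paths: list[Path] = [output_dir / f"sample_{i:03d}.fastq" for i in range(spec.v)]
    qual = "I" * spec.read_length
    for group in spec.groups:
        pool_size = max(spec.records_per_file[i] for i in group)
        pool = [_random_read(rng, spec.read_length) for _ in range(pool_size)]
        for i in group:
            n = spec.records_per_file[i]
            n_shared = round(n * spec.shared_fraction)
            # without replacement while the pool suffices: a fully-shared,
            # equal-size pair is then an identical read multiset
            if n_shared <= pool_size:
                reads = rng.sample(pool, n_shared)
            else:
                reads = rng.choices(pool, k=n_shared)
            reads += [_random_read(rng, spec.read_length) for _ in range(n - n_shared)]
            rng.shuffle(reads)
            with open(paths[i], "w", encoding="ascii", newline="\n") as fh:
                for j, read in enumerate(reads):
                    fh.write(f"@sample_{i}_read_{j}\n{read}\n+\n{qual}\n")
    return paths


# Per-file record counts of the packaged worked example. Only the pair totals
# (340 = F0+F3, 650 = F0+F3+F1, 460 = F1+F4, M = 1060) are fixed by the
# example; this per-file split of those totals is the packaged constant.
_EXAMPLE_COUNTS = (200, 310, 260, 140, 150)

# Printed scores: (3,0) = 0.92 is the global maximum and (4,1) = 0.90 tops the
# list after cluster {0,3} closes. The remaining entries are free; they are
# chosen pairwise distinct, strictly below 0.90, and such that the first
# cluster's growth candidate is file 1 (via sim(1,0) = 0.88 dominating every
# other link to members 0 and 3).
_EXAMPLE_SCORES = {
    (3, 0): 0.92,
    (4, 1): 0.90,
    (1, 0): 0.88,
    (2, 1): 0.86,
    (4, 2): 0.84,
    (2, 0): 0.82,
    (4, 3): 0.80,
    (3, 1): 0.78,
    (3, 2): 0.76,
    (4, 0): 0.74,
}


def worked_example_fixture() -> tuple[tuple[int, ...], SimilarityList, int]:
    """The packaged five-file worked example: (counts, similarity list, K1=2)."""
    entries = tuple(
        SimilarityEntry(a=a, b=b, score=s)
        for (a, b), s in sorted(_EXAMPLE_SCORES.items(), key=lambda kv: -kv[1])
    )
    return _EXAMPLE_COUNTS, SimilarityList(entries=entries, v=5), 2
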