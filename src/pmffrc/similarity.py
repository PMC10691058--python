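"""Size-corrected dice similarity between per-file feature-key multisets.

For files a and b with feature-key multisets A, B:

    sim(a, b) = alpha * 2|A ∩ B| / (|A| + |B|)
    alpha     = 1 / (1 - | |A| - |B| | / (|A| + |B|))

|A ∩ B| is the multiset intersection (sum over distinct keys of the minimum
multiplicity), so repeated redundant reads — the phenomenon being measured —
count with multiplicity. alpha corrects for unbalanced file sizes and can push
scores above 1; only the ordering matters to the clustering stage, so scores
are not clamped. A pair involving an empty file is degenerate (alpha divides
by zero) and scores 0 with a logged warning rather than aborting the run.

All v(v-1)/2 pairs (a > b) are scored; pair s is assigned to logical worker
s mod Pr, and the result is invariant to Pr.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .features import FeatureVector

__all__ = [
    "SimilarityEntry",
    "SimilarityList",
    "balance_factor",
    "dice_similarity",
    "pairwise_similarities",
    "export_similarity_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityEntry:
    """One scored pair; by convention a > b."""

    a: int
    b: int
    score: float

    def __post_init__(self) -> None:
        if not self.a > self.b:
            raise ValueError(f"require a > b, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class SimilarityList:
    """All pairs of a collection, sorted by score descending, ties by (a, b)."""

    entries: tuple[SimilarityEntry, ...]
    v: int

    def __post_init__(self) -> None:
        expect = self.v * (self.v - 1) // 2
        if len(self.entries) != expect:
            raise ValueError(
                f"similarity list for v={self.v} files must have {expect} "
                f"entries, got {len(self.entries)}"
            )

    def __len__(self) -> int:
        return len(self.entries)


def balance_factor(size_a: int, size_b: int) -> float:
    """Size-imbalance correction alpha = (|A| + |B|) / (2 min(|A|, |B|)).

    Raises ZeroDivisionError for a zero size; callers scoring pairs should
    treat that pair as degenerate (score 0) instead of propagating.
    """
    if size_a < 0 or size_b < 0 or size_a + size_b == 0:
        raise ValueError("sizes must be >= 0 and not both zero")
    total = size_a + size_b
    return 1.0 / (1.0 - abs(size_a - size_b) / total)


def dice_similarity(va: FeatureVector, vb: FeatureVector) -> float:
    """alpha-corrected dice coefficient on the two key multisets; symmetric."""
    na, nb = len(va), len(vb)
    if na == 0 or nb == 0:
        logger.warning(
            "degenerate pair (file %d, file %d): empty feature vector, score 0",
            va.file_index,
            vb.file_index,
        )
        return 0.0
    inter = _multiset_intersection(va.integer_keys, vb.integer_keys)
    alpha = balance_factor(na, nb)
    return alpha * 2.0 * inter / (na + nb)


def _multiset_intersection(keys_a: Sequence[int], keys_b: Sequence[int]) -> int:
    ca, cb = Counter(keys_a), Counter(keys_b)
    if len(cb) < len(ca):
        ca, cb = cb, ca
    return sum(min(m, cb[k]) for k, m in ca.items() if k in cb)


def pairwise_similarities(vectors: Sequence[FeatureVector], Pr: int = 1) -> SimilarityList:
    """Score all pairs and sort descending with deterministic tie-break.

    Pair s (in row-major (a, b) enumeration, a > b) is assigned to logical
    worker s mod Pr; output is identical for every Pr.
    """
    if Pr < 1:
        raise ValueError(f"Pr must be >= 1, got {Pr}")
    v = len(vectors)
    if v < 2:
        raise ValueError("need at least 2 files for pairwise similarity")
    entries = []
    s = 0
    for a in range(1, v):
        for b in range(a):
            score = dice_similarity(vectors[a], vectors[b])
            entries.append(SimilarityEntry(a=a, b=b, score=score))
            s += 1  # worker s % Pr; sequential evaluation, same result
    entries.sort(key=lambda e: (-e.score, e.a, e.b))
    return SimilarityList(entries=tuple(entries), v=v)


def export_similarity_tsv(sims: SimilarityList, path: Path | str) -> Path:
    """Write the sorted similarity list as a diagnostic TSV (a, b, score)."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("a\tb\tscore\n")
        for e in sims.entries:
            fh.write(f"{e.a}\t{e.b}\t{e.score:.6g}\n")
    return path
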