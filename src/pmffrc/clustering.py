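"""Two-level capacity-constrained greedy clustering of FASTQ files.

Files-level: the memory model fixes a cluster count K1, giving a per-cluster
read budget ave = floor(M / K1) where M is the collection's total read count.
Reads-level: clusters are grown greedily from the descending-sorted similarity
list under a "first cluster first priority" rule:

1. Seed a new cluster with the highest-scoring pair whose files are both
   unassigned (a seed pair is never split, even if its combined read total
   already exceeds ave — it is logged as a budget warning instead).
2. While the cluster's read total is below ave, tentatively add the unassigned
   file most similar to any current member (single linkage; ties broken by
   ascending file index). If the tentative total exceeds ave the candidate is
   discarded and the cluster closes immediately — no further candidates are
   tried.
3. Similarity entries of assigned files are dead from then on.
4. When no unassigned pair remains, leftover files become singleton clusters
   in ascending index order.

The result is a partition of the collection; the realized cluster count K
(the reads-level K2) may differ from K1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .similarity import SimilarityList

__all__ = ["GrowthRejection", "ClusterPlan", "average_budget", "two_level_cluster"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthRejection:
    """A growth candidate discarded because it would overflow the budget."""

    cluster: int
    candidate: int
    tentative_total: int


@dataclass(frozen=True)
class ClusterPlan:
    """Output of the two-level clustering: an ordered partition of files."""

    K1: int
    ave: int
    clusters: tuple[tuple[int, ...], ...]
    total_records: int
    rejections: tuple[GrowthRejection, ...] = field(default_factory=tuple)

    @property
    def K(self) -> int:
        return len(self.clusters)

    def cluster_totals(self, counts: Sequence[int]) -> list[int]:
        return [sum(counts[i] for i in cluster) for cluster in self.clusters]


def average_budget(M: int, K1: int) -> int:
    """Per-cluster read budget ave = floor(M / K1)."""
    if K1 < 1:
        raise ValueError(f"K1 must be >= 1, got {K1}")
    if M < 0:
        raise ValueError(f"M must be >= 0, got {M}")
    return M // K1


def two_level_cluster(
    sims: SimilarityList | None,
    counts: Sequence[int],
    K1: int,
) -> ClusterPlan:
    """Greedy budgeted clustering from the sorted similarity list.

    ``counts[i]`` is file i's record count; ``sims`` may be None only for
    collections of fewer than two files.
    """
    v = len(counts)
    M = sum(counts)
    ave = average_budget(M, K1)
    if v == 0:
        return ClusterPlan(K1=K1, ave=ave, clusters=(), total_records=0)
    if v == 1:
        return ClusterPlan(K1=K1, ave=ave, clusters=((0,),), total_records=M)
    if sims is None:
        raise ValueError("similarity list required for v >= 2")
    if sims.v != v:
        raise ValueError(f"similarity list is for v={sims.v}, counts give v={v}")

    # pair score lookup for single-linkage growth
    score: dict[tuple[int, int], float] = {}
    for e in sims.entries:
        score[(e.a, e.b)] = e.score
        score[(e.b, e.a)] = e.score

    unassigned = set(range(v))
    clusters: list[tuple[int, ...]] = []
    rejections: list[GrowthRejection] = []

    while len(unassigned) >= 2:
        seed = next(
            (e for e in sims.entries if e.a in unassigned and e.b in unassigned),
            None,
        )
        if seed is None:  # defensive: full lists always contain such a pair
            break
        members = [seed.b, seed.a]  # ascending index, since a > b
        unassigned -= {seed.a, seed.b}
        total = counts[seed.a] + counts[seed.b]
        if total > ave:
            logger.warning(
                "cluster %d: seed pair (%d, %d) total %d already exceeds budget %d",
                len(clusters), seed.b, seed.a, total, ave,
            )
        closed = False
        while not closed and total < ave and unassigned:
            cand = max(
                unassigned,
                key=lambda f: (max(score[(f, m)] for m in members), -f),
            )
            tentative = total + counts[cand]
            if tentative > ave:
                rejections.append(
                    GrowthRejection(
                        cluster=len(clusters), candidate=cand, tentative_total=tentative
                    )
                )
                closed = True
            else:
                members.append(cand)
                unassigned.discard(cand)
                total = tentative
        clusters.append(tuple(members))

    for leftover in sorted(unassigned):
        clusters.append((leftover,))

    plan = ClusterPlan(
        K1=K1,
        ave=ave,
        clusters=tuple(clusters),
        total_records=M,
        rejections=tuple(rejections),
    )
    assert sorted(i for c in plan.clusters for i in c) == list(range(v))
    return plan
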