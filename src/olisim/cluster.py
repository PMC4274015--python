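"""Threshold clustering of unique sequences (MOTU-style).

Unique sequences within a sample are clustered by single linkage at an exact
global-alignment mismatch cutoff d (1-30): two sequences join the same
cluster whenever a chain of pairs at unit-cost edit distance <= d connects
them, subject to a minimum length-ratio between pair members.  A shared-k-mer
candidate prefilter replaces the original BLAST pass; it carries a pigeonhole
superset guarantee (every pair within distance d that satisfies the length
ratio is examined), so the exact distances decide everything.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from .readprep import UniqueSeqTable, collapse_unique

__all__ = [
    "ClusterParams",
    "ClusterSet",
    "nw_distance",
    "candidate_pairs",
    "cluster_motu",
    "saturation_curve",
]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds.

    max_mismatch: the distance cutoff d (1-30).
    prefilter_identity: sensitivity of the k-mer candidate prefilter; pairs
        more similar than this are guaranteed candidates even when d is small.
    min_len_fraction: pairs whose shorter/longer length ratio falls below this
        are never merged.
    """

    max_mismatch: int = 3
    prefilter_identity: float = 0.97
    min_len_fraction: float = 0.87

    def __post_init__(self) -> None:
        if not 1 <= self.max_mismatch <= 30:
            raise ValueError("max_mismatch must be in [1, 30]")
        if not (0 < self.prefilter_identity <= 1 and 0 < self.min_len_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")


def nw_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance (substitution = 1, each gap base = 1)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return edlib.align(a.upper(), b.upper(), mode="NW", task="distance")["editDistance"]


def _length_ok(a: str, b: str, min_len_fraction: float) -> bool:
    return min(len(a), len(b)) >= min_len_fraction * max(len(a), len(b))


def candidate_pairs(table: UniqueSeqTable, params: ClusterParams) -> list[tuple[int, int]]:
    """Index pairs that could be within distance d, by shared k-mers.

    Pigeonhole: a sequence of length m has m-k+1 k-mers and one edit destroys
    at most k of them, so two sequences within distance d share a k-mer
    whenever (m - k + 1) - d*k >= 1, i.e. k <= (m - d + 1) / (d + 1) with m
    the shorter length.  k is chosen from the smallest length in the table and
    the effective distance implied by d and the prefilter identity; if no
    k >= 3 satisfies the bound, every length-compatible pair is emitted.  The
    result is a superset of all pairs with nw_distance <= d that satisfy the
    length-ratio bound.
    """
    seqs = table.sequences
    n = len(seqs)
    if n < 2:
        return []
    min_len = min(len(s) for s in seqs)
    max_len = max(len(s) for s in seqs)
    d_eff = max(
        params.max_mismatch,
        int(-(-(1.0 - params.prefilter_identity) * max_len // 1)),  # ceil
    )
    k = (min_len - d_eff + 1) // (d_eff + 1)
    if k < 3:
        return [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if _length_ok(seqs[i], seqs[j], params.min_len_fraction)
        ]
    k = min(k, 12)
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, s in enumerate(seqs):
        for kmer in {s[i: i + k] for i in range(len(s) - k + 1)}:
            buckets[kmer].append(idx)
    pairs = set()
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if _length_ok(seqs[i], seqs[j], params.min_len_fraction):
                    pairs.add((i, j))
    return sorted(pairs)


@dataclass
class ClusterSet:
    """Single-linkage partition of a UniqueSeqTable at cutoff d."""

    table: UniqueSeqTable
    labels: list[int]
    d: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def clusters(self) -> list[list[int]]:
        groups: dict[int, list[int]] = defaultdict(list)
        for idx, lab in enumerate(self.labels):
            groups[lab].append(idx)
        return [groups[lab] for lab in sorted(groups)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.table.sequences,
                "cluster_id": self.labels,
                "d": self.d,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_motu(table: UniqueSeqTable, params: ClusterParams) -> ClusterSet:
    """Single-linkage clusters at exact distance <= d.

    Deterministic: cluster labels are 0..n_clusters-1 in order of each
    cluster's first (most abundant) member.
    """
    seqs = table.sequences
    uf = _UnionFind(len(seqs))
    for i, j in candidate_pairs(table, params):
        if nw_distance(seqs[i], seqs[j]) <= params.max_mismatch:
            uf.union(i, j)
    roots: dict[int, int] = {}
    labels = []
    for idx in range(len(seqs)):
        root = uf.find(idx)
        if root not in roots:
            roots[root] = len(roots)
        labels.append(roots[root])
    return ClusterSet(table=table, labels=labels, d=params.max_mismatch)


def saturation_curve(
    reads: list,
    depths: list[int],
    params: ClusterParams,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Cluster counts at increasing random read subsamples.

    For each depth, subsample that many reads without replacement (seeded),
    dereplicate, cluster, and count clusters; used to judge when additional
    reads stop revealing novel sequence clusters.  Depths beyond the read
    total are clamped to it.
    """
    if sorted(depths) != list(depths):
        raise ValueError("depths must be sorted ascending")
    rng = random.Random(seed)
    out = []
    for depth in depths:
        eff = min(depth, len(reads))
        sub = rng.sample(list(reads), eff)
        table = collapse_unique(sub)
        out.append((depth, cluster_motu(table, params).n_clusters))
    return out
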