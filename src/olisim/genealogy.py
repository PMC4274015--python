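"""Ancestor-descendant network reconstruction across sampled transfers.

Each unique sequence in a sampled transfer is assigned a putative ancestor:
the unique sequence in the immediately preceding sampled transfer with the
highest Smith-Waterman local alignment score (affine gaps, ties broken at
random under a seeded RNG).  Stacking these assignments over consecutive
sampled transfers yields a forest rooted at the transfer-1 founders, from
which lineage success (total descendants) and founder diversity (distinct
final-transfer descendants) are read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import networkx as nx
import numpy as np
from Bio import Align

from .readprep import UniqueSeqTable, mismatches

__all__ = [
    "SWParams",
    "sw_score",
    "assign_ancestors",
    "edge_distance",
    "build_genealogy",
    "lineage_success",
    "founder_diversity",
    "export_graph",
    "load_graphml",
]


@dataclass(frozen=True)
class SWParams:
    """Local-alignment scoring: gap of length L costs open + (L-1)*extend."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 20.0
    gap_extend: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    def aligner(self) -> Align.PairwiseAligner:
        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.match_score = self.match
        aln.mismatch_score = self.mismatch
        aln.open_gap_score = -self.gap_open
        aln.extend_gap_score = -self.gap_extend
        return aln


def sw_score(a: str, b: str, params: SWParams | None = None) -> float:
    """Optimal local alignment score with affine gap penalties (>= 0)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or SWParams()
    return float(params.aligner().score(a.upper(), b.upper()))


def edge_distance(child: str, parent: str) -> int:
    """Mismatch distance annotated on genealogy edges.

    Equal lengths: positional Hamming distance.  Unequal lengths (indels are
    common here): mismatch plus gap columns of the optimal unit-cost global
    alignment, i.e. the edit distance.
    """
    a, b = child.upper(), parent.upper()
    if len(a) == len(b):
        return mismatches(a, b)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def assign_ancestors(
    children: UniqueSeqTable,
    parents: UniqueSeqTable,
    params: SWParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, float]]:
    """Map every child to its closest-scoring parent.

    Returns (child_index, parent_index, score) triples, one per child.  Exact
    score ties are resolved uniformly at random; pass a Generator to make the
    tie-breaks reproducible across a multi-transfer build.
    """
    if len(parents) == 0:
        raise ValueError("parent sample is empty")
    params = params or SWParams()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    aligner = params.aligner()
    out = []
    parent_seqs = parents.sequences
    for ci, child in enumerate(children.sequences):
        scores = np.array([aligner.score(child, p) for p in parent_seqs])
        best = scores.max()
        winners = np.flatnonzero(scores == best)
        pick = int(winners[0]) if len(winners) == 1 else int(rng.choice(winners))
        out.append((ci, pick, float(best)))
    return out


def _node_id(transfer: int, seq: str) -> str:
    return f"t{transfer}:{seq}"


def build_genealogy(
    samples: list[UniqueSeqTable],
    transfers: list[int] | None = None,
    params: SWParams | None = None,
) -> nx.DiGraph:
    """Genealogy network over ordered sampled transfers (default 1, 3, 7, 11).

    Ancestors are assigned between each consecutive pair of sampled transfers
    working backwards from the most recent; transfer-1 sequences receive no
    ancestors and act as founders.  Vertices carry (sequence, transfer, count)
    and edges the mismatch distance; each non-founder vertex has exactly one
    parent, so the result is a forest.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 sampled transfers")
    if transfers is None:
        transfers = [1, 3, 7, 11][: len(samples)] if len(samples) <= 4 else list(
            range(1, len(samples) + 1)
        )
    params = params or SWParams()
    rng = np.random.default_rng(params.rng_seed)
    g = nx.DiGraph()
    for t, sample in zip(transfers, samples):
        for seq, count in sample:
            g.add_node(_node_id(t, seq), sequence=seq, transfer=int(t), count=int(count))
    for later in range(len(samples) - 1, 0, -1):
        children, parents = samples[later], samples[later - 1]
        tc, tp = transfers[later], transfers[later - 1]
        for ci, pi, _score in assign_ancestors(children, parents, params, rng):
            child_seq = children.sequences[ci]
            parent_seq = parents.sequences[pi]
            g.add_edge(
                _node_id(tp, parent_seq),
                _node_id(tc, child_seq),
                distance=int(edge_distance(child_seq, parent_seq)),
            )
    return g


def _resolve_founder(g: nx.DiGraph, founder) -> str:
    if founder in g:
        return founder
    candidates = [n for n, d in g.nodes(data=True) if d.get("sequence") == founder]
    if not candidates:
        raise KeyError(f"unknown founder: {founder!r}")
    first_transfer = min(g.nodes[n]["transfer"] for n in g)
    roots = [n for n in candidates if g.nodes[n]["transfer"] == first_transfer]
    if not roots:
        raise KeyError(f"{founder!r} is not a first-transfer vertex")
    return roots[0]


def lineage_success(g: nx.DiGraph, founder) -> int:
    """Total number of distinct descendants of a founder (excluding itself)."""
    return len(nx.descendants(g, _resolve_founder(g, founder)))


def founder_diversity(g: nx.DiGraph, founder, final_transfer: int) -> int:
    """Distinct final-transfer unique sequences descending from a founder."""
    node = _resolve_founder(g, founder)
    return sum(
        1
        for n in nx.descendants(g, node)
        if g.nodes[n]["transfer"] == final_transfer
    )


def export_graph(g: nx.DiGraph, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as GraphML (Cytoscape-ready), SIF, or a TSV edge list."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{u}\tancestor_of\t{v}\n")
            for n in nx.isolates(g):
                fh.write(f"{n}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("parent\tchild\tdistance\n")
            for u, v, d in g.edges(data="distance"):
                fh.write(f"{u}\t{v}\t{d}\n")
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def load_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)
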