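"""Read-level preprocessing for fold-or-hold amplicon sequencing.

Covers the pipeline stages applied to raw reads before clustering and network
inference: primer filtering, exact dereplication with reverse-complement
merging, in-silico restriction trimming, and the exhaustive digestion-escape
checker.

Coordinates are 0-based and half-open throughout; restriction cut positions
are between-base indices on the top strand.
"""

from __future__ import annotations

import itertools
from collections import Counter
from functools import lru_cache
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .hairpin import reverse_complement
from .io import ancestor_sequence, primer_sequences

__all__ = [
    "PrimerPair",
    "RestrictionEnzyme",
    "UniqueSeqTable",
    "BSAI",
    "HPYAV",
    "DEFAULT_ENZYMES",
    "default_primers",
    "mismatches",
    "filter_by_primers",
    "collapse_unique",
    "find_restriction_cuts",
    "digest_trim",
    "extended_amplicon",
    "escape_possible_with_k",
]


@dataclass(frozen=True)
class PrimerPair:
    """The two qPCR primers flanking an amplicon.

    An amplicon carries the forward primer verbatim at one 5' end and the
    reverse complement of the other primer at its 3' end (or the same on the
    opposite orientation), because primers are incorporated into every
    amplified strand.
    """

    fwd: str
    rev: str
    max_mm: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd", self.fwd.upper())
        object.__setattr__(self, "rev", self.rev.upper())


def default_primers(max_mm: int = 0) -> PrimerPair:
    fwd, rev = primer_sequences()
    return PrimerPair(fwd=fwd, rev=rev, max_mm=max_mm)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Type IIS enzyme cutting downstream of its recognition sequence.

    ``cut_top`` / ``cut_bottom`` are the number of bases between the 3' end of
    the recognition sequence and the cut on the recognition strand / the
    opposite strand, NEB (top/bottom) notation.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    @property
    def recognition_rc(self) -> str:
        return _cached_rc(self.recognition)


@lru_cache(maxsize=64)
def _cached_rc(seq: str) -> str:
    return reverse_complement(seq)


BSAI = RestrictionEnzyme("BsaI", "GGTCTC", 1, 5)
HPYAV = RestrictionEnzyme("HpyAV", "CCTTC", 6, 5)
DEFAULT_ENZYMES: tuple[RestrictionEnzyme, ...] = (BSAI, HPYAV)


def mismatches(a: str, b: str) -> int:
    """Positional mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("mismatch count requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _seq_of(read) -> str:
    return (read if isinstance(read, str) else str(read.seq)).upper()


def _has_footprints(seq: str, primers: PrimerPair, max_mm: int) -> bool:
    fwd, rev_rc = primers.fwd, reverse_complement(primers.rev)
    if len(seq) < len(fwd) + len(rev_rc):
        return False
    return (
        mismatches(seq[: len(fwd)], fwd) <= max_mm
        and mismatches(seq[-len(rev_rc):], rev_rc) <= max_mm
    )


def filter_by_primers(reads: Iterable, primers: PrimerPair | None = None) -> list:
    """Keep reads whose two ends carry both primer footprints.

    A read passes if, in either orientation, the forward primer matches its
    prefix and the reverse complement of the reverse primer matches its
    suffix, each within ``primers.max_mm`` mismatches.  The default is exact
    matching, the analysis pipeline's only quality gate.
    """
    primers = primers or default_primers()
    kept = []
    for read in reads:
        s = _seq_of(read)
        if _has_footprints(s, primers, primers.max_mm) or _has_footprints(
            reverse_complement(s), primers, primers.max_mm
        ):
            kept.append(read)
    return kept


@dataclass
class UniqueSeqTable:
    """Dereplicated sequences with abundances for one (treatment, transfer) sample."""

    entries: list[tuple[str, int]] = field(default_factory=list)
    sample_id: tuple | None = None

    def __post_init__(self) -> None:
        if any(c < 1 for _, c in self.entries):
            raise ValueError("counts must be >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.entries)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["sequence", "count"])
        df["sample"] = "" if self.sample_id is None else "|".join(map(str, self.sample_id))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UniqueSeqTable":
        df = pd.read_csv(path, sep="\t")
        sample = None
        if "sample" in df.columns and len(df) and str(df["sample"].iloc[0]):
            sample = tuple(str(df["sample"].iloc[0]).split("|"))
        return cls(
            entries=list(zip(df["sequence"].astype(str), df["count"].astype(int))),
            sample_id=sample,
        )


def canonical(seq: str) -> str:
    """Orientation-free representative: lexicographic min of seq and revcomp."""
    s = seq.upper()
    return min(s, reverse_complement(s))


def collapse_unique(reads: Iterable, sample_id: tuple | None = None) -> UniqueSeqTable:
    """Dereplicate reads, merging exact matches and reverse complements.

    Entries are ordered by descending count, ties lexicographically, as the
    pipeline orders "the most abundant within each sample".
    """
    counts: Counter[str] = Counter(canonical(_seq_of(r)) for r in reads)
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return UniqueSeqTable(entries=entries, sample_id=sample_id)


def find_restriction_cuts(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut coordinates implied by recognition sites on either strand.

    For a recognition site read on the top strand at start i, the cut falls
    ``len(recognition) + cut_top`` bases downstream.  For a site read on the
    bottom strand (the recognition's reverse complement at top-strand start j),
    downstream on the bottom strand points left on the top strand, so the cut
    falls ``cut_top`` bases before j.  Coordinates outside [0, len] (the
    implied cut would fall off the molecule) are dropped; the result is sorted
    and deduplicated.
    """
    s = seq.upper()
    n = len(s)
    rec = enzyme.recognition.upper()
    rec_rc = enzyme.recognition_rc
    cuts = set()
    start = s.find(rec)
    while start >= 0:
        c = start + len(rec) + enzyme.cut_top
        if 0 <= c <= n:
            cuts.add(c)
        start = s.find(rec, start + 1)
    start = s.find(rec_rc)
    while start >= 0:
        c = start - enzyme.cut_top
        if 0 <= c <= n:
            cuts.add(c)
        start = s.find(rec_rc, start + 1)
    return sorted(cuts)


def digest_trim(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    mode: str = "three_prime",
) -> str:
    """In-silico digestion of a read.

    three_prime (default): apply the 3'-most cut among all enzymes' cut
    coordinates that fall in the 3' half of the molecule and drop the 3'
    fragment — the digestion step's purpose is cleaving the self-primed
    extension.  all_cuts_keep_longest: cut at every coordinate on both strands
    and keep the longest fragment (this also honours the bottom-strand site
    near the 5' end of the founding molecule).  A sequence without sites is
    returned unchanged.
    """
    s = seq.upper()
    n = len(s)
    cuts = sorted({c for enz in enzymes for c in find_restriction_cuts(s, enz)})
    if not cuts:
        return s
    if mode == "three_prime":
        three_prime_cuts = [c for c in cuts if 2 * c >= n]
        if not three_prime_cuts:
            return s
        return s[: max(three_prime_cuts)]
    if mode == "all_cuts_keep_longest":
        bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
        frags = [s[a:b] for a, b in zip(bounds, bounds[1:])]
        return max(frags, key=len)
    raise ValueError(f"unknown digestion mode: {mode!r}")


def extended_amplicon() -> str:
    """The ancestral PCR amplicon after primer incorporation.

    Amplified copies of the extended founding molecule carry the reverse
    primer verbatim at the 5' end and the reverse complement of the forward
    primer at the 3' end.  The reverse primer's two designed substitutions
    remove the internal bottom-strand BsaI site, leaving the two restriction
    sites at the extended 3' end as the molecule's only cleavable sites.
    """
    fwd, rev = primer_sequences()
    anc = ancestor_sequence()
    core = anc[len(rev): len(anc) - (len(fwd) - 8)]
    return rev + core + reverse_complement(fwd)


def escape_possible_with_k(
    seq_extended: str,
    k: int,
    primers: PrimerPair | None = None,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    max_primer_mm: int = 1,
) -> bool:
    """Can <= k point substitutions evade digestion yet keep primer binding?

    Exhaustively enumerates every set of at most ``k`` substitutions of
    ``seq_extended`` and returns True iff some mutant has no remaining cut
    site in its 3' half (so three-prime digestion leaves it intact) while both
    primer footprints still match within ``max_primer_mm`` mismatches each.
    The restriction sites sit inside the forward-primer footprint by design,
    which is what makes escape expensive.
    """
    if k > 2:
        raise ValueError("exhaustive enumeration supports k <= 2")
    primers = primers or default_primers()
    s = seq_extended.upper()
    bases = "ACGT"

    def escapes(mut: str) -> bool:
        if digest_trim(mut, enzymes, mode="three_prime") != mut:
            return False
        return _has_footprints(mut, primers, max_primer_mm) or _has_footprints(
            reverse_complement(mut), primers, max_primer_mm
        )

    for n_mut in range(k + 1):
        for positions in itertools.combinations(range(len(s)), n_mut):
            alternatives = [[b for b in bases if b != s[p]] for p in positions]
            for combo in itertools.product(*alternatives):
                mut = list(s)
                for p, b in zip(positions, combo):
                    mut[p] = b
                if escapes("".join(mut)):
                    return True
    return False
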