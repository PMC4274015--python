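"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive O(n*m) dynamic programs and exhaustive searches,
kept free of any imports from the package's alignment/clustering code paths.
"""

from __future__ import annotations

NEG = float("-inf")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def nw_unit_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance by full DP."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def sw_affine_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 20.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith-Waterman with affine gaps (length-L gap costs open + (L-1)*extend).

    Gotoh three-state DP, local (scores floored at zero, best cell wins).
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            M[i][j] = max(0.0, diag)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def best_stem(seq: str, min_stem: int):
    """Exhaustive search for the longest suffix/internal-complement duplex.

    Returns (length, partner_start, partner_end, suffix_start, suffix_end),
    1-based inclusive, or None; ties at a given length favour the 5'-most
    partner.
    """
    n = len(seq)
    found = None
    for length in range(min_stem, n // 2 + 1):
        suffix = seq[n - length:]
        target = revcomp(suffix)
        for start in range(0, n - 2 * length + 1):
            if seq[start: start + length] == target:
                found = (length, start + 1, start + length, n - length + 1, n)
                break
    return found


def single_linkage_clusters(seqs: list[str], d: int, min_len_fraction: float) -> list[set[int]]:
    """All-pairs single-linkage partition at edit distance <= d."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            if min(len(a), len(b)) < min_len_fraction * max(len(a), len(b)):
                continue
            if nw_unit_distance(a, b) <= d:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)
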