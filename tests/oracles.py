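"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package's algorithms: a quadratic
three-matrix Smith-Waterman, an all-pairs single-linkage clusterer and an
interval-graph call merger, each written in the most literal way possible.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score_bruteforce(a: str, b: str, match: int = 1, mismatch: int = -1,
                        gap_open: int = -2, gap_extend: int = -1) -> float:
    """Affine-gap local alignment score; a length-k gap costs
    |gap_open| + (k-1)*|gap_extend| (the opening position includes the
    first gapped residue)."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            M[i][j] = max(0.0,
                          s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def single_linkage_bruteforce(positions: list[int], window: int) -> list[list[int]]:
    """All-pairs single-linkage clustering of 1-D positions: repeatedly merge
    any two clusters containing points within ``window`` of each other."""
    clusters = [[p] for p in sorted(positions)]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(abs(p - q) <= window
                       for p in clusters[i] for q in clusters[j]):
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(clusters)


def merge_chains_bruteforce(positions: list[int], window: int) -> list[list[int]]:
    """Connected components of the interval graph linking calls <= window
    apart (transitively), as sorted position lists."""
    return single_linkage_bruteforce(positions, window)
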