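"""Independent oracles used by the test suite.

These deliberately avoid the package's greedy/vectorized code paths:
maximum non-overlapping hit sets are found by exhaustive branch-and-bound
over all subsets, IUPAC matching by per-position set expansion, and
hypergeometric tails by enumerating every draw from the universe.
"""

from functools import lru_cache
from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_matches(pattern: str, seq: str) -> list[int]:
    """Start positions where the pattern matches, by per-position set check."""
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        ok = True
        for p, s in zip(pattern, seq[i : i + k]):
            if not set(IUPAC[s]) <= set(IUPAC[p]):
                ok = False
                break
        if ok:
            out.append(i)
    return out


def max_nonoverlapping_subset(intervals: list[tuple[int, int]]) -> int:
    """Size of the largest mutually non-overlapping subset, exhaustively."""
    ivs = tuple(sorted(set(intervals)))

    @lru_cache(maxsize=None)
    def best(i: int, cursor: int) -> int:
        if i == len(ivs):
            return 0
        skip = best(i + 1, cursor)
        s, e = ivs[i]
        take = 0
        if s >= cursor:
            take = 1 + best(i + 1, e)
        return max(skip, take)

    return best(0, -1)


def joint_count_oracle(seq: str, patterns: tuple[str, ...] = ("GAGA", "TCTC")) -> int:
    """Maximum non-overlapping joint count on the sense strand, exhaustively."""
    ivs = []
    for pat in patterns:
        for s in naive_matches(pat, seq):
            ivs.append((s, s + len(pat)))
    return max_nonoverlapping_subset(ivs)


def hypergeom_enumeration(N: int, n1: int, n2: int) -> dict[int, float]:
    """Exact overlap-size distribution by enumerating all C(N, n2) draws."""
    universe = range(N)
    marked = set(range(n1))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(universe, n2):
        k = len(marked & set(draw))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: c / total for k, c in counts.items()}
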