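"""Venn partitioning and hypergeometric overlap tests for gene lists.

Gene sets live inside a finite named universe (e.g. the genes present on
one microarray platform).  Overlaps between two sets of sizes n1 and n2
drawn from a universe of size N are tested against the hypergeometric
distribution: the over-representation p-value is P(X >= k) and the
under-representation p-value is P(X <= k), both including the observed
overlap k.  No multiple-testing correction is applied by default; a
Bonferroni helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from scipy import stats

from .errors import ContractError, DomainError


@dataclass(frozen=True)
class GeneSet:
    """A named identifier set over a shared finite universe."""

    name: str
    members: frozenset
    universe: frozenset
    n_duplicates: int = 0

    def __post_init__(self):
        extra = self.members - self.universe
        if extra:
            raise ContractError(
                f"set {self.name!r} has {len(extra)} member(s) outside the universe, "
                f"e.g. {sorted(extra)[:3]}"
            )

    def __len__(self):
        return len(self.members)

    @classmethod
    def from_iterable(cls, name: str, ids: Iterable[str], universe: Iterable[str]) -> "GeneSet":
        """Build a set, collapsing duplicates and recording how many there were."""
        ids = list(ids)
        members = frozenset(ids)
        return cls(
            name=name,
            members=members,
            universe=frozenset(universe),
            n_duplicates=len(ids) - len(members),
        )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def venn_partition(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Exact counts for all 2^n - 1 exclusive Venn regions of 2-4 sets.

    Region keys name the sets a member belongs to, joined with a capital
    intersection sign: for sets A, B, C the key ``"A∩B"`` counts members in
    A and B but *not* C.
    """
    if not 2 <= len(sets) <= 4:
        raise ContractError("venn_partition takes 2-4 sets")
    universes = {s.universe for s in sets}
    if len(universes) != 1:
        raise ContractError("all sets must share one universe")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ContractError("set names must be unique")
    out: dict[str, int] = {}
    union = frozenset().union(*(s.members for s in sets))
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = set.intersection(*(set(sets[i].members) for i in combo))
            for i in range(len(sets)):
                if i not in combo:
                    inside -= sets[i].members
            out["∩".join(names[i] for i in combo)] = len(inside)
    assert sum(out.values()) == len(union)
    return out


def hypergeom_overlap(k: int, n1: int, n2: int, N: int, tail: str = "over") -> float:
    """Hypergeometric tail probability of an overlap of size k.

    X ~ Hypergeometric(N, n1, n2): the overlap size when n2 items are drawn
    without replacement from a universe of N containing n1 marked items.
    ``tail="over"`` gives P(X >= k); ``tail="under"`` gives P(X <= k).
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise DomainError(f"set sizes must satisfy 0 <= n1,n2 <= N (got {n1},{n2},{N})")
    lo, hi = max(0, n1 + n2 - N), min(n1, n2)
    if not lo <= k <= hi:
        raise DomainError(
            f"overlap k={k} outside the hypergeometric support [{lo},{hi}] "
            f"for n1={n1}, n2={n2}, N={N}"
        )
    dist = stats.hypergeom(M=N, n=n1, N=n2)
    if tail == "over":
        return float(dist.sf(k - 1))
    if tail == "under":
        return float(dist.cdf(k))
    raise ContractError(f"tail must be 'over' or 'under', got {tail!r}")


@dataclass(frozen=True)
class OverlapResult:
    set_names: tuple[str, str]
    partition_counts: dict
    k: int
    p_over: float
    p_under: float
    direction_call: str  # enriched / depleted / neither


def overlap_test(a: GeneSet, b: GeneSet, alpha: float = 0.05) -> OverlapResult:
    """Both hypergeometric tails for the overlap of two sets, plus a call."""
    if a.universe != b.universe:
        raise ContractError("sets must share one universe")
    k = len(a.members & b.members)
    N = len(a.universe)
    p_over = hypergeom_overlap(k, len(a), len(b), N, tail="over")
    p_under = hypergeom_overlap(k, len(a), len(b), N, tail="under")
    if p_over < alpha and p_over < p_under:
        call = "enriched"
    elif p_under < alpha and p_under < p_over:
        call = "depleted"
    else:
        call = "neither"
    return OverlapResult(
        set_names=(a.name, b.name),
        partition_counts=venn_partition([a, b]),
        k=k,
        p_over=p_over,
        p_under=p_under,
        direction_call=call,
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Optional Bonferroni adjustment (the analysis applies none by default)."""
    m = len(p_values) if m is None else m
    return [min(1.0, p * m) for p in p_values]
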