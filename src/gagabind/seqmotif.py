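"""Degenerate nucleotide pattern matching and non-overlapping motif counting.

This module is the computational core of the package.  It scans DNA
sequences for IUPAC-degenerate motifs (e.g. the GAGA/TCTC tetranucleotide
recognized by plant BBR/BPC GAGA-binding factors, or the degenerate
nonanucleotide consensus RGARAGRRA from earlier literature) and counts the
maximum number of mutually non-overlapping occurrences.

Conventions
-----------
* Coordinates are 0-based, half-open, and always reported on the sense
  strand, matching the bedGraph/BED convention used elsewhere in the
  package.
* The joint GAGA/TCTC class is counted on the sense strand only: a TCTC on
  the sense strand *is* a GAGA on the antisense strand, so sense-strand
  joint counting is equivalent to both-strand GAGA counting with
  cross-strand overlap resolution.  This equivalence is asserted by the
  strand-symmetry property test.
* RGARAGRRA is counted non-overlapping on each strand independently and
  summed (``per_strand=True``).
* Non-overlapping counting uses greedy earliest-end selection over the
  merged, start-sorted hit list.  For hits of equal length this greedy rule
  is provably maximal (classic interval scheduling).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .errors import AlphabetError, ContractError

# IUPAC one-letter ambiguity codes and their expansions.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: default alphabet accepted in input sequences (ambiguity codes other
#: than N require explicit opt-in).
DEFAULT_SEQ_ALPHABET = frozenset("ACGTN")
FULL_IUPAC_ALPHABET = frozenset(IUPAC_EXPANSION)

STRAND_PLUS = "+"
STRAND_MINUS = "-"
_STRANDS = (STRAND_PLUS, STRAND_MINUS)


def _validate(seq: str, alphabet: frozenset, what: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - alphabet)
    if bad:
        raise AlphabetError(
            f"{what} contains characters outside the accepted alphabet: "
            f"{', '.join(repr(c) for c in bad)}"
        )
    return seq


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the IUPAC alphabet.

    Upper-cased on ingestion; by default only A, C, G, T and N are accepted
    (pass ``allow_ambiguity=True`` to accept all IUPAC codes).  Empty
    sequences are legal and match nothing.
    """

    id: str
    seq: str

    def __init__(self, id: str, seq: str, allow_ambiguity: bool = False):
        alphabet = FULL_IUPAC_ALPHABET if allow_ambiguity else DEFAULT_SEQ_ALPHABET
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "seq", _validate(seq, alphabet, f"sequence {id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


SequenceLike = Union[str, NucleotideSequence]


def as_sequence(seq: SequenceLike, id: str = "") -> NucleotideSequence:
    """Coerce a plain string to a :class:`NucleotideSequence`."""
    if isinstance(seq, NucleotideSequence):
        return seq
    return NucleotideSequence(id=id, seq=seq)


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC-degenerate motif (R -> {A,G}, Y -> {C,T}, N -> any...)."""

    name: str
    pattern: str

    def __init__(self, name: str, pattern: str):
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self, "pattern", _validate(pattern, FULL_IUPAC_ALPHABET, f"pattern {name!r}")
        )
        if not self.pattern:
            raise ContractError(f"pattern {name!r} is empty")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One match of a pattern, in sense-strand half-open coordinates.

    ``matched_text`` is always the sense-strand text; for a minus-strand
    hit its reverse complement matches the pattern.
    """

    seq_id: str
    pattern_name: str
    strand: str
    start: int
    end: int
    matched_text: str


# The minimal BBR/BPC binding element and the older degenerate consensus.
GAGA = MotifPattern("GAGA", "GAGA")
TCTC = MotifPattern("TCTC", "TCTC")
RGARAGRRA = MotifPattern("RGARAGRRA", "RGARAGRRA")
GAGA_TCTC = (GAGA, TCTC)


def reverse_complement(seq: SequenceLike) -> SequenceLike:
    """Watson-Crick reverse complement; IUPAC codes map to their complements."""
    if isinstance(seq, NucleotideSequence):
        rc = seq.seq.translate(_COMPLEMENT)[::-1]
        obj = object.__new__(NucleotideSequence)
        object.__setattr__(obj, "id", seq.id)
        object.__setattr__(obj, "seq", rc)
        return obj
    s = _validate(seq, FULL_IUPAC_ALPHABET, "sequence")
    return s.translate(_COMPLEMENT)[::-1]


def _char_class(code: str) -> str:
    """Regex character class of sequence letters compatible with a pattern code.

    A sequence letter matches a pattern code iff its expansion is a subset
    of the code's expansion; hence N in a sequence matches only pattern N,
    while pattern N matches every letter.
    """
    allowed = set(IUPAC_EXPANSION[code])
    letters = [c for c, exp in IUPAC_EXPANSION.items() if set(exp) <= allowed]
    return "[" + "".join(sorted(letters)) + "]"


def _compile(pattern_text: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(_char_class(c) for c in pattern_text) + "))")


def iupac_match(
    pattern: MotifPattern,
    seq: SequenceLike,
    strands: Sequence[str] = _STRANDS,
) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``pattern`` on the requested strands.

    Returns hits in ascending sense-strand start order, ties broken ``+``
    before ``-``.  Minus-strand matching is performed by scanning the sense
    strand with the reverse-complemented pattern, so coordinates never
    leave the sense strand.
    """
    bad = set(strands) - set(_STRANDS)
    if bad:
        raise ContractError(f"unknown strand(s): {sorted(bad)}")
    record = as_sequence(seq)
    hits: list[MotifHit] = []
    k = len(pattern)
    for strand in _STRANDS:
        if strand not in strands:
            continue
        text = pattern.pattern if strand == STRAND_PLUS else pattern.pattern.translate(_COMPLEMENT)[::-1]
        rx = _compile(text)
        for m in rx.finditer(record.seq):
            s = m.start()
            hits.append(
                MotifHit(
                    seq_id=record.id,
                    pattern_name=pattern.name,
                    strand=strand,
                    start=s,
                    end=s + k,
                    matched_text=record.seq[s : s + k],
                )
            )
    hits.sort(key=lambda h: (h.start, 0 if h.strand == STRAND_PLUS else 1))
    return hits


def _as_patterns(motif_class) -> tuple[MotifPattern, ...]:
    if isinstance(motif_class, MotifPattern):
        return (motif_class,)
    patterns = tuple(motif_class)
    if not patterns:
        raise ContractError("empty motif class")
    return patterns


def _greedy_max_nonoverlap(intervals: list[tuple[int, int]]) -> int:
    """Maximum mutually non-overlapping subset via earliest-end greedy."""
    count = 0
    cursor = -1
    for start, end in sorted(intervals, key=lambda iv: (iv[1], iv[0])):
        if start >= cursor:
            count += 1
            cursor = end
    return count


def count_nonoverlapping(
    seq: SequenceLike,
    motif_class,
    strands: Sequence[str] = (STRAND_PLUS,),
    per_strand: bool = False,
) -> int:
    """Maximum number of mutually non-overlapping hits of a motif class.

    All patterns in the class must share one length (this is what makes the
    greedy earliest-end rule provably maximal).  With ``per_strand=False``
    (default) hits from all requested strands compete for the same
    sense-strand positions; with ``per_strand=True`` each strand is counted
    independently and the counts are summed (the convention used for the
    degenerate RGARAGRRA consensus).
    """
    patterns = _as_patterns(motif_class)
    lengths = {len(p) for p in patterns}
    if len(lengths) > 1:
        raise ContractError(
            "joint counting is undefined for patterns of unequal length: "
            + ", ".join(f"{p.name}({len(p)})" for p in patterns)
        )
    record = as_sequence(seq)
    if per_strand:
        total = 0
        for strand in strands:
            ivs = [
                (h.start, h.end)
                for p in patterns
                for h in iupac_match(p, record, strands=(strand,))
            ]
            total += _greedy_max_nonoverlap(ivs)
        return total
    ivs = [
        (h.start, h.end)
        for p in patterns
        for h in iupac_match(p, record, strands=strands)
    ]
    return _greedy_max_nonoverlap(ivs)


def count_joint_gaga_tctc(seq: SequenceLike) -> int:
    """Non-overlapping joint GAGA/TCTC count on the sense strand."""
    return count_nonoverlapping(seq, GAGA_TCTC, strands=(STRAND_PLUS,))


def count_rgaragrra(seq: SequenceLike) -> int:
    """Non-overlapping RGARAGRRA count, per strand, summed over both strands."""
    return count_nonoverlapping(seq, RGARAGRRA, strands=_STRANDS, per_strand=True)


#: registry of named motif classes used by probe annotation and the CLI
MOTIF_CLASSES = {
    "gaga-tctc": count_joint_gaga_tctc,
    "gaga": lambda s: count_nonoverlapping(s, GAGA, strands=(STRAND_PLUS,)),
    "rgaragrra": count_rgaragrra,
}


@dataclass(frozen=True)
class GaTcRepeat:
    """A maximal (GA)_n or (TC)_n dinucleotide run, half-open sense coordinates."""

    start: int
    end: int
    units: int
    unit: str  # "GA" or "TC"


def find_ga_tc_repeats(seq: SequenceLike, min_units: int = 2) -> list[GaTcRepeat]:
    """Maximal GA or TC dinucleotide runs with at least ``min_units`` units.

    Runs are phase-locked (no mixed-phase merging): a run extends in steps
    of two from its first unit.
    """
    if min_units < 2:
        raise ContractError("min_units must be >= 2")
    s = as_sequence(seq).seq
    out: list[GaTcRepeat] = []
    for unit in ("GA", "TC"):
        i = 0
        n = len(s)
        while i + 1 < n:
            if s[i : i + 2] == unit:
                j = i + 2
                while s[j : j + 2] == unit:
                    j += 2
                units = (j - i) // 2
                if units >= min_units:
                    out.append(GaTcRepeat(start=i, end=j, units=units, unit=unit))
                i = j
            else:
                i += 1
    out.sort(key=lambda r: (r.start, r.unit))
    return out
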