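"""Subgroup consensus derivation from grouped protein alignments.

Given a multiple protein alignment whose rows are labelled with subgroup
names, derive per-group consensus rows marking invariant residues, find
columns invariant across every group (candidate DNA-contacting residues of
a conserved domain), and detect single-sequence insertion columns — e.g. a
lone extra histidine carried by exactly one family member while all other
rows are gapped.

Invariance rule (strict): a column is invariant within a group iff every
member carries the identical residue and none is gapped.  Conservative
substitutions (e.g. R/K) are reported separately as "class-conserved"
columns using fixed residue classes, never merged into invariants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import AlignIO

from .errors import ContractError, FormatError

GAP = "-"
VARIABLE = "x"

#: fixed conservative-substitution classes
RESIDUE_CLASSES = ("KR", "DE", "ILVM", "FYW", "ST", "NQ")


@dataclass
class GroupedAlignment:
    """Equal-length aligned rows with one group label per sequence."""

    ids: list[str]
    rows: list[str]
    groups: list[str]

    def __post_init__(self):
        if not (len(self.ids) == len(self.rows) == len(self.groups)):
            raise ContractError("ids, rows and groups must be parallel")
        if not self.rows:
            raise ContractError("alignment is empty")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if any(not g for g in self.groups):
            raise ContractError("group labels must be non-empty")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def group_labels(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    @classmethod
    def from_files(cls, aln_fasta, groups_tsv) -> "GroupedAlignment":
        """Aligned FASTA plus a two-column (id, group) TSV table."""
        aln = AlignIO.read(aln_fasta, "fasta")
        table = pd.read_csv(groups_tsv, sep="\t")
        if not {"id", "group"} <= set(table.columns):
            raise FormatError("group table needs 'id' and 'group' columns")
        mapping = dict(zip(table["id"].astype(str), table["group"].astype(str)))
        ids, rows, groups = [], [], []
        for rec in aln:
            if rec.id not in mapping:
                raise ContractError(f"sequence {rec.id!r} has no group label")
            ids.append(rec.id)
            rows.append(str(rec.seq))
            groups.append(mapping[rec.id])
        return cls(ids=ids, rows=rows, groups=groups)


@dataclass(frozen=True)
class ConsensusRow:
    """Per-group consensus: invariant residue, 'x' variable, '-' all-gap."""

    group_label: str
    consensus: str
    invariant_mask: tuple[bool, ...]


def group_consensus(aln: GroupedAlignment) -> list[ConsensusRow]:
    """One consensus row per group, in order of first appearance."""
    out = []
    for label in aln.group_labels():
        members = [r for r, g in zip(aln.rows, aln.groups) if g == label]
        chars = []
        mask = []
        for col in range(aln.length):
            column = [m[col] for m in members]
            if all(c == GAP for c in column):
                chars.append(GAP)
                mask.append(False)
            elif GAP not in column and len(set(column)) == 1:
                chars.append(column[0])
                mask.append(True)
            else:
                chars.append(VARIABLE)
                mask.append(False)
        out.append(
            ConsensusRow(
                group_label=label, consensus="".join(chars), invariant_mask=tuple(mask)
            )
        )
    return out


@dataclass(frozen=True)
class CrossGroupReport:
    """Columns invariant in every group: identical residue vs same residue class."""

    invariant_columns: dict  # column -> residue (identical across groups)
    class_conserved_columns: dict  # column -> residue class string


def cross_group_invariants(rows: Sequence[ConsensusRow]) -> CrossGroupReport:
    """Columns invariant in all groups with one residue; near-misses by class."""
    if len(rows) < 2:
        raise ContractError("need >= 2 group consensus rows")
    lengths = {len(r.consensus) for r in rows}
    if len(lengths) != 1:
        raise ContractError("consensus rows have unequal lengths")
    invariant: dict[int, str] = {}
    by_class: dict[int, str] = {}
    for col in range(lengths.pop()):
        if not all(r.invariant_mask[col] for r in rows):
            continue
        residues = {r.consensus[col] for r in rows}
        if len(residues) == 1:
            invariant[col] = residues.pop()
        else:
            for cls in RESIDUE_CLASSES:
                if residues <= set(cls):
                    by_class[col] = cls
                    break
    return CrossGroupReport(invariant_columns=invariant, class_conserved_columns=by_class)


def find_single_sequence_insertions(aln: GroupedAlignment) -> list[tuple[int, str]]:
    """Columns where exactly one sequence has a residue and all others are gapped."""
    if len(aln.rows) < 3:
        raise ContractError("need >= 3 sequences to call single-sequence insertions")
    out = []
    for col in range(aln.length):
        carriers = [i for i, r in enumerate(aln.rows) if r[col] != GAP]
        if len(carriers) == 1:
            out.append((col, aln.ids[carriers[0]]))
    return out
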