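"""Probe panels and mutation (titration) series design.

A probe is a named double-stranded oligonucleotide represented by its
biotinylated sense strand.  Panels are annotated with non-overlapping motif
counts per motif class; titration series derive mutant probes whose joint
GAGA/TCTC count steps down a prescribed ladder (mirroring series like
3x -> 2x -> 1x -> 0x GAGA) using as few substitutions as possible while
never creating occurrences of forbidden side-effect patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InfeasibleDesignError
from .seqmotif import (
    MOTIF_CLASSES,
    MotifPattern,
    NucleotideSequence,
    as_sequence,
    count_nonoverlapping,
    iupac_match,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class Probe:
    """A double-stranded oligonucleotide probe, stored as its sense strand."""

    name: str
    sense_seq: NucleotideSequence
    biotinylated: bool = True
    description: str = ""

    def __post_init__(self):
        if len(self.sense_seq) == 0:
            raise ContractError(f"probe {self.name!r} has an empty sequence")


def make_probe(name: str, seq: str, **kwargs) -> Probe:
    return Probe(name=name, sense_seq=as_sequence(seq, id=name), **kwargs)


@dataclass
class ProbePanel:
    """An ordered probe collection plus its motif-count annotation table."""

    probes: list[Probe]
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise ContractError("probe names must be unique within a panel")

    def __iter__(self):
        return iter(self.probes)

    def __len__(self):
        return len(self.probes)

    def get(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(name)


def _class_counter(motif_class) -> tuple[str, Callable]:
    """Resolve a motif class given as registry name, pattern, or pattern tuple."""
    if isinstance(motif_class, str):
        if motif_class not in MOTIF_CLASSES:
            raise ContractError(
                f"unknown motif class {motif_class!r}; known: {sorted(MOTIF_CLASSES)}"
            )
        return motif_class, MOTIF_CLASSES[motif_class]
    if isinstance(motif_class, MotifPattern):
        return motif_class.name, lambda s: count_nonoverlapping(s, motif_class)
    patterns = tuple(motif_class)
    name = "/".join(p.name for p in patterns)
    return name, lambda s: count_nonoverlapping(s, patterns)


def annotate_panel(panel: ProbePanel, classes: Sequence) -> ProbePanel:
    """Return the panel with a (probe x motif class) non-overlapping count table."""
    if len(panel) == 0:
        raise ContractError("cannot annotate an empty panel")
    rows = []
    for probe in panel:
        for cls in classes:
            cls_name, counter = _class_counter(cls)
            rows.append(
                {
                    "seq_id": probe.name,
                    "motif_class": cls_name,
                    "count": counter(probe.sense_seq),
                }
            )
    table = pd.DataFrame(rows, columns=["seq_id", "motif_class", "count"])
    return ProbePanel(probes=list(panel.probes), annotations=table)


def panel_counts(panel: ProbePanel, motif_class: str) -> dict[str, int]:
    """Counts of one motif class as a probe-name -> count mapping."""
    if panel.annotations is None:
        raise ContractError("panel is not annotated")
    sub = panel.annotations[panel.annotations["motif_class"] == motif_class]
    return dict(zip(sub["seq_id"], sub["count"]))


@dataclass(frozen=True)
class TitrationSpec:
    """Specification of a motif-count step-down series from a base probe."""

    base_probe: Probe
    motif_class: object = "gaga-tctc"
    target_counts: tuple[int, ...] = ()
    max_substitutions_per_step: int = 3
    forbidden_side_effects: tuple[MotifPattern, ...] = ()

    def __post_init__(self):
        targets = tuple(self.target_counts)
        if any(t < 0 for t in targets):
            raise ContractError("target counts must be non-negative")
        if list(targets) != sorted(targets, reverse=True) or len(set(targets)) != len(targets):
            raise ContractError("target_counts must be strictly decreasing")
        if self.max_substitutions_per_step < 1:
            raise ContractError("max_substitutions_per_step must be positive")


def _forbidden_hits(seq: str, patterns: Iterable[MotifPattern]) -> dict[str, int]:
    return {p.name: len(iupac_match(p, seq, strands=("+", "-"))) for p in patterns}


def design_titration_series(
    spec: TitrationSpec,
    seed: int = 0,
    sample_equal_cost: bool = False,
) -> list[Probe]:
    """Derive a probe per target count by minimal-substitution search.

    For each target the search enumerates substitution sets of the previous
    step's sequence in increasing Hamming distance (breadth-first, at most
    ``max_substitutions_per_step``), keeping candidates whose re-verified
    joint count equals the target and which gain no occurrence of any
    forbidden pattern on either strand.  Among minimal-distance solutions
    the lexicographically smallest sequence is returned, unless
    ``sample_equal_cost`` requests seeded sampling among them.
    """
    cls_name, counter = _class_counter(spec.motif_class)
    rng = np.random.default_rng(seed)
    current = spec.base_probe.sense_seq.seq
    base_count = counter(current)
    targets = tuple(spec.target_counts)
    if targets and targets[0] > base_count:
        raise ContractError(
            f"first target {targets[0]} exceeds base probe count {base_count}"
        )
    out: list[Probe] = []
    for step, target in enumerate(targets, start=1):
        baseline_forbidden = _forbidden_hits(current, spec.forbidden_side_effects)
        if counter(current) == target:
            chosen = current
        else:
            chosen = None
            for dist in range(1, spec.max_substitutions_per_step + 1):
                solutions = []
                for positions in combinations(range(len(current)), dist):
                    for subs in product(_BASES, repeat=dist):
                        if any(current[p] == b for p, b in zip(positions, subs)):
                            continue
                        cand = list(current)
                        for p, b in zip(positions, subs):
                            cand[p] = b
                        cand_seq = "".join(cand)
                        if counter(cand_seq) != target:
                            continue
                        gained = _forbidden_hits(cand_seq, spec.forbidden_side_effects)
                        if any(
                            gained[name] > baseline_forbidden[name] for name in gained
                        ):
                            continue
                        solutions.append(cand_seq)
                if solutions:
                    solutions.sort()
                    if sample_equal_cost:
                        chosen = solutions[rng.integers(len(solutions))]
                    else:
                        chosen = solutions[0]
                    break
            if chosen is None:
                raise InfeasibleDesignError(
                    f"no derivative with {cls_name} count {target} within "
                    f"{spec.max_substitutions_per_step} substitutions of {current!r}"
                )
        # re-verify by an independent re-scan before returning
        assert counter(chosen) == target
        name = f"{spec.base_probe.name}_step{step}_c{target}"
        out.append(make_probe(name, chosen, description=f"{cls_name} count {target}"))
        current = chosen
    return out
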