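"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its seed and parameters and returns
the ground truth alongside the data, so that every downstream stage can be
closed-loop tested: re-scanning a generated probe panel reproduces the
requested motif counts; re-analyzing generated coverage tracks recovers
the planted peak centers and enrichment intervals; re-partitioning
generated gene sets reproduces the requested overlap.

Defaults emulate the study conditions of a qDPI-ELISA probe panel and a
GFP-tagged factor ChIP experiment: 39-nt probes carrying 0-4 planted GAGA
elements (the top probe a contiguous (GA)_8 repeat), fluorescence affine
in motif count with Gaussian noise truncated at zero, and a promoter-rich
genome with (GA)_8 repeats planted upstream of each gene under
Gaussian-shaped coverage bumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chipprofile import CoverageTrack, call_enriched_regions, fold_enrichment_track
from .errors import ContractError, InfeasibleDesignError
from .probes import Probe, ProbePanel, make_probe
from .seqmotif import count_joint_gaga_tctc, count_rgaragrra, iupac_match, GAGA, TCTC, RGARAGRRA

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SignalModel:
    """Affine ELISA signal model: signal = baseline + gain * count + noise.

    Gaussian noise is truncated at 0 (plate readers emit non-negative
    values); with ``noise_sd == 0`` generation is deterministic.
    """

    baseline: float = 50.0
    gain: float = 100.0
    noise_sd: float = 5.0
    n_replicates: int = 3  # biological replicates (extract x plate)
    n_technical: int = 2  # technical wells per plate

    def __post_init__(self):
        if self.baseline < 0 or self.gain < 0 or self.noise_sd < 0:
            raise ContractError("baseline, gain and noise_sd must be non-negative")
        if self.n_replicates < 2 or self.n_technical < 1:
            raise ContractError("need >= 2 replicates and >= 1 technical well")


def _random_clean_sequence(length: int, rng: np.random.Generator, max_tries: int = 500) -> str:
    """Random ACGT sequence free of GAGA/TCTC and RGARAGRRA on both strands.

    Built by rejection sampling with a scanner check (rather than alphabet
    restriction) to keep base composition realistic.
    """
    for _ in range(max_tries):
        seq = "".join(rng.choice(_BASES, size=length))
        if count_joint_gaga_tctc(seq) == 0 and count_rgaragrra(seq) == 0:
            return seq
    raise InfeasibleDesignError(f"could not draw a motif-free background of length {length}")


def _plant(background: str, insert: str, start: int) -> str:
    return background[:start] + insert + background[start + len(insert) :]


def gen_probe_panel(
    counts: Sequence[int] = (0, 1, 2, 3, 4),
    length: int = 39,
    seed: int = 0,
    ga_repeat_for_max: bool = True,
) -> tuple[ProbePanel, dict[str, int]]:
    """Probe panel with known non-overlapping joint GAGA/TCTC counts.

    Backgrounds are GAGA/TCTC- and RGARAGRRA-free by construction
    (rejection-checked with the scanner).  For each requested count c the
    probe carries c isolated, C-buffered GAGA elements; when
    ``ga_repeat_for_max`` is set the highest-count probe instead carries a
    contiguous (GA)_{2c} repeat, which also contains the degenerate
    nonanucleotide consensus — decorrelating the two motif classes the way
    a repeat-bearing probe does in a real panel.  Every probe is re-scanned
    and must reproduce its requested count exactly.
    """
    if min(counts) < 0:
        raise ContractError("counts must be non-negative")
    if length < 4 * max(max(counts), 1) + 2:
        raise InfeasibleDesignError(
            f"length {length} cannot accommodate {max(counts)} buffered GAGA elements"
        )
    rng = np.random.default_rng(seed)
    probes: list[Probe] = []
    truth: dict[str, int] = {}
    max_count = max(counts)
    for c in counts:
        name = f"probe_c{c}"
        for _ in range(200):
            bg = _random_clean_sequence(length, rng)
            if c == 0:
                cand = bg
            elif ga_repeat_for_max and c == max_count and c >= 2:
                repeat = "GA" * (2 * c)
                start = int(rng.integers(1, length - len(repeat)))
                cand = _plant(bg, "C" + repeat + "C", start - 1)
            else:
                # c isolated GAGAs with C buffers, non-overlapping slots
                slot = 6  # C + GAGA + C
                positions = sorted(rng.choice(length - slot + 1, size=c, replace=False))
                if any(b - a < slot for a, b in zip(positions, positions[1:])):
                    continue
                cand = bg
                for p in positions:
                    cand = _plant(cand, "CGAGAC", p)
            if count_joint_gaga_tctc(cand) != c:
                continue
            if c < max_count and count_rgaragrra(cand) != 0:
                continue
            probes.append(make_probe(name, cand, description=f"{c} planted GAGA/TCTC"))
            truth[name] = c
            break
        else:
            raise InfeasibleDesignError(f"could not build a probe with count {c}")
    return ProbePanel(probes=probes), truth


def gen_binding_measurements(
    counts: dict[str, int],
    model: SignalModel = SignalModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate ELISA measurements for a panel under the affine signal model.

    Each biological replicate is one (extract, plate) pair carrying
    ``n_technical`` independently noisy wells.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for probe in sorted(counts):
        expected = model.baseline + model.gain * counts[probe]
        for rep in range(1, model.n_replicates + 1):
            for tech in range(1, model.n_technical + 1):
                noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "probe": probe,
                        "extract": f"E{rep}",
                        "plate": f"P{rep}",
                        "tech_rep": tech,
                        "signal": max(0.0, expected + noise),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Geometry of a synthetic single-chromosome genome with planted repeats.

    Genes are laid out as [intergenic | gene] blocks; one (GA/TC)_n repeat
    is planted centrally in each gene's upstream intergenic (promoter)
    region and its interval recorded as ground truth.
    """

    n_genes: int = 48
    gene_length: int = 1500
    intergenic_length: int = 1500
    repeat_units: tuple[int, ...] | int = 8
    seed: int = 0
    chrom: str = "synchr1"

    def units_for(self, i: int) -> int:
        if isinstance(self.repeat_units, int):
            return self.repeat_units
        return self.repeat_units[i % len(self.repeat_units)]

    def __post_init__(self):
        if self.n_genes < 1 or self.gene_length < 1 or self.intergenic_length < 20:
            raise ContractError("invalid genome geometry")
        units = (
            [self.repeat_units]
            if isinstance(self.repeat_units, int)
            else list(self.repeat_units)
        )
        if any(u < 2 for u in units):
            raise ContractError("repeat_units must be >= 2")
        if max(units) * 2 + 2 > self.intergenic_length:
            raise ContractError("intergenic region too short for the planted repeat")


def gen_synthetic_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Genome FASTA mapping, gene BED table, and planted-repeat ground truth.

    The non-repeat background is scrubbed of incidental GAGA/TCTC and
    degenerate-consensus occurrences by mutating one base of each hit, so
    planted repeats are the only motif carriers.
    """
    rng = np.random.default_rng(spec.seed)
    block = spec.intergenic_length + spec.gene_length
    total = spec.n_genes * block
    seq = rng.choice(_BASES, size=total)
    # scrub incidental motifs (both strands, via the sense-strand scanners)
    for _ in range(50):
        text = "".join(seq)
        hits = iupac_match(GAGA, text, strands=("+",)) + iupac_match(
            TCTC, text, strands=("+",)
        ) + iupac_match(RGARAGRRA, text, strands=("+", "-"))
        if not hits:
            break
        for h in hits:
            pos = int(rng.integers(h.start, h.end))
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[int(rng.integers(3))]
    else:
        raise InfeasibleDesignError("failed to scrub background motifs")

    genes = []
    truth = []
    for i in range(spec.n_genes):
        gene_id = f"gene{i + 1:03d}"
        promoter_start = i * block
        gene_start = promoter_start + spec.intergenic_length
        units = spec.units_for(i)
        repeat = "GA" * units
        rep_start = promoter_start + (spec.intergenic_length - len(repeat)) // 2
        pad = "C" + repeat + "C"
        seq[rep_start - 1 : rep_start + len(repeat) + 1] = list(pad)
        # integer center: argmax position a symmetric bump rule will return
        center = rep_start + (len(repeat) - 1) // 2
        genes.append(
            {
                "chrom": spec.chrom,
                "start": gene_start,
                "end": gene_start + spec.gene_length,
                "name": gene_id,
            }
        )
        truth.append(
            {
                "gene": gene_id,
                "repeat_start": rep_start,
                "repeat_end": rep_start + len(repeat),
                "units": units,
                "center": center,
            }
        )
    genome = {spec.chrom: "".join(seq)}
    truth_df = pd.DataFrame(truth)
    # verify the plant: each repeat interval must re-scan to its unit count
    for row in truth_df.itertuples():
        segment = genome[spec.chrom][row.repeat_start : row.repeat_end]
        assert segment == "GA" * row.units
    return genome, pd.DataFrame(genes), truth_df


@dataclass
class CoverageTruth:
    centers: dict[str, int]  # gene -> planted peak center
    enriched_regions: list[tuple[int, int]]  # true fold > threshold intervals


def gen_coverage_tracks(
    spec: SyntheticGenomeSpec,
    truth: pd.DataFrame,
    peak_height: float = 18.0,
    peak_sd: float = 150.0,
    background: float = 2.0,
    jitter_sd: float = 0.0,
    pseudocount: float = 1.0,
    threshold: float = 5.0,
    seed: int = 0,
) -> tuple[list[CoverageTrack], list[CoverageTrack], CoverageTruth]:
    """Two treatment and two control tracks plus analytic ground truth.

    Treatment = background + Gaussian bumps centered on the planted repeats
    (+ optional per-position jitter, truncated at 0); control = background
    (+ jitter).  Ground truth records the bump centers and the intervals
    where the true (noiseless) fold exceeds ``threshold``.
    """
    rng = np.random.default_rng(seed)
    total = spec.n_genes * (spec.intergenic_length + spec.gene_length)
    pos = np.arange(total)
    bump = np.zeros(total)
    centers: dict[str, int] = {}
    for row in truth.itertuples():
        bump += peak_height * np.exp(-((pos - row.center) ** 2) / (2 * peak_sd**2))
        centers[row.gene] = int(row.center)
    t_true = background + bump
    c_true = np.full(total, background)

    def noisy(base: np.ndarray) -> CoverageTrack:
        vals = base.copy()
        if jitter_sd > 0:
            vals = np.maximum(0.0, vals + rng.normal(0.0, jitter_sd, size=total))
        return CoverageTrack(chrom=spec.chrom, start=0, values=vals)

    treatments = [noisy(t_true), noisy(t_true)]
    controls = [noisy(c_true), noisy(c_true)]

    true_fold = CoverageTrack(
        chrom=spec.chrom,
        start=0,
        values=(t_true + pseudocount) / (c_true + pseudocount),
    )
    regions = [
        (r.start, r.end) for r in call_enriched_regions(true_fold, threshold=threshold)
    ]
    return treatments, controls, CoverageTruth(centers=centers, enriched_regions=regions)


def gen_gene_sets(
    N: int,
    n1: int,
    n2: int,
    k: int,
    seed: int = 0,
    names: tuple[str, str] = ("A", "B"),
) -> tuple[frozenset, "tuple"]:
    """A universe of size N and two gene sets with overlap exactly k."""
    from .genesets import GeneSet

    if not (0 <= k <= min(n1, n2)) or n1 + n2 - k > N:
        raise ContractError(
            f"infeasible overlap design: N={N}, n1={n1}, n2={n2}, k={k}"
        )
    rng = np.random.default_rng(seed)
    universe = [f"g{i:05d}" for i in range(N)]
    order = rng.permutation(N)
    a_ids = [universe[i] for i in order[:n1]]
    b_ids = a_ids[:k] + [universe[i] for i in order[n1 : n1 + (n2 - k)]]
    uni = frozenset(universe)
    a = GeneSet.from_iterable(names[0], a_ids, uni)
    b = GeneSet.from_iterable(names[1], b_ids, uni)
    assert len(a.members & b.members) == k
    return uni, (a, b)
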