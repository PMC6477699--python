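"""Coverage-track post-processing for ChIP fold-enrichment profiling.

Starts from per-base coverage tracks (bedGraph text, one chromosome per
track), computes replicate-combination fold enrichment with a pseudocount,
the per-position median over the four treatment x control replicate
combinations, calls maximal >threshold-fold regions, locates per-gene peak
maxima, and builds strand-resolved GAGA/TCTC motif density and
distribution maps centered at those maxima.

Read mapping and peak calling are upstream concerns; this module's inputs
are already-computed coverage tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError, FormatError
from .seqmotif import GAGA, TCTC, MotifPattern, iupac_match

DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CoverageTrack:
    """Per-base non-negative coverage over [start, start+len(values)) on one chromosome."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("coverage values must be one-dimensional")
        if self.start < 0:
            raise ContractError("track start must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def value_at(self, pos: int) -> float:
        """Coverage at a genome position; positions off the track are 0."""
        if self.start <= pos < self.end:
            return float(self.values[pos - self.start])
        return 0.0

    def to_intervals(self) -> list[tuple[int, int, float]]:
        """Run-length encoding as (start, end, value) bedGraph intervals."""
        out = []
        i = 0
        n = len(self.values)
        while i < n:
            j = i + 1
            while j < n and self.values[j] == self.values[i]:
                j += 1
            out.append((self.start + i, self.start + j, float(self.values[i])))
            i = j
        return out


def read_bedgraph(path) -> CoverageTrack:
    """Parse a single-chromosome bedGraph file into a dense coverage track.

    Intervals must be sorted and non-overlapping; uncovered gaps read back
    as coverage 0.  Overlap, disorder, or a second chromosome raise a
    :class:`FormatError` naming the offending line.
    """
    intervals: list[tuple[int, int, float]] = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            c, s, e, v = parts
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise FormatError(
                    f"{path}:{lineno}: multiple chromosomes ({chrom!r}, {c!r}) in one track"
                )
            if e <= s:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            if intervals and s < intervals[-1][1]:
                raise FormatError(f"{path}:{lineno}: unsorted or overlapping interval")
            intervals.append((s, e, v))
    if not intervals:
        raise FormatError(f"{path}: no data lines")
    start = intervals[0][0]
    values = np.zeros(intervals[-1][1] - start)
    for s, e, v in intervals:
        values[s - start : e - start] = v
    return CoverageTrack(chrom=chrom, start=start, values=values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as run-length-encoded bedGraph (round-trip exact)."""
    with open(path, "w") as fh:
        for s, e, v in track.to_intervals():
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v!r}\n")


def _align(tracks: Sequence[CoverageTrack]) -> tuple[str, int, np.ndarray]:
    chroms = {t.chrom for t in tracks}
    if len(chroms) != 1:
        raise ContractError(f"tracks are on different chromosomes: {sorted(chroms)}")
    start = min(t.start for t in tracks)
    end = max(t.end for t in tracks)
    stacked = np.zeros((len(tracks), end - start))
    for i, t in enumerate(tracks):
        stacked[i, t.start - start : t.end - start] = t.values
    return chroms.pop(), start, stacked


def fold_enrichment_track(
    treatment: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CoverageTrack:
    """Per-position (treatment + pseudocount) / (control + pseudocount)."""
    if pseudocount <= 0:
        raise ContractError("pseudocount must be positive")
    chrom, start, (t, c) = _align([treatment, control])
    return CoverageTrack(chrom=chrom, start=start, values=(t + pseudocount) / (c + pseudocount))


def median_fold_track(
    treatments: Sequence[CoverageTrack],
    controls: Sequence[CoverageTrack],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    allow_general: bool = False,
) -> CoverageTrack:
    """Per-position median fold over all treatment x control replicate pairs.

    The canonical design is 2 treatment and 2 control replicates (4
    combinations; the median of 4 values is the mean of the two middle
    ones).  Other replicate layouts require ``allow_general=True``.
    """
    if not allow_general and (len(treatments) != 2 or len(controls) != 2):
        raise ContractError(
            "expected exactly 2 treatment and 2 control tracks "
            "(pass allow_general=True for other layouts)"
        )
    chrom, start, stacked = _align(list(treatments) + list(controls))
    t = stacked[: len(treatments)] + pseudocount
    c = stacked[len(treatments) :] + pseudocount
    folds = t[:, None, :] / c[None, :, :]  # (n_treat, n_ctrl, positions)
    med = np.median(folds.reshape(-1, folds.shape[-1]), axis=0)
    return CoverageTrack(chrom=chrom, start=start, values=med)


@dataclass(frozen=True)
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    min_fold: float


def call_enriched_regions(
    track: CoverageTrack,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_length: int = 1,
) -> list[EnrichedRegion]:
    """Maximal runs of positions with value strictly above ``threshold``."""
    if threshold <= 0:
        raise ContractError("threshold must be positive")
    above = track.values > threshold
    out: list[EnrichedRegion] = []
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_length:
                out.append(
                    EnrichedRegion(
                        chrom=track.chrom,
                        start=track.start + i,
                        end=track.start + j,
                        min_fold=float(track.values[i:j].min()),
                    )
                )
            i = j
        else:
            i += 1
    return out


@dataclass(frozen=True)
class PeakCenter:
    position: int
    degenerate: bool  # all-zero (flat) region


def locate_peak_center(
    track: CoverageTrack,
    region: tuple[int, int] | None = None,
) -> PeakCenter:
    """Position of the coverage maximum within a region.

    Ties are broken at the floored midpoint of the leftmost maximal run.
    An all-zero region is flagged degenerate (its leftmost position is
    returned by the same rule).
    """
    if region is None:
        region = (track.start, track.end)
    s, e = region
    s = max(s, track.start)
    e = min(e, track.end)
    if e <= s:
        raise ContractError("empty region")
    window = track.values[s - track.start : e - track.start]
    peak = window.max()
    i = int(np.argmax(window == peak))
    j = i
    while j < len(window) and window[j] == peak:
        j += 1
    mid = (i + j - 1) // 2
    return PeakCenter(position=s + mid, degenerate=bool(peak == 0))


@dataclass
class DensityProfile:
    """Per-gene motif occurrence indicators in windows centered at peak maxima.

    ``occupancy[pattern]`` is a (genes x offsets) 0/1 matrix marking motif
    *start* offsets (all occurrences, overlapping allowed — this maps
    positions, it does not count);  ``aggregate[pattern]`` is its
    column-wise mean across genes, in [0, 1].
    """

    genes: list[str]
    offsets: np.ndarray
    occupancy: dict[str, np.ndarray]
    aggregate: dict[str, np.ndarray] = field(init=False)
    clipped: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.aggregate = {
            name: occ.mean(axis=0) if len(occ) else occ.sum(axis=0).astype(float)
            for name, occ in self.occupancy.items()
        }


def motif_density_map(
    sequences: Mapping[str, str],
    centers: Mapping[str, tuple[str, int]],
    halfwidth: int = 1000,
    patterns: Sequence[MotifPattern] = (GAGA, TCTC),
) -> DensityProfile:
    """Sense-strand motif density/distribution map centered per gene.

    ``centers`` maps gene id -> (sequence id, center position).  For each
    gene the window [center - W, center + W) is extracted; motif start
    offsets are marked per pattern for every (possibly overlapping)
    occurrence.  Windows clipped at sequence ends are padded-as-absent and
    the gene is flagged; a center outside its sequence skips the gene with
    a warning.
    """
    if len({len(p) for p in patterns}) != 1:
        raise ContractError("density-map patterns must share one length")
    if halfwidth < max(len(p) for p in patterns):
        raise ContractError("halfwidth must be at least the pattern length")
    genes: list[str] = []
    clipped: list[str] = []
    skipped: list[str] = []
    rows: dict[str, list[np.ndarray]] = {p.name: [] for p in patterns}
    k_by_pattern = {p.name: len(p) for p in patterns}
    n_offsets = {p.name: 2 * halfwidth - len(p) + 1 for p in patterns}
    for gene, (seq_id, center) in centers.items():
        if seq_id not in sequences:
            warnings.warn(f"gene {gene!r}: unknown sequence {seq_id!r}; skipped")
            skipped.append(gene)
            continue
        seq = sequences[seq_id]
        if not (0 <= center < len(seq)):
            warnings.warn(
                f"gene {gene!r}: center {center} outside sequence {seq_id!r}; skipped"
            )
            skipped.append(gene)
            continue
        lo, hi = center - halfwidth, center + halfwidth
        if lo < 0 or hi > len(seq):
            clipped.append(gene)
        genes.append(gene)
        window = seq[max(lo, 0) : min(hi, len(seq))]
        pad_left = max(lo, 0) - lo
        for p in patterns:
            row = np.zeros(n_offsets[p.name], dtype=np.int8)
            for hit in iupac_match(p, window, strands=("+",)):
                off = hit.start + pad_left
                if off < n_offsets[p.name]:
                    row[off] = 1
            rows[p.name].append(row)
    occupancy = {
        name: (np.vstack(r) if r else np.zeros((0, n_offsets[name]), dtype=np.int8))
        for name, r in rows.items()
    }
    # offsets are motif start positions relative to the center; a motif of
    # length k can start no later than W - k inside the window
    any_pattern = patterns[0]
    offsets = np.arange(-halfwidth, halfwidth - len(any_pattern) + 1)
    return DensityProfile(
        genes=genes, offsets=offsets, occupancy=occupancy, clipped=clipped, skipped=skipped
    )
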