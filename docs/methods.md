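# Methods

## Scope and model of the data

`gagabind` implements the quantitative analysis pipeline around the
minimal-motif question for plant GAGA-binding factors (the BBR/BPC family):
does binding scale with the number of available GAGA/TCTC tetranucleotide
elements, rather than with the longer degenerate RGARAGRRA consensus from
earlier literature?  The pipeline has five analytical stages — motif
scanning/counting, probe-panel design, (q)DPI-ELISA statistics, ChIP
coverage profiling, and gene-set overlap testing — plus a protein-alignment
consensus stage and seeded generators that produce every input with known
ground truth.

## Motif scanning and non-overlapping counting

Patterns are IUPAC-degenerate strings.  A sequence letter matches a pattern
letter iff its expansion is a subset of the pattern letter's expansion, so
an `N` in a sequence matches only pattern `N` while pattern `N` matches
every letter.  Matching is overlapping and strand-resolved; minus-strand
hits are found by scanning the sense strand with the reverse-complemented
pattern, so coordinates are always 0-based half-open on the sense strand
(the bedGraph/BED convention).

Non-overlapping counting selects hits greedily by earliest end over the
merged, start-sorted hit list.  For equal-length hits this is the classic
interval-scheduling argument and is provably maximal; the test suite
additionally verifies equality with an exhaustive branch-and-bound oracle
on thousands of random sequences.  Two conventions matter and are fixed
here:

* **Joint GAGA/TCTC class — sense strand only.**  A TCTC on the sense
  strand is a GAGA on the antisense strand, so sense-strand joint counting
  equals both-strand GAGA counting with cross-strand overlap resolution.
  The property `count(seq) == count(revcomp(seq))` is asserted for random
  sequences.  This convention reproduces the two worked examples the
  pipeline is anchored to: a (GA/TC)8 dinucleotide repeat counts **4**
  and the element `GAGAGATGAGAGA` counts **2**.
* **RGARAGRRA — per strand, summed.**  The degenerate nonanucleotide is
  counted non-overlapping on each strand independently and the two counts
  added.  Probes in this problem domain are GA-rich on the sense strand,
  so this convention is strand-agnostic without double-resolving overlaps
  across strands.

`find_ga_tc_repeats` annotates maximal phase-locked (GA)n / (TC)n runs
(no mixed-phase merging), the genomic elements the factors bind in vivo.

## Probe titration design

`design_titration_series` steps a base probe down a strictly decreasing
ladder of joint counts.  For each target it enumerates substitution sets in
increasing Hamming distance (breadth-first, bounded by
`max_substitutions_per_step`), keeps candidates whose re-scanned count
equals the target and which gain no occurrence of any forbidden pattern on
either strand, and returns the lexicographically smallest minimal-distance
solution (seeded sampling among equal-cost solutions is opt-in).  Every
returned probe is re-verified by an independent re-scan.  The search is
exhaustive within its distance budget, hence deterministic; infeasibility
is reported naming the failing target.

## ELISA statistics

Measurement tables carry `(probe, extract, plate, tech_rep, signal)`.
Technical wells are averaged within a plate before any cross-plate
statistic, so replication is counted at the (extract, plate) level and
technical wells do not inflate n.  Per-probe summaries use the unbiased
standard deviation.  Normalization subtracts the mean signal of the
non-binding background probe and divides by the background-subtracted mean
of the single-motif reference probe; negative background-subtracted values
are retained and flagged, never clamped (clamping would bias folds near
zero).  Fold differences are therefore invariant under any positive-gain
affine rescaling of the raw signals (tested).

Significance of binding is a two-sided Welch t-test of a probe's replicate
signals against the background probe's (unequal variances across plates
and extracts are the rule, not the exception); `p < alpha` with
`alpha = 0.05` by default.  The degenerate all-equal case returns p = 1 and
is flagged.

Two statistics address the minimal-motif question:

* **Pearson coefficient** between per-probe motif counts and fold
  differences (error on constant axes).
* **Chi-square goodness-of-fit** of observed folds against expected folds
  proportional to motif count, `expected(p) = count(p)/count(reference)`;
  the statistic is `sum((obs-exp)^2/exp)` over probes with positive
  expectation, and the p-value is the upper chi-square tail with
  (included − 1) degrees of freedom.  Probes with count 0 are excluded and
  reported.  Note: published "chi-square" values in this assay family are
  quoted in [0, 1] without saying whether they are statistics or p-values;
  this package always reports **both**, reading "high interdependence"
  as p ≈ 1.  A class in which the reference probe has count 0 has no
  defined ratio model and is skipped in the panel-level report.

One-way ANOVA across probes uses the classical F statistic with df
(k − 1, N − k); a 9-probe × 3-replicate design yields the familiar
F(8, 18) layout.

## Coverage profiling

bedGraph text is parsed to dense per-base tracks (sorted, non-overlapping
intervals enforced with line numbers in errors; gaps read back as 0).
Fold enrichment is `(t + c0)/(c + c0)` with pseudocount `c0 = 1.0` by
default — chosen for boundedness at zero coverage.  The replicate-combined
track is the per-position median over all treatment × control pairs of the
canonical 2 × 2 design (median of four = mean of the middle two); other
layouts are allowed behind an explicit flag.  Enriched regions are maximal
runs strictly above the threshold (default 5-fold, honouring "more than
5-fold"); plateau peak maxima resolve to the floored midpoint of the
leftmost maximal run, and all-zero regions are flagged degenerate.

Density maps mark **all** (overlapping) GAGA and TCTC start offsets on the
sense strand in windows of halfwidth W (default 1000 bp, configurable)
centered at each gene's peak maximum — position mapping, not
non-overlap counting, because the map plots where motifs sit, not how many
bind.  Windows clipped at sequence ends are padded-as-absent and flagged;
centers outside their sequence skip the gene with a warning.  The
distribution map is the column-wise mean across genes.

## Gene-set overlaps

Sets live in a shared finite universe; duplicates are collapsed on
ingestion and counted.  Venn partitions are exact for 2–4 sets.  Overlap
significance uses the hypergeometric distribution with both one-sided
tails including the observed overlap: `P(X >= k)` for enrichment,
`P(X <= k)` for depletion.  Raw p-values are reported; no multiple-testing
correction is applied by default (a Bonferroni helper exists).  Tails are
verified against exhaustive enumeration of every draw for all universes up
to N = 12.

## Alignment consensus

Within a group, a column is invariant iff all members carry the identical
residue and none is gapped — a deliberately strict rule (a gap breaks
invariance), since shading conventions for published domain consensi are
rarely stated.  Cross-group invariants require the same residue invariant
in every group; columns invariant per group but differing across groups
are flagged separately as class-conserved using the fixed classes
{KR, DE, ILVM, FYW, ST, NQ} (e.g. the R/K position of a WAR/KHGTN-type
motif), never merged into invariants.  Single-sequence insertion columns —
exactly one row with a residue, all others gapped, as for the lone extra
histidine in one family member — are reported as (column, sequence id).

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of seed and parameters, and returns its
ground truth so the consuming stage can be closed-loop tested.

* **Probe panels** (default: counts 0–4, 39-nt probes): backgrounds are
  rejection-sampled to be free of GAGA/TCTC and RGARAGRRA on both strands
  (a scanner check, not alphabet restriction, keeping base composition
  realistic).  Requested counts are planted as isolated C-buffered GAGA
  elements; the top-count probe is a contiguous (GA)_{2c} repeat, which
  also carries the degenerate nonanucleotide — decorrelating the two motif
  classes the way a repeat-bearing probe does in a real panel.  Panels are
  re-scanned and must reproduce their counts exactly.
* **Signals**: `signal = baseline + gain × count + N(0, sd)`, truncated at
  0 (plate readers are non-negative; truncation biases means upward at
  high noise — documented, and defaults keep noise at 5 % of the
  single-motif signal: baseline 50, gain 100, sd 5 a.u., 3 biological
  replicates × 2 technical wells).
* **Genomes/tracks** (default 48 genes × (1500 + 1500) bp): one (GA)8
  repeat planted centrally in each promoter, background scrubbed of
  incidental motifs; treatment coverage is background 2.0 plus Gaussian
  bumps (height 18.0, sd 150 bp) centered on the repeats, controls are
  background, optional truncated-Gaussian jitter.  With pseudocount 1 the
  true fold maximum is (2+18+1)/(2+1) = 7 > 5, so planted enrichment
  intervals are recoverable; their analytic record is the ground truth.
* **Gene sets**: two sets with an exactly requested overlap from a fixed
  universe.

The generators emulate the *statistical structure* the analysis assumes —
affine signal in count, symmetric peaks on motif-free backgrounds, exact
overlaps.  They do not emulate plate-position effects, assay saturation
(the colorimetric assay is only semi-quantitative), fragment-length or GC
bias in coverage, correlated replicate noise, or annotation errors.
Passing closed-loop tests therefore demonstrates correctness of the
computations, not robustness to every artefact of real data.

## Problem sizes and numerical choices

Default test and acceptance runs use desk-scale problems chosen to make
every check exact and fast: 1000 random sequences of length ≤ 40 for the
counting oracles, 200 noisy panels for the correlation-ordering check,
8–24 genes for profile recovery, and N ≤ 12 for hypergeometric
enumeration.  Headline dataset-scale figures from in-vivo studies (e.g.
thousands of target regions) depend on raw data that is not redistributed
and are out of scope; the package reproduces the printed worked-example
counts and the methodological behaviour instead.

Ties and degenerate inputs are handled by stated rules rather than chance:
lexicographic tie-breaks in probe design, leftmost-run midpoints for
coverage plateaus, p = 1 for all-equal ANOVA/t-test inputs, and explicit
errors for constant correlation axes, unequal pattern lengths in a joint
class, and out-of-support hypergeometric arguments.  All randomness flows
through `numpy.random.default_rng(seed)`; reruns are byte-identical.
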