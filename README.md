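# gagabind

Quantitative analysis of GAGA/TCTC cis-regulatory elements and their
recognition by plant GAGA-binding factors (the BBR/BPC family of BASIC
PENTACYSTEINE transcription factors).

Plant BBR/BPC proteins bind GA/TC-rich DNA, and the minimal element they
require is the GAGA tetranucleotide (equivalently TCTC on the opposite
strand) rather than the longer degenerate nonanucleotide consensus
RGARAGRRA proposed earlier.  Testing that claim quantitatively requires a
small pipeline: count how many *non-overlapping* GAGA/TCTC elements each
oligonucleotide probe or promoter offers, turn replicate DNA–protein
interaction ELISA ((q)DPI-ELISA) signals into background-subtracted fold
differences, ask which motif count explains the folds (Pearson ε, χ²
goodness-of-fit, one-way ANOVA), profile ChIP coverage fold enrichment
around peak maxima with GAGA/TCTC density maps, and test gene-list
overlaps against a finite universe with the hypergeometric distribution.
`gagabind` implements that pipeline for people who run binding assays or
reanalyze ChIP coverage for GAGA-factor biology, plus a protein-alignment
consensus tool for the conserved BPC DNA-binding domain and seeded
synthetic-data generators so every stage is testable end to end.

## The statistics at the core

For a probe p with non-overlapping motif count `c(p)`, background probe
`bg` and single-motif reference `ref`:

```
bs(p)   = mean(p) − mean(bg)                      background subtraction
fold(p) = bs(p) / bs(ref)                         fold difference
ε       = corr_Pearson(c(p), fold(p))             count–signal correlation
χ²      = Σ_p (fold(p) − c(p)/c(ref))² / (c(p)/c(ref)),  p-value from
          the χ² upper tail with (n_included − 1) df
```

Non-overlapping counts use greedy earliest-end interval selection, which
is provably maximal for equal-length hits; the joint GAGA/TCTC class is
counted on the sense strand (a sense TCTC *is* an antisense GAGA, and the
count is invariant under reverse complement).  Coverage fold enrichment is
`(t + 1)/(c + 1)` per base, combined as the per-position median over the
2 × 2 treatment × control replicate pairs, with regions called strictly
above 5-fold.  Overlap significance is `P(X ≥ k)` / `P(X ≤ k)` for
`X ~ Hypergeometric(N, n1, n2)`.

## Worked example

```python
import gagabind as g
from gagabind import synthdata as sd

for name, seq in [("BKn3-like (GA/TC)8", "GAGAGAGAGAGAGAGA"),
                  ("BAK1/KNAT1 element", "GAGAGATGAGAGA")]:
    print(f"{name:22s} joint GAGA/TCTC = {g.count_joint_gaga_tctc(seq)}  "
          f"RGARAGRRA = {g.count_rgaragrra(seq)}")

panel, truth = sd.gen_probe_panel(seed=1)          # probes with 0..4 motifs
meas = sd.gen_binding_measurements(truth, sd.SignalModel(), seed=2)
summaries, pearson, reports, anova = g.analyze_panel(
    meas, {"gaga-tctc": truth}, background_probe="probe_c0",
    reference_probe="probe_c1")
print(summaries[["n", "mean_signal", "fold_difference", "significant"]].round(2))
rep = reports["gaga-tctc"]
print(f"Pearson = {pearson['gaga-tctc']:.4f}   "
      f"chi2 = {rep.statistic:.4f} (df {rep.df}), p = {rep.p_value:.4f}")
print(f"ANOVA F({anova.df_between},{anova.df_within}) = {anova.F:.2f}, "
      f"p = {anova.p_value:.2e}")
```

prints

```
BKn3-like (GA/TC)8     joint GAGA/TCTC = 4  RGARAGRRA = 1
BAK1/KNAT1 element     joint GAGA/TCTC = 2  RGARAGRRA = 0
          n  mean_signal  fold_difference  significant
probe
probe_c0  3        49.80             0.00        False
probe_c1  3       150.70             1.00         True
probe_c2  3       249.31             1.98         True
probe_c3  3       350.84             2.98         True
probe_c4  3       447.46             3.94         True
Pearson = 1.0000   chi2 = 0.0012 (df 3), p = 1.0000
ANOVA F(4,10) = 4246.27, p = 4.23e-16
```

The (GA/TC)8 repeat packs four non-overlapping GAGA/TCTC elements and the
`GAGAGATGAGAGA` promoter element two.  On the simulated panel (signal
affine in motif count, 5 % noise) fold differences track the counts almost
exactly: ε = 1.0 and a χ² goodness-of-fit p near 1 say the motif counts
fully explain the signals, and the ANOVA confirms the probes differ far
beyond replicate noise.

Every stage is also exposed on the command line —
`gagabind scan | count | probes design | binding | profile | overlap |
consensus | simulate` — each writing plain-text outputs plus a
`provenance.json` sidecar (parameters, seed, input checksums), so reruns
with the same configuration are byte-identical.

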