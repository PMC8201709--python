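# nucqc

Quality control and annotation of nucleosome organization maps from
MNase-seq, for chromatin and regulatory-genomics analyses.

MNase-seq samples deposited in public archives vary enormously in quality,
and most downstream claims about promoter chromatin architecture hinge on
picking (or building) one trustworthy nucleosome map per cell type.
`nucqc` implements that selection pipeline end to end, plus the per-locus
feature quantification and the nucleosome-aware transcription-factor
binding predictor that such maps enable:

1. **Sample QC** — six measurements per sample: sequencing coverage (fold),
   AA/TT/AT dinucleotide periodicity, nucleosomal DNA length (mode of the
   fragment-length histogram, ranked by deviation from 146 bp), nucleosome
   depletion at TSSs, nucleosome fuzziness downstream of TSSs (CV of the
   +1..+4 spacings; Pass iff < 0.4), and enrichment of positioned arrays at
   DHSs.  Each metric except coverage carries a Pass/Fail label.
2. **Ranking, pooling and reference selection** — samples of a cell type /
   treatment are ordered lexicographically by
   (N_good, C_better, R_better): the Pass count, the number of metrics with
   rank quantile above the group mean, and the sum of rank quantiles.
   Samples whose 1 kb-window occupancy correlates with Pearson r > 0.6 are
   pooled; the top-ranked ("High Quality") sample is the referenced
   landscape unless it belongs to a pool, in which case the pooled sample
   is.  References below five-fold coverage are filtered out.
3. **Per-locus features** — at each TSS (strand-aware) or DHS (both sides):
   depletion level `1 − N_center/N_background` (maxima over the central
   200 bp bin and its 200 bp flanks, clamped to 0), mean occupancy over the
   central 100 bp, array score (window mean over genome mean of the
   array-regularity signal), nucleosome positions (smoothed local maxima,
   merged below 100 bp), the +1/−1 nucleosome, linker length (mean adjacent
   spacing − 147 bp), linker SD, and nucleosome count.  Undetectable values
   carry the literal sentinel −1.
4. **TF binding prediction** — motif hits are labeled bound/unbound by
   ChIP-seq peak overlap; logistic regressions with and without the four
   nucleosome predictors are compared under identical stratified 10-fold
   cross-validation, and the headline statistic is
   `AUC(motif + nucleosome) − AUC(motif)`.

A fully deterministic synthetic-data generator (`nucqc.synthetic`) emulates
all required inputs — genomes with planted 10 bp dinucleotide phase, NFRs,
phased arrays, ~147 bp fragments, background noise, and generative binding
models with known coefficients — so the whole pipeline runs and is tested
without any downloads.

## Worked example

`examples/` contains one narrative script per capability.
`examples/01_simulate_and_qc.py` simulates a healthy library and runs QC:

```
sample sim: 60000 fragments
  coverage_fold                  29.374  (unlabeled)
  dinucleotide_periodicity        0.840  Pass
  fragment_length_bp            145.000  Pass
  tss_depletion                   0.933  Pass
  tss_fuzziness                   0.119  Pass
  dhs_array_enrichment            1.564  Pass
  N_good = 5 of 5 labeled metrics pass
```

Coverage is ~29× (well above the five-fold reference gate); the fragment
mode sits at the nucleosomal DNA length; depletion near 1 means clear NFRs
at the synthetic TSSs; fuzziness 0.119 < 0.4 means well-phased +1..+4
nucleosomes; and arrays are 1.56-fold enriched at DHSs.

`examples/04_tf_prediction.py` generates binding that depends on motif
score *and* nucleosome depletion, then compares the two models:

```
3000 labeled motif hits, 1462 bound
AUC (motif score only):          0.707
AUC (+ nucleosome organization): 0.812
AUC improvement:                 +0.105

full-model coefficients (maximum likelihood):
  intercept           -6.696  (SE 0.312)
  motif_score         +0.511  (SE 0.026)
  depletion_level     +2.977  (SE 0.175)
  occupancy           +0.063  (SE 0.055)
  array_score_up      +0.073  (SE 0.095)
  array_score_down    +0.036  (SE 0.094)
```

The fitted depletion coefficient recovers the generative value (3.0) within
one standard error, and adding nucleosome information lifts the
cross-validated AUC by 0.105.

A thin CLI mirrors the library (`nucqc simulate | tracks | qc | rank |
select | features | tfpredict`); run `nucqc --help` for the commands.

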