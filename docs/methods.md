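# Methods

This note documents the models and procedures `nucqc` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.  Coordinates are 0-based half-open throughout; BED inputs are taken
as-is, 1-based formats (SAM) are converted at the boundary.

## Signal tracks

**Occupancy.**  Each MNase-protected fragment contributes a dyad-centered
footprint: the fragment midpoint `(start + end) // 2` extended by
`footprint // 2` on both sides (default footprint 147 bp, so a 146 bp
half-open extent), clipped at chromosome ends.  Occupancy at a base is the
number of footprints covering it.  By default the track is divided by its
genome-wide mean, so occupancy is expressed relative to the genome average
(mean exactly 1).  Normalization makes depletion ratios, array-score
ratios and cross-sample correlations comparable between samples of
different depth.  Tracks are dense float vectors at 1 bp resolution
(configurable binning averages into fixed-width bins); bedGraph round-trip
is lossless at 1e-6 relative, bigWig export is optional.

**Array signal.**  Regularly spaced nucleosome arrays are detected with a
windowed autocorrelation statistic: for every 100 bp step bin, the
occupancy in a 2 kb window centered on the bin is mean-subtracted and the
normalized autocorrelation `r(lag) = Σ x_t x_{t+lag} / Σ x_t²` is
maximized over lags 150–220 bp (the plausible nucleosome repeat-length
range); the value, clipped to [0, 1], is assigned to the bin.  The
statistic is dimensionless, invariant to positive scaling of occupancy,
equals ~1 for a long periodic array, and 0 for flat signal (windows whose
variance is at float-noise level — below `(1e-8·max|x|)²·n` — are defined
as 0 to avoid denormal-driven artifacts).  A window must be at least twice
the maximum lag, otherwise construction aborts.

## The six QC measurements

1. **Sequencing coverage** — fold = Σ fragment lengths / Σ chromosome
   lengths.  Unlabeled; used by the five-fold reference gate.
2. **Dinucleotide periodicity** — positional frequency of {AA, TT, AT}
   dinucleotide starts over 147 bp fragment-midpoint-centered windows; the
   score is the rfft power in the 9–11 bp period band of the
   mean-subtracted profile divided by total non-DC power (∈ [0, 1]).
   Nucleosomal DNA shows the ~10 bp helical phasing of flexible
   dinucleotides; a degraded or arbitrarily fragmented library does not.
   Requires the genome FASTA; otherwise NA (label Fail, quantile 0).
   Fragments are subsampled (default cap 20 000) for speed.
3. **Nucleosomal DNA length** — mode of the 1 bp fragment-length
   histogram.  Ranked by |mode − 146|; fewer than 100 fragments flags the
   value low-confidence.
4. **TSS depletion** — mean per-TSS depletion level (below).
5. **TSS fuzziness** — the aggregate strand-aware occupancy profile over
   [TSS, TSS + 1500) (minus-strand windows reversed) is peak-called with
   the same machinery as the locus features; the CV (population SD / mean)
   of the three spacings between the first four peaks is the fuzziness.
   The 1.5 kb span is used because four nucleosomes at a ~190 bp repeat
   extend past 1 kb.  Fewer than four aggregate peaks → NA → Fail.
   Computing on the aggregate profile (rather than per-TSS then averaging)
   is robust at modest coverage; population SD (divide by k) is used so
   the 0.4 threshold is exactly reproducible.
6. **DHS array enrichment** — mean array signal over DHS ± 1 kb divided by
   the genome-wide mean array signal.

**Labels.**  Fuzziness passes iff CV < 0.4 (strict; 0.40 fails).  The
other four thresholds are package defaults, overridable via
`QCThresholds` and flagged as defaults in reports: depletion ≥ 0.2, array
enrichment ≥ 1.2, fragment mode within 146 ± 20 bp, periodicity ≥ 0.08
(about twice the flat-spectrum expectation of the 9–11 bp band fraction,
3/73 ≈ 0.04).  NA values fail conservatively.

**Rank quantiles.**  Per metric, samples are ranked with the
metric-appropriate direction (coverage, periodicity, depletion and
enrichment descending; length-deviation and fuzziness ascending), average
ranks on ties, and `quantile = 1 − (rank − 1)/(n − 1)` (single ranked
sample → 1.0; NA → 0, excluded from ranking).  Quantiles are
permutation-equivariant and invariant to monotone rescaling of a metric.

## Ranking, pooling, reference selection

Within a (cell type, treatment) group: `N_good` = Pass count (0–5),
`C_better` = number of metrics whose quantile strictly exceeds the group's
mean quantile for that metric (sample included in the mean; a singleton
group therefore scores 0), `R_better` = sum of the six quantiles.  The
ordering is the descending lexicographic sort on (N_good, C_better,
R_better); residual ties break on coverage fold, then sample id, making
the order total and invariant to input permutation.

Pooling: occupancy is averaged in non-overlapping 1 kb windows over the
genome; windows with zero occupancy in both members of a pair are dropped
from that pair's Pearson correlation (shared unmappable regions are not
agreement).  Pools are single-linkage connected components of the
r > 0.6 graph with ≥ 2 members — "pooled with" is read as transitive.
The pooled sample is the union of member fragment sets, so its coverage
fold is the sum of member folds.

Selection: the top-ranked sample is the reference unless it belongs to a
pool, in which case the pooled sample is.  The five-fold coverage filter
applies to the final candidate (high-quality or pooled), not to ranking
membership; a group whose candidate falls below five-fold gets no
reference.

## Per-locus features

**Depletion level** at a site point: `N_center` = max occupancy on
[site − 100, site + 100), `N_background` = max over [site − 300,
site − 100) ∪ [site + 100, site + 300).  If the center exceeds the
background (or the background is zero) the value is 0, else
`1 − N_center/N_background` — always in [0, 1).  The "central 200 bp bin"
and its flanks are anchored on the site point as [−100, +100) and
[−300, −100) ∪ [+100, +300).

**Occupancy** at a site: mean over [site − 50, site + 50).

**Array score**: mean array signal over the strand-aware 1 kb window on
the requested side of the site, divided by the genome-wide mean array
signal (a ratio; 1 = genome-typical).

**Position calling**: the occupancy profile over the 1 kb scan (downstream
on the anchor's strand; upstream mirrored for DHS scans) is smoothed with
a centered 50 bp moving average (edge-truncated; the window is shorter
than any credible inter-nucleosome distance).  Candidates are strict
local maxima, plateaus yielding their leftmost base; a maximum at offset
0 is excluded so the +1 search domain is strictly downstream.  Candidates
below 25 % of the tallest candidate are discarded: without a height
floor, background sampling noise inside NFRs produces spurious "+1"
calls at noise amplitude (the floor is configurable; 0 disables it).
Finally, while any adjacent pair of calls is closer than 100 bp, the
globally lowest call among violators is removed (equal heights drop the
call farther from the anchor), which is order-independent; surviving
calls are therefore always ≥ 100 bp apart.

**Linker statistics**: with ordered positions, the first is the +1 (or −1
upstream) nucleosome; linker length = mean adjacent spacing − 147 bp of
nucleosomal DNA (values in [100, 147) bp spacing give negative linkers,
reported as computed); linker SD = population SD of the spacings.
Sentinels: no position → +1 = linker = SD = −1; fewer than 2 positions →
linker = SD = −1; fewer than 3 → SD = −1.  TSS records scan downstream
strand-aware; DHS records (unstranded, anchored at the narrowPeak summit
when a valid 10th column exists, else the interval midpoint) add the
mirrored upstream scan and upstream array score.  Sites whose windows
leave the chromosome produce NA records, logged.

## TF binding prediction

Motif hits (with scores) are labeled bound iff they intersect ≥ 1 bp of
any peak (half-open intervals; touching is not overlap).  Predictors at
the hit center, unstranded: motif score, depletion level, occupancy, and
upstream/downstream array scores — computed by the same locus-feature
operations.  Two logistic regressions (motif-only; full) are fitted by
maximum likelihood on identical stratified k-fold splits (default 10
folds, seed 1234; folds are reduced with a log message when a class is
smaller than the fold count; non-convergence, e.g. perfect separation,
falls back to a weak ridge penalty, C = 1e6).  Out-of-fold probabilities
are pooled and the AUC computed as the rank statistic (equivalently the
normalized Mann–Whitney U; per-fold AUCs are also reported).
`auc_improvement = AUC(full) − AUC(motif-only)` on the pooled out-of-fold
AUCs.  Classification metrics (sensitivity, specificity, precision, F1,
FPR) are evaluated at probability 0.5.  Reported coefficients come from a
full-data maximum-likelihood fit with standard errors; when that fit is
degenerate, ridge coefficients without SEs are reported instead.

## Synthetic data

`simulate_sample` places TSSs and DHSs on a deterministic interleaved
grid (margins 5 kb), builds nucleosome dyad positions as arrays flanking
a nucleosome-free region (default NFR 250 bp, so the +1 dyad sits at
NFR/2 + 73 = 198 bp; repeat length 190 bp; 5 nucleosomes downstream, 2
upstream of TSSs, 5 on each side of DHSs), with optional per-step
random-walk jitter of the array positions (phase decays away from the
anchor, as in real chromatin).  Fragments have Normal(147, 15) lengths
truncated to [80, 250] and are centered on dyads with a midpoint
dispersion composed of a 10 bp-quantized rotational component (SD 10 bp;
nucleosomes slide preferentially in helical-twist frames, which preserves
dinucleotide phase) plus a small continuous component (SD 2.5 bp); a
configurable fraction (default 20 %) is uniform background.  The genome
sequence is random with AA planted every 10 bp inside nucleosomal DNA
(dyad ± 73 bp) so the periodicity QC has signal.  Binding data draw hit
positions half at NFR anchors and half uniformly, score them
Normal(10, 2), and assign bound labels Bernoulli(σ(intercept + β·x)) on
the natural predictor scales (a None intercept is centered at the median
of the linear predictor for balanced classes); peaks are ±150 bp around
bound hit centers.  Outputs are byte-identical given the seed.

What the generator does **not** emulate: sequence-dependent nucleosome
affinity, MNase digestion bias, chromatin domains and copy-number
structure, mappability gaps, or correlated biological replicates beyond a
shared dyad grid.  Passing tests therefore demonstrate the correctness of
the decision rules and estimators under the stated generative model, not
the calibration of the default Pass thresholds on real libraries.

## Problem sizes and defaults

Default synthetic samples use 2 × 150 kb chromosomes, 30 TSSs, 20 DHSs
and 60 000 fragments (~29-fold coverage) — deep enough that per-locus
features are stable while the full test suite and the acceptance script
run in well under a minute each.  Model-evaluation tests use 1 000–5 000
motif hits and 10-fold CV.  All randomness flows through explicit seeds;
the acceptance script derives every simulation from its `--seed`
argument.

## Known limitations

- The occupancy and array-signal constructions are principled stand-ins
  for upstream-pipeline definitions that are not restated here; both are
  isolated behind the `SignalTrack` role tag and can be swapped.
- Four of the five Pass thresholds are package defaults, not published
  cutoffs, and are labeled as such in reports.
- The dinucleotide QC reads the genome into memory per chromosome and
  subsamples fragments; for very large genomes a streaming implementation
  would be preferable.
- bigWig writing depends on the installed pyBigWig build; bedGraph is the
  canonical interchange format.
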