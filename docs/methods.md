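# Methods

This note documents the statistical procedures implemented in
`primedpeaks`, the choices made where the design was genuinely open, what
the synthetic-data generators emulate, and known limitations.

## Coordinates and peak annotation

All intervals are 0-based half-open (BED convention) and are read/written
without shifting. The anchor point for TSS distances is the peak summit
when present, otherwise the interval midpoint (floor); summits mark the
accessibility maximum and are the better proxy for the regulatory signal.
Signed distances are strand-oriented (negative = upstream of the gene), so
a peak 3 kb genome-left of a minus-strand TSS is +3 kb (downstream).
Equidistant TSSs are resolved by lexicographically smallest gene id, purely
for determinism. Peak merging unions overlapping **and** book-ended
intervals (standard merge semantics) and drops summits of fused peaks;
blacklist removal uses any-overlap (≥ 1 bp) semantics, the conservative
reading. Window filters (±8 kb regulatory, ±2 kb promoter) are inclusive
at the boundary.

## Paired-motif enrichment

Scanning is plain log2-odds against a background base composition, both
strands, with minus-strand windows scored against the reverse-complement
matrix and offsets reported on the forward strand. Windows containing N are
skipped. The default scan threshold is 6.0 log2-odds; a fixed documented
threshold keeps runs reproducible where an external scanner's defaults
would not be.

Per peak and motif, the occupancy score is
`−log10 P(X ≥ k)` with `X ~ Binomial(n, p_bg)`, `k` the hit count and
`n = 2·max(0, L − w + 1)` the scanned positions. It is computed in log
space (logsumexp over tail pmf terms) and is exactly 0 at k = 0. The
background rate `p_bg` is estimated empirically as total hits of the motif
across the universe divided by total scanned positions, floored at 1e-9 —
an empirical rate makes the score self-calibrating across motifs of
different information content. Ranking uses hit counts by default
(`rank_by="score_sum"` is available for sensitivity analysis).

"Peaks containing both motifs" is operationalised strictly as the
intersection of the two motifs' top-N ranked sets (N = 5000 by default,
clipped to the universe); raw-hit presence is available behind
`pair_mode="presence"`. The enrichment of a test gene set's peaks within
that intersection is the upper-tail hypergeometric probability, and
q-values are BH-adjusted across all C(M,2) unordered pairs (self-pairs
excluded; the pair matrix is symmetric). On the 600-peak synthetic
universe the tests and the acceptance script use top_n = 150: clipping the
production default of 5000 to a 600-peak universe would make every top set
the whole universe and void the statistic.

## Cross-species promoter linkage

"Relative distance in relation to the TSS" is read as |d_a − d_b| of
strand-oriented signed summit-to-TSS distances — the only reading that
makes a 500 bp tolerance meaningful across species. When a gene has
several promoter peaks, only the |d_a − d_b|-minimising combination is
kept (one pair per ortholog), preventing double-counting in the paired
test; ties break on peak names. Accessibility per matched peak is the
count of read 5′ positions in summit ± 50 bp (inclusive), normalised to
reads-per-million over the matched set.

The paired comparison is a one-sample Wilcoxon signed-rank test on
per-pair differences: zero differences discarded, average ranks on ties,
tie-corrected variance, 0.5 continuity correction, two-sided normal
p-value. All-zero differences return p = 1 with a degenerate flag. The
normal approximation is accurate to a few percent against the exact 2^n
sign-permutation distribution for mid-range p at n ≈ 6–10, but can deviate
by ~25% in the extreme tail at such small n; production use compares tens
to hundreds of matched pairs, where the approximation is excellent. Note
also that RPM normalisation couples the pairs (differences sum to zero),
which makes the null slightly conservative — observed null exceedance of
p > 0.05 is ~97% rather than 95%.

## Differential accessibility

The test is a documented simplification of an exact NB test with
dispersion machinery: replicate counts are rescaled to the geometric-mean
library size, summed per group and rounded half-to-even; conditional on
the total `s`, the null distribution of one group's sum is
`P(y) ∝ f(y; m, φ_s) f(s − y; m, φ_s)` with `f` the NB pmf at mean
`m = s/2`. Because the sum of n i.i.d. NB(m, φ) draws is NB(nm, φ/n), the
per-replicate dispersion (config default 0.05; a method-of-moments
estimate is available) is divided by the replicate count before the
conditional computation. Two-sidedness follows the minimum-likelihood
rule (sum all outcomes with probability ≤ observed, with the customary
1e-7 float slack); φ = 0 reduces exactly to the two-sided Binomial(s, ½)
test. Exact reproduction of any particular published peak count is not a
goal of this simplification. PCA input selection takes the top-k
(default 500) rows by variance of log2(x+1), ties by peak id; PC signs are
fixed so each component's largest-magnitude loading is positive.

## Footprints and insert-size QC

Raw alignments are reduced to Tn5 insertion points with the standard
+4/−5 strand offsets; pre-shifted 1-bp BED input bypasses the shift.
Average profiles accumulate per-bp cut counts per strand over windows
[start − F, end + F) (F = 100 bp default), orienting minus-strand motif
instances by reversal and strand-label swap, weighting each instance
equally, and dividing by the number of usable instances (windows crossing
the chromosome start are dropped).

The insert-size estimator histograms lengths 1–1000, detrends the
40–250 bp range with a 21-bp centred moving average (edges trimmed), and
takes the dominant period as the argmax of the normalised autocorrelation
over 8–15 bp lags, refined by parabolic interpolation to 0.1 bp. The
search band targets the DNA helical pitch; the ~200 bp nucleosome
spacing is visible in the raw histogram but deliberately not estimated.
When no lag in the band exceeds a 2/√n noise level on the normalised
autocorrelation the result is None rather than a spurious period.

## Expression programs

Quantile normalisation is the classic column-rank procedure; tied values
receive the mean of the reference values their ranks span. Differential
testing is a pooled-variance t-test per probe (df = n_a + n_b − 2) with BH
correction; fold changes are median ratios reported with the
negative-reciprocal convention (r < 1 ⟶ −1/r, so 0.5 becomes −2). The
filter is strict: q < 0.05 AND ratio > 1.5 (up) or < 1/1.5 (down); the
boundary values are excluded. Gene collapse takes unique gene ids of
qualifying probes; a gene with discordant probes appears in both sets
(a strict mode drops it from both).

Clustering log2-transforms, median-centres each row, drops zero-variance
rows with a warning, and applies average-linkage agglomeration on
one-minus-Pearson distances, cutting to k clusters (default 4). Labels
are canonicalised by descending cluster size, then first row id. Both
per-sample columns and per-group medians are valid inputs.

The module score bins genes into 24 equal-frequency bins of dataset-average
expression, draws 100 control genes (with replacement) per module gene
from the gene's own bin, and reports per-cell mean module expression minus
mean control expression; fully seeded.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed); one global seed
fans out to per-output streams through a fixed counter scheme, so adding
an output never perturbs existing ones. Defaults are the study conditions
the tests assume:

- **Genome/peaks**: 2 × 1 Mb chromosomes of i.i.d. sequence (GC 0.42), 60
  genes, 600 peaks whose summit-to-TSS distances are N(0, 3 kb) truncated
  at ±8 kb. No repeats, CpG islands or mappability structure.
- **Motifs**: eight sharp 8-mers (0.91 consensus probability per
  position); the planted pair is co-inserted in test-gene peaks at rate
  0.6 (0 = null) in disjoint peak halves, all motifs background-inserted
  at 5% per peak; insertions never overwrite one another (an insertion
  that finds no free room is skipped and omitted from the truth table).
- **Counts**: 2000 peaks, 3v3 replicates, lognormal base means (median
  ~55), NB dispersion 0.05, ±15% library-size jitter, 30 differential
  peaks at |log2FC| = 2, half up, half down.
- **Cut sites**: 500 motif instances; per-bp Poisson cuts at rate 0.5 per
  strand on flanks and rate·(1 − δ) over the motif core (δ = 0.6), so the
  realised dip depth equals δ. Fragment lengths follow an exponential
  decay modulated by a cosine of period 10.4 bp (amplitude 0.25); no Tn5
  sequence bias is simulated.
- **Two species**: 120 one-to-one orthologs, one promoter peak each side
  with relative TSS offsets within ±300 bp (matched by construction),
  Poisson reads around summits from a shared per-gene intensity; the
  flagged subset (40 genes) gets 2^shift-fold species-B control reads
  (shift 1.0 by default, 0 = null).
- **Expression**: four temporal programs over {P5-ctrl, P5-trt, P10-ctrl,
  P10-trt} × 6 replicates — immune-like (developmentally down, boosted by
  treatment at P5), cell-cycle-like (down by P10, persisting under
  treatment), myelination-like (up by P10, blunted there, no P5 effect),
  and early-down — 50 genes per program plus 400 flat genes, 1–3 probes
  per gene (~1200 probes), probe offsets sd 2.0, noise sd 0.3 (0.2 in DE
  checks). The planted truth derives analytically from each gene's
  amplitude-scaled pattern against the log2(1.5) threshold.

Passing tests on these fixtures demonstrate the correctness and
calibration of the *procedures*, not performance on real data: real
chromatin has correlated noise, GC and Tn5 bias, non-1-to-1 orthology and
probe cross-hybridisation that the generators deliberately omit.

### A note on quantile normalisation at miniature scale

The expression fixture keeps planted up- and down-mass at P5 comparable
and the DE fraction minor, because quantile normalisation assumes mostly
unchanged distributions. Even so, at ~1200 probes the rank "ripple" from
one program's coherent shift can push of order 1% of flat probes past the
−1.5 fold-change threshold: the UP probe count is recovered within ±5% at
noise 0.2, while the DOWN count can overshoot by ~10–30% from these
artefactual calls (all planted DOWN probes are themselves recovered). A
real 60k-probe array dilutes the ripple by an order of magnitude. The
tests therefore pin UP recovery tightly and DOWN recovery as a superset.

## Problem sizes

Unit and property tests run on the generator defaults above; replicated
checks use 20 seeds for recovery rates and 100 seeds for null calibration
(200 for the uniformity property), with the PMET fixture at a 600-peak
universe and top_n 150. These sizes make the full suite and the
acceptance script each complete in a few minutes on a single CPU while
leaving every statistical margin comfortably resolved.
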