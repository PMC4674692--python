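# Methods

This document records the statistical models, algorithmic conventions,
default parameters, and numerical choices behind each module, plus the
scope and limitations of the synthetic-epigenome generator.

## Conventions

- All genomic intervals are **0-based, half-open** `[start, end)`. BED and
  bedGraph I/O follow that convention natively; gene tables use a
  strand-dependent TSS (`start` for `+`, `end` for `-`).
- Interval midpoints are `(start + end) // 2` (integer floor).
- Signal tracks are fixed-bin vectors per chromosome (`bin_size` bp per
  bin). `quantify` pro-rates partially covered bins by the covered
  fraction, so quantification is exactly additive over any partition of an
  interval.
- Library normalization is per-million: normalized = raw × 1e6 / library
  total. Tests assert that normalized genome-wide totals are equal across
  conditions to floating-point precision.
- All stochastic components (simulator, k-means restarts) are driven by
  explicit seeds through `numpy.random.default_rng`; identical seeds yield
  byte-identical output files.

## Differential calling (`epireprog.clusters.call_differential`)

For region counts x (condition) and r (reference), the test conditions on
the total n = x + r: under the null of equal per-million activity,
x ~ Binomial(n, p0) with p0 = L_x / (L_x + L_r), the condition's share of
the combined library. Two-sided exact p-values (`scipy.stats.binomtest`)
are Benjamini–Hochberg corrected across regions
(`statsmodels.stats.multitest.multipletests`). A region is *called*
(direction "up"/"down") only when q ≤ α (default 0.05) **and** the
normalized, pseudocounted fold change satisfies max(fc, 1/fc) ≥ min_fc
(default 2.0, pseudocount 1.0). The conditional binomial is the exact
analogue of a two-library count ratio test and is calibrated under
Poisson sampling: on a Poisson(100) null the empirical call rate is ≈ 0
at these settings, and power at a planted four-fold change is ≈ 1
(see `scripts/acceptance.py`).

## Co-variation clustering (`cluster_covariation`)

Each pooled region's profile is log2(normalized + pseudocount), z-scored
per region, so clustering responds to profile *shape* only. Zero-variance
profiles receive the reserved label 0 and are excluded from k-means.
K-means (`sklearn.cluster.KMeans`, `n_init=10`, fixed `random_state`) is
run on the z-scores; labels are renumbered by descending cluster size so
label 1 is always the largest cluster. Patterns differing only by a
constant offset are indistinguishable after standardization — by design:
amplitude is analyzed separately (expression coupling, signatures).
Cluster quality versus planted truth is measured with the adjusted Rand
index; `silhouette_scan` supports choosing k on real data.

Downstream, clusters are deconvoluted into TSS-proximal (midpoint-to-TSS
distance ≤ 2,500 bp, inclusive) and TSS-distal elements, proximal elements
are assigned their nearest TSS (ties to the smaller TSS coordinate, then
lexicographic gene id), per-cluster expression is summarized as the median
linear FPKM, and per-condition signatures take the top decile
(ceiling) of genes by log2((FPKM_cond + 0.1)/(FPKM_ref + 0.1)) among
up-regulated genes. Signature scoring z-scores log2(FPKM + 0.1) per gene
across samples and averages over signature genes; high/low groups split at
the median (ties to low).

## Super-enhancers (`epireprog.superenhancers`)

Peaks are stitched when the inter-peak gap is ≤ 12,500 bp (gap ≤ 0 means
touching or overlapping; `stitch_bp = 0` still fuses book-ended peaks).
Peaks fully contained in a TSS ± 2,500 bp window are excluded before
stitching. Stitched enhancers are ranked ascending by total signal; both
the rank axis and the signal axis are min–max scaled to [0, 1], and the
elbow is the index maximizing (scaled rank − scaled signal), ties broken
to the largest index. An enhancer is an SE iff its rank index exceeds the
elbow; a perfectly linear signal curve therefore yields zero SEs. This is
the standard tangent-line ("hockey-stick") cutoff; both the elbow and the
SE set are tested against brute-force maximization over all indices.
Recovery of planted SEs depends on the typical-signal tail: with
uniform typical signals the planted boundary is recovered exactly, while
heavy-tailed typicals bleed extra calls below the elbow — a property of
the method, not of this implementation.

Condition-specific SE calls are merged (union of overlapping spans) into a
catalogue with a per-condition boolean membership matrix, quantified, and
clustered with the same co-variation machinery. Peak–valley–peak
decomposition finds plateau-aware local maxima within an SE, keeps summits
≥ 25% of the SE maximum, and reports, between each adjacent summit pair,
the maximal run of bins strictly below 50% of the lower summit containing
an interior minimum.

## Footprints and motifs (`epireprog.footprints`)

Candidate windows slide across accessible intervals with stride equal to
the center width (default 20 bp), requiring full flanks (default 100 bp)
inside the interval. The footprint score is
(mean flank cuts/bp + 1) / (mean center cuts/bp + 1): > 1 indicates
central depletion, the +1 regularizer shrinks low-coverage windows toward
1 and makes the zero-coverage score exactly 1. The top-N windows by score
(ties by genomic order) are retained per condition.

PWMs are column-stochastic probability matrices; consensus-derived PWMs
place 1 − 3·pseudo on the consensus base. Scanning scores every window on
both strands as Σ log2(p_b / 0.25) against a uniform background and
reports matches ≥ threshold (default 6 bits) with forward-strand
coordinates; windows containing non-ACGT bases never match. The scanner is
tested for exact equality against a per-window brute-force oracle.
Motif-presence counts between two conditions are compared with Pearson's
χ² on the 2×2 table without continuity correction
(`scipy.stats.chi2_contingency(correction=False)`); the (10,90) vs
(30,70) example equals the closed form 12.5 exactly.

## TAD decomposition (`epireprog.tads`)

Per-TAD aggregates are per-million-normalized sums; TADs below a minimum
signal density (default 1.0 per kb in both conditions) are dropped. The
TAD ratio is (agg_cond + pc)/(agg_ref + pc). Ranking is descending by
ratio, ties by genomic coordinate; percentile = 100·(rank − 1)/N, and
`top5` marks percentile < 5. Gene decomposition compares the gene's local
log2 change (over its promoter-proximal regions) with its host TAD's
aggregate log2 change using a symmetric threshold τ = log2(1.2):

1. |local| ≤ τ → `neutral`;
2. else |global| ≤ τ → `punctuated_amplified`;
3. else same sign → `concordant_passenger`;
4. else → `punctuated_opposed`.

With 500-bin TADs at ~25 counts/bin, the planted 0.8× TAD's log2 ratio
sits ≈ 3σ below −τ, which is what makes the ≥ 99/100 punctuated
classification rate achievable; substantially smaller TADs or shallower
coverage would erode that margin.

## Synthetic epigenome (`epireprog.simulate`)

One seed drives every draw. Chromosomes have fixed roles: chr1 carries the
planted cluster regions, genes, and footprint sites; chr2 the SEs and
typical peaks; chr3 the TADs.

- **Counts**: each condition's H3K27ac track is an independent Poisson
  draw per bin (default 200 bp) around a mean field. Background mean is
  `background_rate` (default 25/bin).
- **Cluster regions**: 1-kb regions at a fixed pitch; each planted pattern
  is a vector of per-condition multipliers; every region also gets a
  lognormal amplitude (sd 0.4) shared across conditions, so z-scored
  profiles are unchanged but absolute activity varies and correlates with
  expression.
- **SEs**: groups of constituents (5 × 1 kb, 3 kb apart) at 15× background
  plus typical 2× peaks; constituent spacing is below the stitch gap and
  region pitch is above it, so planted SEs stitch and cluster regions do
  not.
- **TADs**: one TAD is shifted uniformly (1.5×) in the shift condition; a
  second is *punctuated*: its whole-TAD per-million ratio nets to 0.8×
  while a 1-kb interior window is raised 4×, with the remaining bins
  compensated so the net ratio is exact in expectation.
- **Expression**: FPKM = scale · activity^exponent · lognormal(0, sd)
  per gene/condition, where activity inherits the region's pattern
  multiplier and amplitude; the punctuated gene follows its local window,
  opposing its TAD.
- **Footprints**: accessible windows around motif-bearing sites carry
  uniform DNase cut density; only in the footprint condition is the
  central 20 bp depleted (×0.1). The accessible half-width is aligned so
  one sliding window lands exactly on the depleted center. The genome
  FASTA embeds the motif consensus at each site center.
- **Ground truth** (region→pattern labels, SE spans, TAD identities,
  punctuated gene, footprint windows, motif positions) is serialized as
  JSON next to the data.

**Scope and limitations.** The generator is a test harness, not a
biophysical model: bins are independent Poisson draws (no read
autocorrelation, fragment-length effects, GC bias, or copy-number
structure); peaks are rectangular; TADs are abutting fixed-width tiles;
expression depends on promoter activity through a single power law; the
DNase model has flat accessibility and a single motif. Conclusions about
the *methods'* correctness transfer to real data; simulated effect sizes
and error rates do not.

## Numerical choices

- Pseudocounts: 1.0 on fold changes and TAD aggregates (count scale),
  0.1 on FPKM log-ratios, +1 per-bp in footprint scores, configurable
  (tiny values recover pure ratios in tests).
- Ties are always broken deterministically (largest index at the elbow,
  genomic order for footprints and TAD ranks, smaller TSS then gene id for
  nearest-TSS), so outputs are order- and rerun-stable.
- bedGraph values are written with `%g`; files round-trip bit-identically
  for the integer-valued Poisson tracks used throughout.
- Manifest checksums are SHA-256 over output bytes; determinism claims in
  the README are asserted at that level.
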