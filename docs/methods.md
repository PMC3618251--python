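# Methods

## The statistic

The analysis targets promoters with the *prototypical methylation
pattern* (PMP) of cancer/testis antigen (CTA) genes: unmethylated in
sperm, methylated in normal somatic tissue, unmethylated again in
tumors. Given a beta-value matrix **B** (loci × samples, values in
[0, 1]) and a class label per sample (germline, somatic-normal, tumor),
the PMP reference vector **v** has one entry per sample:

* `minmax` mode (default): `v_i = min_j B_ji` for germline and tumor
  samples, `v_i = max_j B_ji` for somatic normals. Using each sample's
  own extremes rather than constants keeps the reference on the
  sample's measured intensity scale.
* `binary` mode: 0 for germline/tumor, 1 for somatic-normal.

PMP-sim of locus *j* is the Pearson correlation `S_j = cor(B_j·, v)`
over pairwise-complete samples. `S_j` is reported missing when either
side has zero variance on the observed samples or fewer than
`min_samples` (default 30) samples are observed; Pearson correlation is
undefined at zero variance and unstable below that support. PMP-sim is
invariant under strictly increasing affine transforms of **v**, which
is why the two vector modes rank loci near-identically.

## Group comparisons

All two-group comparisons are two-sided Mann–Whitney U tests. When
`n_a·n_b ≤ 400` the exact null distribution is used: scipy's exact
method for tie-free pooled samples, full enumeration of rank splits
when ties are present and `C(n, n_a) ≤ 2·10^5`. Otherwise the
tie-corrected normal approximation without continuity correction is
used and flagged `NORMAL_APPROX`. Exact-with-ties beyond the
enumeration limit falls back to the normal approximation; with group
products that large the approximation error is negligible.

## Robustness controls

**Within-series permutation.** For each locus and each series (batch)
independently, the values across the series' samples are uniformly
shuffled (missing values travel with the shuffle, so every
(locus, series) value multiset is preserved exactly). This destroys
tumor/normal identity while preserving series-level biases; surviving
PMP-sim reflects batch structure, not biology. A residual positive
mean remains even after permutation because series differ in their
tumor/normal composition (and one series is all sperm), which couples
series-level means to the reference vector; the control is judged by
the collapse of the planted/CTA signal toward that floor, not to zero.

**Stratified subsampling.** Samples are redrawn without replacement
per (series, tissue, class) stratum to confirm scores are not driven
by the largest series.

## Genomic clustering

Loci with non-missing PMP-sim are binarized at the top-`pct` percentile
(default 20%) and ordered along the genome within a CGI or non-CGI
subset (adjacency is within-subset). The threshold is the
`(100−pct)`-th linear-interpolation percentile; ties at the threshold
are all included, so the ones count can exceed `pct`%. Percentile
scope is `PER_SUBSET` by default with a `GLOBAL` option (the LAD
analysis uses `GLOBAL`, matching its combined high-PMP locus set);
both are emitted because the two conventions give different subset ones
counts and neither is canonical. A *run* is a maximal stretch of
consecutive ones; runs never span a chromosome boundary, since genomic
adjacency is undefined across chromosomes. Headline statistics are
reported both for all runs and for runs of length ≥ 2: the mean over
all runs is the quantity the permuted control calibrates, while the
mean over runs ≥ 2 describes the clustered fraction.

The permutation null shuffles the bit vector uniformly (ones count
preserved, positions fixed). For `m` ones in `n` slots the expected
number of runs is `m(n−m+1)/n`, so the null mean run length is
approximately `n/(n−m+1)` ≈ 1.25 at 20% ones; the simulation agrees
with this closed form and with the published permuted controls. Class
membership (fraction of CTA/CTX loci inside runs ≥ 2) is compared to
the same shuffled null via a z-score with a one-sided upper-tail
normal p; a degenerate null (sd = 0) yields flagged missing values.

## Boundary contrast (delta-PMP)

For a candidate boundary point (CTCF site or LAD edge), the `k = 3`
nearest genes by TSS on each genomic side with a measured,
non-missing-sim locus in the active subset form the flanks; delta-PMP
is `|mean(left sims) − mean(right sims)|`. Sites need at least one
gene per side; a gene whose TSS coincides with the site belongs to
neither side; when a gene has several probes the one nearest its TSS
represents the promoter. Genomic left/right is used for 5'/3' because
site strand is unknown. The control draws the same number of positions
uniformly from each chromosome's TSS span, chromosomes weighted by span
length; observed and control deltas are compared by Mann–Whitney. LAD
boundaries are analysed by treating both ends of each merged LAD
interval as sites.

## LAD overlap

Loci are flagged in/out of merged, half-open LAD intervals
(`start ≤ pos < end`). Enrichment of high-PMP loci inside LADs uses
Fisher's exact test on the 2×2 of high-PMP × in-LAD, two-sided by the
convention of summing hypergeometric probabilities no larger than the
observed table's; the sample odds ratio `ad/bc` is reported (missing on
a zero margin). PMP-sim inside vs outside LADs uses the shared
Mann–Whitney machinery.

## Synthetic methylomes

The generator emulates a 27K-style promoter array compendium at desk
scale: 3 chromosomes of 30 Mb, 3000 loci at ≥1 kb spacing, five series
whose sample counts are proportional to the 501-sample compendium the
package miniaturizes (24 somatic normals, 33 tumors, 3 sperm). Planted
PMP loci (mean beta 0.15 in germline/tumor, 0.85 in somatic normal)
are clustered into 48 non-overlapping domains of 5 loci (80% planted
inside a domain). The domain scale mirrors the observed run-length
scale of the real phenomenon (subset runs of ~2–4, range up to ~15),
which also keeps locus-level tests honest: much coarser clustering
makes Fisher's test on loci strongly anticonservative. Background loci
are constitutively low (0.10) or high (0.85); CGI labels are biased
toward constitutively-low loci. Values are Beta-distributed around the
role/class mean (concentration 20), shifted on the logit scale by a
per-(series, locus) batch effect (sd 0.8) and per-cell noise (sd 0.8),
then clipped to [0, 1]. Batch shifts at this scale are what makes the
within-series permutation control informative; per-cell noise is at
inter-individual tissue-variability scale. Tumors are a mixture: each
tumor hypomethylates each planted locus with probability 0.7,
mimicking heterogeneous derepression. 1% of cells are masked missing.
CTA labels are assigned to in-domain genes with probability 0.3 (CTX
on the X-like chromosome); TSSs sit a fixed 100 bp from the probe on
the annotated strand. One LAD is generated per domain, covering it
(with 500 bp padding) with probability 0.8, otherwise placed uniformly
on the same chromosome; `lad_random_placement=True` forces the
independent-placement calibration scenario.

What the generator does **not** emulate: probe-level CpG density and
probe affinity artifacts, genome-scale chromosome counts, copy-number
or purity variation in tumors, and correlated (smoothly varying)
methylation outside planted domains. Passing recovery tests therefore
demonstrates that the pipeline's machinery is correct and well
calibrated under realistic batch/noise structure — not that effect
sizes on real arrays will match.

## Numerical and design choices

* Coordinates are 0-based, half-open throughout; BED is consumed
  natively; chromosomes sort naturally (1..22, X, Y, then others).
* Missing beta values are empty TSV fields; no sentinel inside [0, 1].
* The minmax reference uses all loaded loci, not a subset.
* Correlations clip to [−1, 1] to absorb floating-point overshoot.
* Every stochastic operation takes an explicit seed
  (`numpy.random.default_rng`); identical config + seeds give
  byte-identical pipeline output.
* Problem sizes in the test-suite recovery studies: 10 generator seeds
  for recovery metrics, 200 seeds for false-positive calibration,
  200–500 shuffles for permutation nulls — sizes at which the measured
  quantities are stable to well within the asserted margins.

## Known limitations

* Exact Mann–Whitney with heavy ties beyond the enumeration limit is
  approximated (flagged in the output).
* The run analysis treats the array's locus ordering as the genome
  metric; physical gaps between adjacent loci are ignored, as in the
  original run-of-ones formulation.
* delta-PMP is unsigned; it detects contrast, not direction.
* Fisher's exact test assumes independent loci; under strong spatial
  clustering of high-PMP loci it becomes anticonservative. The
  calibration study bounds this at the generator's realistic domain
  scale but it will re-emerge on data with much broader hypomethylated
  blocks.
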