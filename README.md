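# pmpscan

Analysis of the **prototypical methylation pattern** (PMP) of
cancer/testis antigen (CTA) promoters on promoter CpG methylation
arrays: unmethylated in sperm, methylated in normal somatic tissue,
unmethylated again in cancer. The package is for computational
epigenomics work on beta-value matrices (27K-style promoter arrays)
with germline, normal and tumor samples, and answers four questions:

1. **Which loci follow the pattern?** Per locus *j*, PMP-sim is the
   Pearson correlation `S_j = cor(B_j·, v)` between the locus's beta
   values across samples and a PMP reference vector `v` that is low
   (column minimum, or 0) in sperm/tumor samples and high (column
   maximum, or 1) in somatic normals. Robustness controls: a
   within-series permutation that destroys tumor/normal identity while
   preserving batch structure, and stratified subsampling.
2. **Are they clustered on the genome?** Loci in the top 20% of
   PMP-sim are marked 1 in a genome-ordered binary vector (separately
   for CGI and non-CGI promoters); maximal runs of ones are compared
   against uniformly shuffled controls, whose mean run length is
   `n/(n−m+1)` ≈ 1.25 at 20% ones.
3. **Do insulators separate them?** delta-PMP at a CTCF site (or LAD
   edge) is the absolute difference in mean PMP-sim between the three
   nearest measured promoters on each side, versus random positions.
4. **Do they sit in lamina-associated domains?** Fisher's exact test
   on the 2×2 of high-PMP × in-LAD, plus PMP-sim inside vs outside
   LADs.

Everything runs end-to-end on synthetic methylomes with planted ground
truth (clustered hypomethylation domains, batch effects, boundary
sites, LAD intervals), so each stage's recovery is testable without any
downloads. See `docs/methods.md` for the model and all defaults.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
generated dataset (later scripts read the earlier ones' output):

```sh
python analysis/01_simulate.py            # 3000 loci x 60 samples
python analysis/02_pmp_similarity.py      # PMP-sim + controls
python analysis/03_genome_runs.py         # run-of-ones clustering
python analysis/04_insulator_boundaries.py
python analysis/05_lad_overlap.py
python analysis/06_recovery.py            # multi-seed truth recovery
```

`02_pmp_similarity.py` prints:

```
PMP-sim computed for 3000 loci; overall mean 0.038 +/- 0.204
CTA vs all loci: mean 0.502 vs 0.038, Mann-Whitney p = 1.73e-16 (NORMAL_APPROX)
CTX vs all loci: mean 0.452 vs 0.038, Mann-Whitney p = 4.86e-08 (NORMAL_APPROX)
CTA mean PMP-sim: 0.502 original -> 0.066 after within-series permutation
CTX mean PMP-sim: 0.452 original -> 0.059 after within-series permutation
```

CTA/CTX promoters (planted inside hypomethylation domains by the
generator) score far above the locus background, and the signal
collapses under the within-series permutation — so it is not a batch
artifact. `03_genome_runs.py` then shows the clustering:

```
CGI: 376 ones of 1876 loci (threshold 0.145); 274 runs, 67 of length >= 2 (mean >= 2: 2.522)
  permuted control mean run length 1.250 +/- 0.029; observed-vs-null Mann-Whitney p = 0.0312
  CTA: 0.783 (18 of 23) in runs >= 2; null 0.077 +/- 0.066, z = 10.6, p = 1.27e-26
```

Observed runs are longer than the shuffled control's ~1.25, and most
CTA loci sit inside multi-locus runs. `04_…` and `05_…` close the loop:
delta-PMP at planted domain edges is ~3–4× the random control, and
high-PMP loci are strongly enriched inside LADs (odds ratio ≈ 14 on
this dataset) — the planted genomic organization is recovered by every
stage. All summary tables land under `results/`.

The same pipeline is scriptable on any dataset in the documented TSV
and BED formats via the `pmpscan` CLI
(`pmpscan simulate | pmp | runs | boundaries | lads | all`).

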