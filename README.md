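# splicenoise

De novo splice-junction discovery from short RNA-seq reads and
quantification of **noisy splicing** — the low-level, largely
non-functional use of unintended splice sites by the spliceosome.

Most multi-exon genes show many rare isoforms in deep RNA-seq. The
question this package addresses is how much of that diversity is
splicing *error* rather than regulated alternative splicing, and how to
measure it: junctions are discovered without reference to annotation by
splitting unmapped reads, validated by their intronic dinucleotides,
classified against gene models, stratified by evolutionary conservation,
and summarized into a per-intron splicing error rate with its
correlates. It is aimed at computational biologists studying splicing
fidelity, and at anyone who needs a fully synthetic, truth-tracked
RNA-seq benchmark for junction callers.

## What it computes

- **Split-read junction discovery.** Reads that fail contiguous
  alignment are split into their first/last 20-mers; with both ends
  uniquely mapped 51–20,000 bp apart, every breakpoint with ≥ 10 bases
  of overhang is scored and the minimum-mismatch placements reported;
  with one end mapped, the alignment is extended mismatch-free and the
  remainder must match uniquely within 20 kb. Boundary repeats make a
  read consistent with several shifted intron placements, so each
  junction carries an equivalence class, canonicalized to GT-AG.
- **Control-dinucleotide FDR.** A junction consistent with GT-AG/GC-AG
  is canonical; one consistent only with GT-TC/GC-TC (the acceptor
  consensus complemented) is a control. If all controls are false,
  FDR = n_control / n_canonical — e.g. 4,230 / 306,606 ≈ 1.4%.
- **Junction classes and splice-site usage.** Five-way classification
  against annotation (known junction / known sites newly paired / novel
  3′ / novel 5′ / both novel), per-site partner counts and major-form
  fractions, saturation curves under read subsampling.
- **Splicing error rate.** For introns with both splice sites highly
  conserved, the fraction of reads from either end spliced to
  unconserved (score ≤ 0.5) partner sites. Per gene,
  P(mis-spliced) = 1 − (1 − r)ⁿ over n splicing reactions: r = 0.007,
  n = 3 gives ≈ 2% of transcripts.
- **Reading-frame periodicity.** Minor splice sites near major
  protein-coding sites, normalized by AG/GT opportunity counts per
  offset; one-sided exact binomial test of the in-frame excess against
  1/3 (the signature of NMD removing frame-disrupting errors).
- **Correlates.** Error rate vs intron length and gene expression
  (reads per exonic base, max across samples) in 100 equal-count bins
  with Spearman trend and a GCV smoothing spline; residual correction
  to separate the confounded covariates.
- **Motifs.** Hexamer enrichment in the flanks of unconserved "noise"
  splice sites versus matched unused-dinucleotide decoys (per-hexamer
  2×2 chi-square, Bonferroni over 4⁶), overlap with exonic splicing
  enhancer lists, and positional profiles around constitutive exons.
- **Synthetic data.** A generator producing genome (FASTA), gene models
  (GTF/BED12), a conservation track (bedGraph), variant positions,
  error-bearing transcripts and reads (FASTQ) with full ground truth —
  every estimator above is validated against it.

## Worked example

```python
from splicenoise import SimConfig, run_pipeline

result = run_pipeline(SimConfig(n_genes=100, seed=5),
                      outdir="run", n_junction_reads=150_000)
r = result.report
print("canonical junctions:", r["junctions"]["n_canonical"])
print("fdr:", r["junctions"]["fdr"])
print("fraction_unannotated:", round(r["classify"]["fraction_unannotated"], 3))
print("mean_partners:", round(r["usage"]["mean_partners"], 2))
print("mean_major_fraction:", round(r["usage"]["mean_major_fraction"], 4))
print("global_error_rate:", round(r["error_rate"]["global_error_rate"], 5))
```

prints

```
canonical junctions: 725
fdr: 0.0
fraction_unannotated: 0.594
mean_partners: 1.73
mean_major_fraction: 0.9965
global_error_rate: 0.0066
```

Read it as: from 150,000 junction-spanning reads over 100 genes the
mapper recovered 725 canonical junctions with no control-dinucleotide
junctions (estimated FDR 0); 59% of distinct junctions are unannotated
cryptic junctions but they carry only ~0.7% of junction reads; a splice
site averages 1.73 partners with the major form taking 99.65% of its
reads; and the conserved-to-unconserved read fraction recovers the
generator's per-intron error rate of 0.007 (here 0.0066 at this depth).
The same pipeline is available from the shell:

```bash
splicenoise run --preset default --seed 5 --reads 150000 --out run
splicenoise report run/report.json
```

Presets (`tiny`, `default`, `confounded-expression`, `frame-biased`,
`null`) encode the scenarios the test suite uses; `splicenoise fixture
<preset>` prints the underlying generator configuration.

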