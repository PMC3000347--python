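# Methods

`splicenoise` quantifies "noisy splicing" — the low-frequency use of
unintended splice sites by the spliceosome — from short single-end
RNA-seq reads. Because real deep-sequencing datasets (billions of reads
against a mammalian genome) are far beyond what a test suite can process,
the package pairs every analysis with a synthetic-data generator whose
ground truth makes the estimators testable end to end. This note
documents the model behind the generator, the discovery and estimation
procedures, the numerical choices, and what the tests do and do not
establish about real data.

## The generative model

**Genome and genes.** Genes are placed left to right on one synthetic
chromosome with uniform random intergenic gaps (300–800 bp). Exon count
per gene is 1 + Geometric(p) with p chosen so the mean is 4 (the typical
multi-exon vertebrate gene), clipped to [2, 12]; exon lengths are uniform
on [50, 300] bp; intron lengths are log-normal (median ≈ 365 bp,
log-sd 0.9) clipped to [60, 20000] bp so that every true junction is
discoverable under the mapper's geometric constraints. Sequence is
uniform random ACGT; each intron's boundary dinucleotides are forced, in
transcription orientation, to GT..AG (GC..AG at 3%, the approximate
genome-wide share of GC-AG introns; AT-AC introns are not generated).
Genes fall on either strand with equal probability.

**Expression.** Gene weights are 1 + Pareto(α = 1.2), normalized to mean
one — a heavy-tailed (power-law) expression distribution. The
`expression_length_coupling` knob multiplies the weight by
(mean intron length / median)^(−c), producing the empirically observed
anti-correlation between expression and intron length when a confounded
scenario is needed.

**Splicing errors.** Each pre-mRNA copy splices each intron
independently. With probability ε(intron) the spliceosome uses a cryptic
site instead of a true one; ε is either constant (default 0.007 per
intron — the headline per-intron error rate this package is built to
recover) or affine in log10(intron length) via `error_length_slope`,
clipped to [0, 0.5]. An error event picks a donor-side or acceptor-side
cryptic site among candidate dinucleotides (sense GT for donors, AG for
acceptors) located in the intron (up to 98 bp from the true site) or in
the flanking exon (up to ~30 bp), subject to the resulting intron staying
within 51–20000 bp.

**The proposal kernel and reading frames.** Cryptic sites cluster near
the true site. The kernel weight is geometric across *distance triples*:
weight q^(3·⌊|offset|/3⌋) with q = 0.97, and the support is truncated to
complete triples {3k, 3k+1, 3k+2} on each side (offsets −2..+2 are
excluded as mapping-ambiguous). The triple-constant form, rather than a
plain q^|offset| decay, is deliberate: with support starting at |offset|
= 3, a plain geometric decay gives the frame-preserving class (offsets
±3k) a weighted share of 1/(1+q+q²) ≈ 0.35 rather than 1/3, because the
two offsets of every distance ±3k are both in frame. Truncating to
complete triples with triple-constant weights makes the three frame
classes exchangeable, so with no NMD bias exactly one third of proposed
cryptic sites preserve frame — the null hypothesis the periodicity test
assumes. The clustering across triples still reproduces the near-site
concentration of minor splice sites seen in real data; the exact decay
law of real cryptic sites is unknown, and the profile shapes produced
here are qualitative.

**NMD proxy.** Isoforms whose error disrupts the downstream reading
frame (offset not a multiple of 3) survive to the sequenced pool with
probability `frame_bias` relative to frame-preserving errors; degraded
transcripts are removed, not resampled. This is a survival multiplier,
not a mechanistic PTC model — sufficient to induce the in-frame excess
among observed minor sites that the periodicity analysis detects.
`frame_bias = 1` (default) disables the proxy; note that thinning with
`frame_bias < 1` lowers the realized error-read fraction below ε.

**Conservation track.** Per-base scores emulate a phyloP-like signal:
exonic bases and the two canonical dinucleotide bases of every true
splice site are drawn from N(2.0, 0.3); everything else — including the
dinucleotide bases of every cryptic candidate, even when they fall
inside exons — from N(0.05, 0.15). The carve-out at cryptic dinucleotides
encodes the biological premise under test (error sites are not
conserved) and keeps the conserved-to-unconserved estimator unbiased for
ε; without it, exonic cryptic sites would inherit exonic conservation
and be silently excluded from the numerator.

**Polymorphism.** Variant positions fall uniformly at 10⁻³ per base,
except at true splice-site dinucleotides, which are monomorphic
(purifying selection); cryptic sites get no protection.

**Reads.** Junction-spanning reads (46 bp default, also 35 bp) are
generated per junction variant: counts are Poisson with mean
depth × expression weight (or rescaled to a requested total), the
breakpoint is uniform over spanning positions, and per-base substitution
errors occur at 10⁻³. Read ids encode the source gene, intron, splice
variant, and breakpoint for truth tracing. A uniform-start
whole-transcript generator and a chimeric-artifact generator (random
same-chromosome joins, used to calibrate the FDR) complement it.

## Junction discovery

Reads failing contiguous alignment are split into their first and last
20 bases; each end is looked up in an exact 20-mer index of the forward
genome (both read orientations are tried; a junction found in reverse
orientation is reported on the minus strand in forward coordinates).
Contiguous alignment itself is seed-and-verify: loci seeded by either
20-mer end, verified full-length at ≤ 2 mismatches, "unique" meaning a
single best locus with no runner-up within one mismatch — a toy-scale
operationalization of a unique mapping-quality threshold.

With both ends uniquely placed on one strand, in order, 51–20000 bp
apart, every breakpoint leaving ≥ 10 bases on each side is scored by
prefix/suffix mismatch cumulative sums and all placements at the minimum
mismatch count (≤ 2) are reported. For a 46 bp read this gives 27
allowable breakpoints (offsets 10–36); for a 35 bp read, 16 — though
only offsets in [10, 15] ∪ [20, 25] are actually recoverable for 35-mers
given 20-base end seeds, which is why short-read junction recovery is
partial by design. Reads shorter than 40 bp with both ends uniquely
mapped are discarded (a config switch relaxes this to discarding only
mutually consistent contiguous placements). With exactly one end placed,
the alignment is extended base-by-base with zero mismatches and the
remainder (≥ 10 bases) must match perfectly at exactly one position
within 20 kb on the appropriate side.

Intron boundaries frequently sit in locally repeated sequence, so a
junction-spanning read is consistent with several coordinate-shifted
intron placements. Every candidate carries this equivalence class
(shifts enumerated up to ±20, the overhang bound); the canonical
placement is the one whose intron reads GT..AG in sense orientation,
preferring GT-AG over GC-AG, then the leftmost shift. A junction is
*canonical* when any placement is GT-AG/GC-AG, *control* when any
placement is GT-TC/GC-TC (the acceptor consensus replaced by its
complement) and none is canonical, *other* otherwise. Assuming all
controls are false positives, FDR = n_control / n_canonical. The
published counts this arithmetic is checked against give 4230/306606 =
1.38% (the source text rounds the same ratio to 1.4% in one place and
reports 1.5% in another; the implementation reports the ratio itself).

## Noise metrics

**Conservation labels.** A splice site's label is the mean conservation
score over its two canonical intronic bases: conserved at ≥ 1.5,
unconserved at ≤ 0.5, intermediate between. Both cutoffs are explicit
configuration — 0.5 follows the published relaxed unconserved threshold,
while 1.5 is this package's default for "highly conserved" (the source
text's exact value is not recoverable from the extraction); every result
reports the thresholds used.

**Error rate.** For each annotated junction with both sites conserved,
the error rate is the fraction of reads involving either end that splice
to an unconserved partner site. Reads to intermediate partners are
excluded from numerator and denominator, making the estimate a
conservative lower bound; a variant including them in the denominator is
reported alongside. The global rate is read-weighted (matching a
"fraction of reads" definition); the unweighted per-intron mean is also
reported. Per-gene arithmetic: with per-reaction error r and n
splicing reactions, the expected mis-spliced transcript fraction is
1 − (1−r)ⁿ; at r = 0.007 and n = 3 (the median four-exon gene) this is
≈ 2%.

**Periodicity.** For the 3′-side analysis, anchors are 5′ sites with
≥ 20 reads, ≥ 2 acceptor partners, a major partner holding ≥ 90% of
reads (the 90% share is a package default; the printed value is not
recoverable), and both the anchor and major site annotated within coding
sequence. Minor-site offsets from the major site (transcription
direction, |offset| ≤ 101, excluding ±2) are counted against the number
of AG dinucleotides at each offset; the ratio profile shows the
frame-periodic pattern, and the in-frame share among minor sites is
tested with a one-sided exact binomial test against 1/3. The 5′ analysis
mirrors this with GT opportunities. The window (101) and kernel support
(98) are both ≡ 2 mod 3 so window truncation cannot bias the frame
composition.

**Trends and correction.** Introns are sorted into 100 equal-count bins
by the covariate (ties broken by coordinates); the trend statistic is
Spearman's rho over bin means, with a cubic smoothing spline
(generalized cross-validation, `scipy.interpolate.make_smoothing_spline`)
as the overlay. Residual correction regresses the per-intron rate on
log10 of one covariate and re-bins the residuals against the other.
Expression is reads per exonic base, maximized across samples.

**Motifs.** Noise sites are unannotated, unconserved sites spliced to an
annotated partner and > 50 bp from any annotated site of their type;
each is matched to the nearest unused GT/AG dinucleotide strictly
between it and the annotated partner (nearest, for local composition
matching; the choice among eligible decoys is otherwise unspecified in
the source). Flanks are 50 bp on each side minus exclusion zones (5′
sites: 5 exonic + 5 intronic; 3′: 2 exonic + 20 intronic — the
polypyrimidine tract); the 50/50 split of the 100-base window is a
package choice. Overlapping hexamers are counted (N-containing windows
skipped) and each hexamer is tested in a 2×2 chi-square (this hexamer vs
all others × noise vs decoy, no continuity correction; Fisher's exact
test when an expected cell is < 5), Bonferroni-corrected over 4096
hexamers at α = 0.05. The log2 enrichment applies a pseudocount of one
to all four cells (finite ratios at zero counts; the test itself uses
raw counts). This construction is exactly antisymmetric under swapping
noise and decoy.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; a junction is keyed by
  its intron interval on the forward strand plus a strand flag.
- Stage seeds derive from the single run seed via a CRC-based fan-out,
  so each stage is reproducible in isolation; identical (config, seed)
  pairs give byte-identical outputs.
- The seed index stores exact 20-mers only; candidate loci therefore
  require at least one error-free read end. At the 10⁻³ sequencing error
  rate this loses ~0.04% of reads and none of the estimators depend on
  absolute recovery, only on class-balanced recovery.
- Degenerate inputs: empty annotation classifies everything as novel
  (with a warning); an intron with no cryptic dinucleotide available
  falls back to intron retention and is flagged; sites with missing
  track coverage are labelled intermediate and excluded.
- Replicate-heavy analyses (periodicity calibration, confounding) use
  the generator's junction-count fast path (multinomial read counts per
  splice variant) rather than read-level simulation; the read-level path
  with full split-read discovery is exercised by the mapper-oracle and
  parameter-recovery suites. The two paths share the same error model.

## Problem sizes

The shipped checks use: 8-gene fixtures for exhaustive mapper oracles;
100–400-gene genomes for catalogue and trend analyses (0.3–0.8M junction
reads via the count path); 200 genes and 2×10⁶ junction-spanning reads
through the full read-level pipeline for error-rate recovery; 200
replicates for test calibration and 100 for motif spike-in power. These
sizes give standard errors comfortably inside the tolerances asserted
(e.g. 3 binomial SE at 2×10⁶ reads is ±1.8×10⁻⁴ around ε = 0.007).

## Limitations

Synthetic sequence is uniform random: it has no codon structure, no real
splice-site motif beyond the forced dinucleotides, no repeats, and no
GC heterogeneity, so mapper uniqueness is easier than on a mammalian
genome and hexamer backgrounds are flat. Conservation is a two-component
Gaussian caricature; real phyloP tracks have heavy tails and
autocorrelation. The NMD proxy ignores PTC position and 3′ UTR rules.
Passing tests therefore demonstrate correctness of the estimators under
the stated model — unbiasedness, calibration, oracle equivalence — not
performance on real libraries, where mappability, annotation error, and
sequence composition add biases the generator does not emulate.
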