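# Methods

## The measurement this package models

Targeted deep bisulfite amplicon sequencing reads out DNA methylation at
single-molecule resolution. Bisulfite treatment deaminates unmethylated
cytosine to uracil (sequenced as T) while 5-methylcytosine resists
conversion (sequenced as C). PCR amplification of a promoter region from
converted DNA, followed by deep paired-end sequencing, therefore yields
thousands of reads per sample in which each CpG position carries a binary
methylation state. The combination of states over the k CpGs of one read
is that molecule's **epiallele**; k CpGs span 2^k possible epialleles
(128 for the 7-CpG amplicon, 256 for the 8-CpG amplicon in the demo
design). An **epiallele class** pools all epialleles with the same number
of methylated CpGs (the Hamming weight), regardless of position.

Because a tissue is a mixture of cell populations, the distribution of
epialleles carries information that the average methylation level
discards: two samples can share identical mean methylation and identical
class distributions yet have disjoint epiallele support, and the package's
ordination analysis is designed to expose exactly that (see
`examples/04_epiallele_tables.py`).

## Pipeline stages and their contracts

**Pair merging.** Forward and reverse reads are assembled by an
exhaustive suffix–prefix overlap scan after reverse-complementing the
reverse read. Among candidate overlaps of at least `min_overlap` bases
(default 40) whose mismatch fraction is at most `max_mismatch_frac`
(default 0.1), the lowest mismatch fraction wins, ties broken by the
longest overlap; conflicting overlap bases are resolved in favour of the
forward read. This is a deliberately simple, fully specified consensus
contract rather than an emulation of any particular assembler's
quality-weighted rules. Rejection is a value, not an exception, so filter
reports always partition their input.

**Quality filtering.** Merged reads are checked for length deviation
(default ≤ 10% of the reference length), N content (default ≤ 2%), and a
primer anchor match at ≥ 80% identity on at least one end, compared
against the bisulfite-converted reference with Y/R degeneracy tolerated.
Thresholds are configuration, chosen to be permissive.

**Alignment and calling.** Alignment operates in "three-letter" space:
both read and reference are fully C→T converted before scoring, so
methylated (C) and unmethylated (T) CpGs match the reference equally.
Reads whose length equals the reference take a direct positional
correspondence when identity clears the floor (default 0.8); otherwise a
global affine-gap alignment (match 2, mismatch −3, gap open −5, extend
−1, free terminal gaps on the read) resolves indels. At each CpG, C calls
'1', T calls '0', and any other base or a gap is ambiguous; a read with
ambiguous CpGs cannot be placed in the 2^k epiallele space and is
excluded from the count table (`max_ambiguous` defaults to 0). Each
read's conversion QC is the fraction of non-CpG reference cytosines read
as T; reads below `min_read_conversion` (default 0.95) are discarded as
incompletely converted molecules.

**Conversion-efficiency estimation.** A fully unmethylated spike-in
fragment (a synthetic C-rich stand-in sequence bundled with the package)
is sequenced alongside the samples; the pooled fraction of its reference
C positions read as T across aligned reads estimates conversion
efficiency, with a binomial (Clopper–Pearson) 95% interval. At 5000 reads
the estimator is accurate to well under ±0.005.

**Conversion-bias correction.** Residual conversion failure is not only a
QC concern: an unconverted unmethylated CpG is read as spuriously
methylated, which shifts observed epiallele frequencies away from the
truth by roughly `k × failure_rate` in relative terms — a systematic
error that exceeds binomial sampling noise at typical depths. Because
CpG sites are independent given the molecule, the observed distribution
is the true distribution multiplied by the k-fold Kronecker product of a
per-site 2×2 miscall matrix; `correct_conversion_bias` inverts that map
using the spike-in-estimated failure rate (and optionally an
inappropriate-conversion rate for methylated CpGs), clipping at zero and
renormalising. The correction is well conditioned for failure rates of a
few percent. Raw counts are always reported alongside; the correction is
an estimator on frequencies, not a rewrite of the table.

**Count table, rarefaction, ordination.** The sample × epiallele table
stores observed columns sparsely (absent = 0) over the lexicographic 2^k
column space and serialises to TSV and BIOM v1.0 sparse JSON. Rarefaction
subsamples each sample without replacement to a common depth (default:
the minimum retained count) via the multivariate hypergeometric
distribution, as a single draw with a recorded seed; expected
frequencies are preserved exactly. Ordination defaults to PCoA
(eigen-decomposition of the double-centred squared-distance matrix, via
scikit-bio) on Bray–Curtis distances of rarefied counts, with plain PCA
on frequency rows available; axis signs are fixed by making the
largest-magnitude coordinate on each axis positive, and degenerate
all-identical inputs return zero coordinates with zero variance
fractions. Note that Bray–Curtis is a true metric only at equal row sums
(where it reduces to L1/(2N)) — one more reason rarefaction precedes
ordination.

**Expression and statistics.** Relative expression is 2^−ΔCt with
ΔCt = Ct(target) − mean(Ct(housekeeping)); technical replicates are
averaged on the Ct scale before ΔCt. Stage comparisons use classical
one-way ANOVA followed by pairwise two-sample t tests — Welch by default
(the safer choice under unequal variances), pooled variance optionally
(which reproduces F = t² for two groups); no multiple-testing correction
by default, Holm by flag. Methylation–expression association is Pearson
correlation; constant inputs yield an explicit NA result. The heatmap
builders correlate, per tissue with stages pooled, each epiallele class's
proportion (and each individual epiallele's frequency, above a 1% mean-
frequency floor) with relative expression.

## The synthetic-data generator

The generator defines the study conditions under which everything is
tested. Defaults: two amplicons of 388 bp/7 CpGs and 403 bp/8 CpGs;
samples structured as two tissues (brain, heart) × three postnatal
stages (P1, P15, P60) × 3 replicates; 10,000 read pairs per sample at
251 × 2 nt (so amplicons of ≤ ~460 bp always merge with ≥ 40 nt
overlap); bisulfite conversion 0.995 with inappropriate conversion
0.005 and per-base substitution error 0.001; a 5000-read fully
unmethylated spike-in. Only the bisulfite top strand is simulated,
matching directional amplicon BS-PCR with strand-specific primers.
Replicate count per group (n = 3) is a configurable assumption. Primer
anchor zones are generated cytosine-free so the converted primer is
unambiguous.

Per tissue × stage, the demo mixture is a Bernoulli(p) product
distribution over the 2^k profiles (so its class distribution is exactly
Binomial(k, p)), with p rising 0.10 → 0.35 across stages in brain and
falling 0.45 → 0.20 in heart, plus two tissue-specific "signature"
epialleles at 10% total mass with disjoint support between tissues.
These mixtures are demo configuration, not biological claims. Simulated
expression is linear in mean methylation on the 2^−ΔCt scale
(coupling −0.9 by default, so the noise-free correlation is exactly −1),
with Gaussian noise of 0.05 cycles applied on the Ct scale to target and
housekeeping wells.

What the generator does **not** emulate: indels, PCR duplicates and
amplification bias, opposite-strand (OT/OB) reads, realistic quality
scores (qualities are constant; filtering is sequence-based), per-
molecule (rather than per-site) conversion failure, and mate-independent
sequencing error (errors are applied to the converted molecule, so
overlapping mates agree). Green tests therefore demonstrate correctness
of the algorithms under a clean, fully specified error model — not
robustness to every artefact of real libraries.

## Reproducibility and numerics

Every source of randomness in a pipeline run derives from the single run
seed through `numpy.random.SeedSequence` spawning, so a rerun of the same
configuration is byte-identical; the manifest records seeds, thresholds
and depths. Problem sizes used by the test-suite checks: 10^4 reads per
sample for round-trip and mixture recovery, 5000 spike-in reads, 200
seeds for rarefaction and correlation-recovery frequencies, 100 seeds for
ordination separation. Ties in merging are broken deterministically
(lowest mismatch fraction, then longest overlap); degenerate statistics
(zero within-group variance, constant correlation inputs) return flagged
infinite/NA results rather than raising.

## Known limitations

- The conversion-bias correction assumes site-independent miscalls and a
  single rate shared across sites and molecules.
- Bray–Curtis ordination is only meaningful on equal-depth (rarefied)
  tables; the API permits but does not encourage unrarefied input.
- The aligner is intended for amplicon-scale references; it does no
  genome-scale bisulfite mapping and no SNP-aware calling.
- Heatmap correlations across pooled stages inherit all the caveats of
  small-n Pearson correlation; they are descriptive, as in the class of
  studies this pipeline serves.
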