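# epiamplicon

Epiallele analysis of targeted deep bisulfite amplicon sequencing, as a
tested Python library: from paired-end bisulfite reads to per-molecule
binary methylation profiles, epiallele-class distributions, rarefied
profile-count ordination, and correlation of methylation with qPCR
expression.

## Who this is for

Labs running deep amplicon bisulfite sequencing of promoter regions —
hundreds of bp, a handful of CpGs, 10^4–10^5 reads per sample — who want
single-molecule resolution rather than just average methylation. Each
sequenced molecule yields an **epiallele**: a binary string over the
amplicon's k CpG sites where `1` marks a methylated CpG (read as C after
bisulfite conversion) and `0` an unmethylated one (read as T), ordered 5'
to 3'. With k CpGs there are 2^k possible epialleles; the **class** of an
epiallele is its number of methylated CpGs regardless of position.
Because tissues are cell mixtures, the epiallele distribution can
discriminate samples that share identical mean methylation — the package
quantifies this by ordination (PCoA on Bray–Curtis distances of rarefied
sample × epiallele count tables).

The package also ships a first-class synthetic-data generator (amplicon
references with a known CpG map, ground-truth epiallele mixtures,
configurable bisulfite-conversion failure and sequencing error, a fully
unmethylated spike-in, and expression values coupled to methylation), so
the whole pipeline is testable end to end against known truth.

## What it computes

- **Read processing** — exhaustive overlap merging of read pairs
  (minimum 40-base overlap by default), FASTQ→FASTA conversion,
  length/N/primer quality filtering with partitioned filter reports.
- **Methylation calling** — alignment to the in-silico converted
  reference in three-letter (C→T) space, per-CpG calls into epiallele
  strings, per-read conversion QC over non-CpG cytosines, and spike-in
  conversion-efficiency estimation with a binomial 95% CI, ΔCt-style:
  efficiency = fraction of unmethylated Cs read as T.
- **Epiallele analysis** — sample × epiallele count tables (TSV and BIOM
  sparse JSON), hypergeometric rarefaction to a common depth, class
  distributions, mean and per-CpG methylation (the mean equals the
  across-CpG average exactly), PCoA/PCA ordination, and an optional
  conversion-bias correction that deconvolves the spike-in-estimated
  per-site miscall rate out of observed epiallele frequencies.
- **Expression** — relative expression as 2^−ΔCt with
  ΔCt = Ct(target) − mean(Ct(housekeeping)).
- **Statistics** — one-way ANOVA across stages, pairwise t tests (Welch
  default, pooled optional, Holm optional), Pearson
  methylation–expression correlation, and per-tissue heatmaps of r
  between class proportions / epiallele frequencies and expression.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

`examples/06_full_pipeline.py` runs the built-in demo design — two
promoter amplicons (7 CpGs in 388 bp, 8 CpGs in 403 bp), brain and heart
at postnatal stages P1/P15/P60 with 3 replicates, here at 2000 simulated
reads per sample:

```
== promoter_a (7 CpGs, 388 bp) ==
  brain mean methylation P1->P15->P60: 12.3% -> 22.7% -> 33.9%
  heart mean methylation P1->P15->P60: 42.8% -> 29.3% -> 20.4%
  rarefied to 1987 reads/sample
  methylation-expression correlation:
    brain: r = -0.931 (p = 0.00026)
    heart: r = -0.969 (p = 1.7e-05)
  ordination PC1+PC2 variance: 89.4%

spike-in conversion efficiency: 0.9946 [0.9943, 0.9949]
```

Methylation rises with age in brain and falls in heart (the generator's
ground truth), relative expression tracks it inversely in both tissues
(strongly negative Pearson r), the rarefied table puts every sample at
the same depth, and the spike-in recovers the simulated 99.5% conversion
rate. The other examples each demonstrate one capability — simulation,
merging + calling, the spike-in estimator, count tables/ordination, and
ΔCt expression.

A thin CLI wraps the same pipeline:

```bash
epiamplicon demo --out config.yaml --seed 1
epiamplicon run --config config.yaml --outdir out/
```

All outputs (filter and call reports, raw/rarefied count tables, class
distributions, per-CpG methylation, ordination coordinates, expression
and statistics tables, manifest) are plain TSV/JSON; a rerun with the
same config and seed is byte-identical.

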