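# Methods

## Concordance model

The benchmark treats the genome-derived (gDNA) SNV call set as truth for
the transcriptome-derived (cDNA) set.  Both sets are first screened with
the post-caller quality rules typical of short-read SNV tables:

| rule | cDNA default | gDNA default | sense |
|---|---|---|---|
| minimum SNP quality (Phred) | 30 | 20 | quality >= threshold passes |
| minimum alt-supporting reads | 3 | 3 | alt_support >= 3 passes |
| maximum site depth | 1,000,000 | 10,000,000 | depth <= threshold passes |
| end-of-read rule (cDNA only) | 0.20 | off | end fraction > 0.20 fails |

Threshold senses follow the literal reading of each rule ("above a
minimum", "fewer than three", "more than 20%"); each comparator is a
`FilterParams` flag, so a strict-inequality variant is one configuration
change.  Removals are attributed to the first failing rule in the order
above.  The end-of-read rule targets spliced reads whose last 1–3 bases
align on the wrong side of an exon junction; it is off for gDNA because
the artifact is transcriptome-specific.  Other caller-internal filters
(SNP clustering, gap adjacency) are deliberately not re-implemented: the
package consumes post-caller tables, not alignments.

Calls are then restricted to annotated exons (1-based inclusive
endpoints; BED converted at the boundary) and annotated with every
covering transcript and gene.  Duplicate positions within one set keep
the highest-quality record (ties broken lexicographically on genotype).

Classification matches by `(chrom, pos)` (**position** mode) or
additionally by the unordered allele pair (**genotype** mode).  In
genotype mode a position-matched pair with discordant genotypes counts as
one FP *and* one FN — the genomic variant was missed and a wrong variant
was asserted — which preserves the conservation laws `tp + fn = |gDNA|`
and `tp + fp = |cDNA|` in both modes.  The literature does not pin this
convention down, so it is exposed as `mismatch_policy` ("fp+fn",
"fp_only", "drop").  Known-site (dbSNP-like) membership is matched by
position only.  Genotypes are unordered pairs; phase is never
represented.  Zygosity discordance among matched pairs is split into four
exclusive categories: full allele mismatch (no shared allele), het-gDNA /
hom-cDNA (allelic dropout signature), hom-gDNA / het-cDNA (usually thin
gDNA coverage), and zygosity match.

Sensitivity and specificity are binomial proportions; `ConcordanceResults`
reports Wilson score intervals.  Undefined metrics (zero denominator) are
NaN, never 0.

## Coverage

Per-exon coverage is the mean per-base read depth over the exon, zeros
included, computed from a run-length depth track (bedGraph at the
boundary).  The coverage summary reports the fraction of exons at or
above a threshold (default 5x; ">= " by default, comparator
configurable) and the median mean-coverage of that subset.  The median
uses the lower-median convention for even counts (configurable to
mean-of-middle); at realistic exon counts the choice is immaterial.

## Stratification conventions

* **Expression bins** are log-spaced on the percent-of-max scale; the
  default is 2 bins per decade spanning 0.04%–100%, which makes the 4%
  "expressed" threshold an exact bin edge.  A call covered by several
  transcripts takes the **maximum** expression among them: the variant is
  detectable if any covering transcript is expressed.  Transcripts absent
  from the expression table count as unexpressed.
* **Depth windows** are inclusive on both ends and restrict the cDNA side
  only; FN is recomputed against the full gDNA set (gDNA depth is a
  different quantity), so windowing lowers sensitivity by construction.
* **Paralog split** uses an any-rule: one paralogous covering gene places
  a call in the with-paralog stratum; the strata are disjoint and
  exhaustive, and a covering gene missing from the annotation table is an
  error.
* **Lane curves** classify cumulative cDNA snapshots under one fixed QC
  configuration; TP monotonicity across snapshots is checked and
  violations are flagged in the output, never silently repaired.

## Synthetic-data generator

The generator emulates a single-individual genome/transcriptome
comparison at desk scale.  Reads are never materialised; depth and
allele-support counts are sampled directly, which is what the analysis
consumes.

Geometry: one synthetic chromosome, genes tiled with fixed gaps, one
transcript per gene, exon count ~ 1 + Poisson(5) and exon length
~ max(40, Poisson(160)) bases.  `n_genes` (default 400; 2,000 in the
benchmark suite, giving ~13,000 planted sites) is a scale knob, not a
study condition.

Expression: a fraction of genes (`silent_fraction`, default 0.3) is not
expressed in the tissue at all; the rest draw log-normal expression
(sigma 1.4) rescaled so the most expressed transcript is 100%.  These two
values were chosen so that roughly a fifth of genes exceed the 4%
"expressed" threshold and about half of exons reach 5x coverage, the
regime the emulated study reports; the generator makes no claim about the
true parametric form of tissue expression.

Depth: gDNA site depth ~ Poisson(24).  cDNA exon depth per lane ~
Poisson(k · expression_pct), with k calibrated per realisation so the
median full-lane depth of expressed exons hits 126x at 8 lanes.  Every
site in an exon shares the exon's realised per-lane depths.  Lane
snapshots are nested — each lane's reads are drawn once and cumulated —
so alt support is non-decreasing in lanes as a property of the draw.

Alleles: truth variants occur at 7e-4 per exon base (33% homozygous
non-reference).  Heterozygotes sample alt reads ~ Binomial(depth, 1/2);
with probability `allelic_imbalance` (default 0.10) a heterozygous site
expresses a single allele (ref or alt, equally), which produces the
het-gDNA/hom-cDNA discordance class and, for ref-only expression, allelic
dropout.  Homozygotes use 1 − per_base_error.  The called genotype is
hom-alt when the alt fraction reaches 0.9, het otherwise.

Caller emulation: a site becomes a call when alt support reaches 3 reads
(the raw caller gate), *before* pipeline QC.  SNP quality is a proxy —
10·alt_support + 0.05·depth + bounded uniform noise, capped at 255 —
monotone in both arguments, since re-deriving a consensus caller's
quality model is out of scope.  At the gDNA threshold (20) the proxy
always clears for 3+ alt reads, so gDNA emission of a heterozygote is
exactly the Binomial(depth, 1/2) upper tail; at the cDNA threshold (30)
3-read calls sit at the boundary and the noise term makes some fail,
which gives the quality screen real work.

False-positive processes (all planted in the truth set with per-class
known-site membership, so every FP is attributable):

* **Paralog misalignment** — candidate sites at 5e-3 per exon base in
  paralog-flagged genes (73% of genes).  Misaligned reads are driven by
  the expression of a randomly chosen *partner* paralog, at 0.05 reads
  per unit of partner depth, saturating at an expected pile of 8 reads at
  full lanes (only reads straddling the homologous junction can
  misalign).  Misaligned reads add to both alt support and site depth, so
  on silent hosts these calls appear as low-depth, high-alt-fraction
  "dust" — the dominant FP class, concentrated below ~50x.
* **End-of-read artifacts** — candidate sites at 1e-3 per exon base;
  artifact alt reads ~ Poisson(0.02 · host depth) with ~90% of supporting
  bases flagged as read ends, so the 20% end-fraction rule removes almost
  all of them.  Ordinary calls draw end flags at the baseline 2/75 per
  supporting read (two end positions in a 75-bp read).
* **Sequencing noise** — candidate sites at 1.5e-3 per exon base with alt
  reads ~ Binomial(depth, 0.002): negligible at gDNA depth (a ~cubic tail
  in the error rate), but increasingly able to clear the 3-read gate as
  cDNA depth grows — the high-depth FP surge that makes specificity fall
  as lanes accumulate and collapse above the useful depth window.

Known-site membership is Bernoulli per planted site: 0.94 for true
variants, 0.23 for artifact sites, so the pipeline's per-class known-site
rates are parameter-recovery checks.

The generator intentionally omits: read-level effects (mapping quality,
strand bias, PCR duplicates), splice-graph structure, RNA editing,
multi-transcript genes, inter-gene expression correlation, and
non-uniform coverage within an exon.  Passing tests therefore demonstrate
that the pipeline measures what the generative model plants — not that
real RNA-Seq data meets these assumptions.

## Numerical and degenerate-input conventions

Internal coordinates are 1-based inclusive everywhere; BED/bedGraph are
converted at the I/O boundary.  Quality-score re-encoding preserves the
Phred value (encoded − 64 + 33) and rejects codes below the source
offset.  Empty exon lists empty the call set with a warning; an empty
coverage list, an empty lane-snapshot list, mixed-source filter input,
duplicate in-set positions at classification time, and reference-allele
disagreements between the two sets are errors.  Multi-allelic VCF rows
keep the two called alleles and reject rows calling more than two
distinct alleles.  All randomness flows from `numpy.random.default_rng`
seeded from `SimulationConfig.seed` (truth, gDNA and cDNA use seed,
seed+1, seed+2), so identical configurations are byte-identical on disk.

## Problem sizes

The test and benchmark suites use n_genes = 2,000 (~13,000 planted sites,
a few seconds end to end), with smaller configurations for unit tests and
a 10,000-gene draw for the expression-distribution check; these sizes
give 3-standard-error resolution on every directional comparison while
keeping the suite fast.  Statistical acceptance checks compare recovered
quantities to planted parameters or closed-form oracles at 3 standard
errors under fixed seeds.
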