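# Methods

`bulkmap` implements the desk-analysis side of a combined BSA-seq +
RNA-seq candidate-gene study of a biparental segregating population, and a
synthetic study generator that reproduces the statistical structure such
data is assumed to have. This note records the models, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
tests do and do not demonstrate.

## The association statistic

For a biallelic site with the two parents fixed for different alleles,
the per-pool index is the fraction of pool reads carrying the M-parent
allele:

    index(aa) = Maa / (Paa + Maa)
    index(ab) = Mab / (Pab + Mab)
    Δ-index   = index(aa) − index(ab)

where `aa` is the small-phenotype pool, `ab` the large-phenotype pool, and
`Maa`/`Paa` the depths supporting the M- and P-parent alleles in pool aa.
Sites where a pool has no informative depth are flagged missing and
excluded from windows. Which VCF sample plays P and which M is
configuration (`RoleMap`), not a guess: the two conventions differ only in
the sign of Δ, and region calling is two-sided because either parent may
contribute the trait-increasing allele. The default maps M to the
alternate-allele parent (the mutant), so Δ peaks positive at loci where
mutant alleles are enriched in the small pool.

Site filtering before the scan (criteria are standard QTL-seq practice and
configurable): each parent covered at ≥ 4 reads with minor-allele read
fraction ≤ 0.1 and opposite major alleles; each pool covered at ≥ 4 reads.

## Windows, smoothing, thresholds, regions

Δ values are averaged in 1 Mb windows sliding every 100 kb (defaults);
windows with fewer than 10 informative sites are missing and can never be
significant. The window track is then smoothed per chromosome by locally
weighted regression (tricube-weighted local linear fit, span 0.1 of the
chromosome's windows, no robustness iterations so that constant and linear
tracks are reproduced exactly). Span 0.1 resolves roughly Mb-scale peaks
on tens-of-Mb chromosomes; chromosomes with fewer than 10 windows are
passed through unsmoothed with a warning.

The significance threshold is simulated, not analytic. For a site depth
`d`: draw 2×30 F2 individuals (P2-allele dosage Binomial(2, ½) each),
split into two bulks of 30, compute each bulk's allele frequency, draw
pool reads Binomial(d, freq), and take the empirical two-sided quantiles
of the resulting null Δ at the configured confidence (99% default).
Bounds are computed on a small grid of depths and linearly interpolated at
each window's mean pool depth.

Two numerical points:

* **Lattice smoothing.** At fixed depth the null Δ lives on a lattice of
  spacing 1/d with appreciable mass on single atoms; an empirical quantile
  band on the raw statistic can only cover 98.6% or 99.3% at d = 30, never
  99%. The simulator therefore jitters the read-count difference by
  Uniform(−½, ½) before dividing by depth — the standard randomised-
  quantile construction for discrete data — which makes the band attain
  its nominal level exactly (verified by fresh-draw coverage in the test
  suite and the acceptance script).
* **Per-window thresholds are per-site thresholds.** Sites inside a window
  are tightly linked, so they share the bulks' local genotype draw; the
  window mean fluctuates on the per-site scale and does *not* shrink like
  1/√n_sites. Attaching a band for the mean of n independent null sites
  would be ~6× too narrow at 100 sites/window and would flood QTL-free
  chromosomes with false regions. The per-site band at the window's mean
  depth is the correct null envelope under linkage, and matches standard
  QTL-seq practice.

Windows whose fitted value falls outside the band are merged into maximal
runs per track; runs separated by less than one step are merged. The
candidate set is the interval intersection (≥ 1 bp, half-open coordinates,
`max(starts)..min(ends)`) of SNP-derived with Indel-derived regions —
requiring both variant classes to agree suppresses class-specific
artefacts. Coordinates are 0-based half-open internally, 1-based in VCF,
0-based half-open in BED.

## Variant effects

Parent-differentiating variants are classified per overlapping gene:
coding SNVs by translating the affected codon on the coding strand
(standard nuclear code) — synonymous vs nonsynonymous; coding indels by
length difference mod 3 — frameshift vs in-frame; positions within
2 kb 5′ of the transcription start on the coding strand — upstream;
inside the gene span otherwise — intronic; everything else — intergenic
(reported only when no gene is within reach). The 2 kb upstream window is
a conventional promoter-proximal default and is configurable. Deletions
straddling a CDS boundary are conservatively reported as frameshift. A
variant overlapping several genes yields one record per gene.

## Differential expression

FPKM = counts × 10⁹ / (gene length × library size). Genes with FPKM < 1
in every sample are excluded *before* testing, so the multiple-testing
correction only spans tested genes. The test itself is a
negative-binomial Wald pipeline: median-of-ratios size factors; per-gene
method-of-moments dispersion pooled across genes by a lowess trend against
log mean; group means taken directly on size-factor-normalised counts with
a delta-method standard error `var(log q̄) = (Σ_j 1/(q·s_j) + m·α)/m²`;
normal Wald p-values; Benjamini–Hochberg FDR. A gene is a DEG when
FDR < 0.01 and |log2FC| > 1 (condition 2 over condition 1 by sorted label;
the direction is recorded in the output).

Choices worth recording:

* The dispersion trend is fitted on the **linear** dispersion scale with
  **no** robustness iterations. Raw method-of-moments estimates at 3
  replicates are strongly right-skewed; log-scale averaging or outlier
  downweighting biases the pooled dispersion low and makes the test
  anti-conservative (~11% null rejections at the 5% level in simulation);
  the linear-scale local mean is approximately unbiased and yields 4.5–6.5%
  across simulation seeds. The default puts full weight on the trend
  (`dispersion_shrink = 1.0`); per-gene mixing is available but loosens
  calibration at few replicates.
* The closed-form group-mean estimator (rather than an iterative NB-GLM
  fit) makes two documented invariants *exact*: rescaling any sample's
  counts leaves every log2FC unchanged (the size factor absorbs it), and
  swapping condition labels negates every log2FC. Gene-level p-values are
  therefore not numerically identical to any particular external NB tool;
  agreement of fold-change estimates with an independent NB implementation
  is checked by correlation in the test suite, and calibration by
  simulation.

## Candidate triage

Stage 1: genes overlapping candidate regions by ≥ 1 bp. Stage 2: the
DEGs among them. Stage 3: those carrying at least one qualifying variant
class — frameshift, nonsynonymous or upstream by default (synonymous and
intronic variants do not qualify). Ranking for follow-up: genes whose
only qualifying variants are upstream *and* whose |log2FC| ≥ 2 come first
(the signature of a promoter-driven expression change), then |log2FC|
descending, then FDR ascending; the key is recorded in the output. An
expression/gene-model identifier overlap below 50% aborts with an error
(almost always a mismatched annotation build).

## Promoter comparison

Two cloned promoter alleles are aligned globally with affine gaps
(match 2, mismatch −1, gap open −4, gap extend −1; a gap of length L costs
open + (L−1)·extend). The defaults make a 3 bp indel (−6) preferable to
three isolated substitutions (−9 net), so short indel runs are reported as
single events: maximal gap runs collapse to one insertion/deletion each,
mismatch columns are SNPs, positions are 0-based on allele A. The aligner
is exact (Gotoh); its deterministic first-optimal alignment is reported,
and scores are verified against exhaustive enumeration for short
sequences in the tests.

Motifs are matched as IUPAC consensus strings on both strands, all
overlapping occurrences reported. The shipped catalog carries
PlantCARE-style approximate consensus entries (MYC-motif CANNTG, WUN-motif
AAATTTCCT, G-box, ABRE, CAAT-box, TATA-box, W-box, MBS, ARE, GT1); these
are editable configuration data, not measured binding sites, and should be
replaced when project-specific definitions exist. Two hits correspond
when their alignment-column spans overlap for the same motif and strand; a
hit without a correspondent is a loss (allele A) or gain (allele B), and
each is annotated with the overlapping variant events. The
correspondence is symmetric, so swapping alleles swaps gains and losses.

## The synthetic study generator

The generator emulates the design the pipeline targets, with these
defaults as the study conditions:

* **Population/trait:** F2 of 341 selfed progeny; thousand-seed weight
  4.9 g (P1) vs 2.6 g (P2); phenotype = midparent + Σ effect×dosage +
  N(0, 0.5 g); default one QTL of −1.15 g per P2 allele (half the parental
  difference). Bulks are the 30 smallest and 30 largest plants, ties
  broken by index.
* **Sequencing:** parents fixed (P1 reference, P2 alternate); site depth
  Poisson with means 28/29/28/23× for small pool / large pool / P1 / P2;
  symmetric read-error rate 0.001.
* **Linkage:** each marker links to its *nearest* QTL on the chromosome
  through a Haldane map at a uniform 2 cM/Mb; per bulk, the marker's
  alternate-allele count is drawn haplotype-wise from the bulk's QTL
  genotypes through the recombination fraction. Chromosomes without a QTL
  reduce exactly to independent 1:1 segregation. Marker–marker linkage,
  interference and epistasis are not modelled.
* **Expression:** log-normal baseline means (median ≈ 150), common NB
  dispersion 0.05, 3 replicates per line, log-normal library-size factors
  (σ = 0.15); 150 of 2000 genes shifted by |log2FC| = 2 with random sign.
  The true fold changes and size factors are emitted for recovery tests.
* **Gene models/promoters:** non-overlapping strand-mixed genes with 1–5
  CDS segments (frame-consistent); one promoter pair of 1.5 kb with 16
  substitutions + 5 indels (1–4 bp) planted at ≥ 25 bp spacing — 21 events
  total, the count a single promoter comparison of this kind typically
  yields — two of which fall inside embedded MYC/WUN motif instances and
  break them.

A single integer seed drives deterministic per-stage substreams, so every
output is byte-reproducible.

What the generator does *not* emulate — and hence what green tests do not
show about real data: read-level errors correlated along reads, mapping
artefacts and repeat regions, multi-allelic sites, segregation distortion,
linked marker–marker correlation beyond the shared QTL, batch effects and
heterogeneous dispersions in expression, and annotation errors. Passing
the planted-QTL recovery test shows the caller recovers loci under the
stated model at the stated design; it does not bound false-discovery
behaviour under mapping artefacts.

## Problem sizes used in the checks

The planted-QTL recovery check runs 50 seeded studies on a compact
two-chromosome genome (2 × 10 Mb, 2000 SNPs + 800 indels, one QTL; one
chromosome deliberately empty) — large enough for ~100 SNPs per 1 Mb
window, the density regime the window statistics assume, while keeping a
full 50-study replication inexpensive. Null-band calibration uses 10⁵
simulations and 10⁵ fresh draws; expression calibration uses 2000 genes ×
(3+3) replicates.

## Known limitations

* The null band conditions on depth only through the window's mean depth;
  depth heterogeneity within a window is ignored.
* The Wald test is asymptotic in counts; at very low means it leans on the
  pooled dispersion trend and the FPKM filter to stay calibrated.
* Effect classification handles one variant at a time (no haplotype-aware
  codon changes) and reports boundary-spanning indels conservatively as
  frameshift.
* Interval intersection reports one fragment per overlapping SNP×Indel
  region pair; deliberately no merging across distinct pairs.
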