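# Methods

## Coordinate and format conventions

All internal coordinates are 1-based inclusive, the convention shared by
the two count-bearing inputs (Bismark coverage and VCF).  BED gene
annotation is converted on read (`start+1`, `end`) and this is the only
off-by-one boundary in the code; it is fencepost property-tested.  The
methylation-percent column of coverage files is never trusted —
fractions are always recomputed from the count columns.  Indels and
multi-nucleotide variants read from the VCF are anchored at POS and
flagged non-SNV: they participate in masking (they still disrupt the
cytosine context) but can never qualify as subspecies-specific SNPs.

## Masking of genetically confounded cytosines

Masking partitions the cytosine universe into three disjoint sets:
on-a-variant, exactly ±1 bp from a variant, and kept.  The variant set
is the union of *all* detected variants in either group, not only fixed
differences — a cytosine confounded by a segregating C/T is just as
uninterpretable as one confounded by a fixed difference.  Fixation
matters only for the proximity analysis.  An allele-aware mode
(`mask_mode="ct_only"`, restricting to C/T and G/A SNVs) is provided
for sensitivity analysis, not as a default: positional masking is the
conservative choice.

Subspecies-specific SNPs (ssSNPs) are SNVs at which every sample of one
group is homozygous for one allele and every sample of the other group
homozygous for a different allele.  By default a single missing
genotype disqualifies the position (strict mode, reproducible); a
lenient mode requires at least *k* concordant called homozygotes per
group.

## Coverage rule and season merging

A site enters analysis only with coverage ≥ `min_cov` (default 10) in
*every* sample; a site absent from one sample's file counts as coverage
0 and is dropped.  The unit of analysis is the individual strand-specific
cytosine; CpG-dyad destranding (folding minus-strand counts onto the
plus-strand position one base upstream) is available by flag but off by
default, because the coverage filter and DMC counts are defined on
cytosines.  When each animal is sampled in two seasons, counts are
summed per animal cell-wise and the coverage filter is re-applied to the
merged counts, so a site at 6X + 5X in the two seasons is analysable at
11X.  Differential testing runs on the merged (per-animal) matrix; PCA
and the variance partition use the season-level matrix.

## Differential test

Per site, the two-group binomial model (MLE = pooled within-group
fraction) is compared to the one-group model by a likelihood-ratio
statistic.  Overdispersion across replicate animals is absorbed by a
quasi-likelihood correction: the Pearson X² of the two-group fit over
its residual degrees of freedom, floored at 1 so that under-dispersed
sites are not anti-conservatively sharpened.  The scaled statistic is
referred to F(1, n₁+n₂−2) — the reference used for quasi-binomial
deviance tests, deliberately conservative at 5 + 5 animals.  Cells whose
fitted proportion is 0 or 1 contribute zero to X² (the pooled MLE then
equals the shared observation).  Sites where a group has zero total
coverage are skipped and logged.

The effect size is the absolute difference of the *unweighted* means of
per-sample fractions (robust to coverage imbalance between animals); a
pooled-count mode is available by flag.  A cytosine is a DMC iff
BH-adjusted q ≤ 0.05 **and** the absolute difference ≥ 0.10.  Effect
classes partition DMCs at 30% and 70%, with both boundary values
assigned to the middle class so the three classes are a partition.  BH
adjustment is delegated to statsmodels and checked against a hand-rolled
step-up in the tests.  A Fisher exact test on within-group pooled counts
is available for degenerate replicate structures (it ignores
between-animal variability and is not the default).

## SNP-proximity profile

For each tested cytosine the nearest same-chromosome ssSNP distance is
computed by binary search (an all-pairs scan is the test oracle);
distance 0 cannot occur because on-variant cytosines were masked.
Distances are binned into [1,10], [11,20] … [91,100] bp.  Proportions
are normalised by the full set size (all DMCs, or all MCs), so a bin
reads as "the fraction of the set lying this close to a fixed
difference"; sites beyond 100 bp contribute to the denominator only, and
a within-window normalisation is available by flag.  Per-bin enrichment
uses the 2×2 Fisher exact test with Haldane–Anscombe 0.5-corrected odds
ratios when a cell is zero (a bin empty in both sets reports OR = 1).

## Stretches, genes, grouping

DMC stretches are maximal runs of DMCs with consecutive gaps below
`max_gap` and a shared sign of the group difference ("similar
methylation status" is read as same direction; a direction-blind mode
exists).  The closeness threshold is a parameter, default 2000 bp, and
is always echoed in the run summary.  Singletons are not stretches.
A DMC belongs to a gene when it lies in the gene body or the upstream
promoter flank (default 2 kb, strand-aware); overlapping genes share
DMCs, and a stretch attaches to every gene any member touches.  Genes
are ranked by DMCs per kb of gene length (ties: DMC count, then gene
id).  Gene grouping counts genes whose *largest* stretch reaches ≥2, ≥3
and >3 members — nested categories by construction; a stretch-count
mode is available by flag.  The terminal gene-set enrichment is a
one-sided hypergeometric tail over a GMT collection with BH adjustment.

## PCA and variance partition

PCA runs on methylation fractions (comparable across coverage depths),
site-wise mean-centred, without variance scaling, via SVD.  Signs are
fixed by making each component's largest-magnitude loading positive, so
results are bit-reproducible.  A zero-variance input (e.g. identical
samples) returns all-zero scores and explained fractions with a warning
rather than an error.

The variance partition is a per-site sequential sums-of-squares
decomposition on the fraction scale in the order breed →
individual-within-breed → season, the nesting-aware order for a design
where each animal belongs to one breed and is measured in both seasons;
the remainder is residual.  Reported numbers are means of per-site
fractions over sites with non-zero variance (constant sites are skipped
and counted).  This deterministic decomposition supports ordering
claims (which factor dominates); it is not a mixed-model variance
component estimate, and per-factor fractions inherit an upward bias
proportional to each stratum's degrees of freedom under pure noise.

## Synthetic data generator

The generator emulates the post-alignment products of a two-subspecies
RRBS + genotyping design: 5 + 5 animals (groups "A" and "N"), two
seasons (C/R) with negligible season effect, CpG sites on a 3 Mb
two-chromosome toy genome, fixed and segregating SNPs, genes, and a full
truth table.  The per-site, per-sample methylation probability is

    π = clip(baseline + effect·g/2 + shift·g/2 + ind + seas, 0, 1)

with `g = ±1` by group.  Choices worth stating:

- **Baseline** is Beta(7.4, 2.6) (mean 0.74, matching the study-scale
  mean methylation level; the shape keeps little mass near 0/1 so the
  clip is essentially inert and the pooled mean calibrates to the beta
  mean within ±0.02).  No published per-site distribution exists; the
  beta-binomial form is this package's choice.  At true-effect sites
  the baseline is instead drawn uniformly from a range leaving room for
  ±effect/2, so clamping never erodes a planted effect class.
- **Effects** are drawn per class — <30% from U(0.10, 0.30), 30–70%
  from U(0.30, 0.70), >70% from U(0.70, 0.95) — with the class mixture
  configurable.  Clustered effect sites are planted as runs with
  sub-threshold gaps, one shared sign and class per cluster, each run
  confined to one chromosome window so planted stretches are
  unambiguous.
- **Variance structure**: individual effects N(0, 0.08) per (animal,
  site), shared across that animal's seasons; breed baseline shifts
  N(0, 0.03) per site; season effects N(0, 0.01) per (site, season) —
  the ordering individual > breed > season.  All effects add on the
  probability scale.
- **Coverage** is negative binomial with mean 30 and size 8
  (variance ≈ 142), a realistically over-dispersed depth under which
  roughly a quarter of sites fail the 10X-in-all-20-samples rule while
  merged per-animal coverage (~60X) almost always passes.
- **The confound**: a configurable fraction of fixed SNPs are C→T
  placed exactly on CpG cytosines of sites with zero true effect;
  samples homozygous for T emit all reads as unmethylated.  CpG sites
  live on an even-coordinate lattice and other SNPs on odd linear
  coordinates, so accidental SNP-on-CpG collisions cannot occur and the
  planted confound count is exact.  "Near-DMC" fixed SNPs are placed at
  odd offsets of 3–99 bp so they flank, but never mask, the cytosine.
- **Determinism**: all draws derive from `numpy.random.default_rng`
  seeded from the config; identical configs give byte-identical output
  files.

What the generator does *not* model: read-level artifacts, incomplete
bisulfite conversion, alignment bias, bimodal methylation landscapes,
CpG-island structure, and linkage between SNPs.  Passing tests
therefore demonstrate the pipeline's logic and statistical behaviour
under its stated assumptions, not performance on any real methylome.

## Problem sizes and numerical notes

The validation suites use simulations of 1,500–10,000 CpG sites with 10
animals × 2 seasons — large enough for stable rates (standard errors on
the null call rate are ~10⁻³) while keeping the whole suite fast.
Degenerate inputs are handled explicitly: empty variant sets keep all
cytosines; empty DMC or MC sets produce all-zero profiles with a
warning; a group with zero coverage skips the site; constant matrices
yield zero-variance PCA results; ties in gene ranking break
deterministically.  Reported percentages use round-half-even at the
stated precision via exact decimal arithmetic.
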