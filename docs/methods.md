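# Methods

This note documents the models, estimators, numerical choices and
limitations behind `popgendiff`. Notation: populations are indexed
i, j; a gene region contains m bi-allelic SNPs; p_ik is the frequency
of the tracked allele at SNP k in population i.

## Input model and quality control

Genotypes are unphased alternate-allele dosages (0/1/2, with missing
coded separately); only bi-allelic autosomal SNPs are considered
(multi-allelic and non-SNP records are skipped on read, half-calls
become missing). Missing genotypes are excluded from every frequency
denominator — no imputation. Alleles are taken as written; no strand
flipping is attempted, which is safe because dosages within one
dataset are strand-consistent by construction.

QC applies three filters — exact Hardy–Weinberg test p ≥ 0.001, call
rate ≥ 0.75, minor allele frequency ≥ 0.01 (all configurable) — and by
default applies them **per population**, retaining a SNP only if it
passes all three in every population. This is the conservative choice
consistent with the companion rule that a gene is retained only if it
has ≥ 2 SNPs in all populations; a pooled mode (one test on the
combined sample) is available. The HWE test is the exact conditional
test (Levene/Haldane distribution over heterozygote counts given
allele counts, two-sided by summing outcomes no more probable than the
observed one) rather than the χ² approximation, because a 0.001
threshold is unreliable under χ² at small genotype counts.

Coordinates: VCF positions are 1-based, gene regions (BED) 0-based
half-open; a SNP at position pos belongs to a gene iff
start ≤ pos − 1 < end. Gene sets (GMT) are pruned to catalogue genes
before the ≥ 10-gene inclusion filter, and a gene belonging to several
sets contributes to each independently.

## Allele-frequency features

The tracked allele at each SNP is the **minor allele in a designated
reference population** (first panel population by default); a tie at
frequency 0.5 deterministically tracks the VCF alt allele. d_AF is the
mean absolute per-SNP difference of these frequencies, bounded in
[0, 1], symmetric, and zero iff the oriented frequency vectors agree.

FST is the Weir–Cockerham (1984) θ for two populations, computed from
genotype counts via the variance components a (among populations), b
(among individuals within populations) and c (within individuals),
using observed heterozygosities — no HWE assumption. Per-SNP θ =
a/(a+b+c) can be slightly negative by sampling; the gene-level
estimator is the ratio of sums Σa / Σ(a+b+c) over the gene's SNPs
(lower bias than averaging per-SNP ratios; an averaging mode exists
for comparison). SNPs monomorphic in both populations of a pair have
undefined components and are excluded from FST; they remain in d_AF,
where |p − p| = 0 is well defined.

## LD features

Two-locus haplotype frequencies are maximum-likelihood estimates from
unphased genotypes by EM. Only the double heterozygote is phase
ambiguous; all other cells contribute fixed haplotype counts. EM is
initialized at linkage-equilibrium product frequencies (making the
result deterministic; EM converges to a stationary point, which the
test suite checks against exhaustive simplex-grid search), iterated to
a maximum frequency change < 1e-8 (cap 1000 iterations). Samples
missing at either locus are dropped pairwise. From haplotype
frequencies, D = p_AB − p_A p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)) and
D′ = |D|/D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0,
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0; a monomorphic marginal makes
both undefined (missing).

Haplotype blocks come from the four-gamete test: a SNP pair "fails"
when all four gametes have EM frequency ≥ 0.01 (the conventional
existence threshold; configurable). Blocks are built greedily left to
right as maximal contiguous runs in which **every** pair passes;
singleton SNPs extending no block are not counted as blocks. Gamete
frequencies come from the same two-locus EM rather than naive
counting so that missing data and double heterozygotes are handled
consistently. Per gene and population the block summaries are: block
number; mean block span in bp (end − start + 1); SNP density as the
mean over blocks of SNPs-per-kb (per-block densities averaged, not
pooled); and haplotype diversity H = n/(n−1) (1 − Σ p_h²) with n the
number of chromosomes entering the block's EM, averaged over blocks.
The n/(n−1) factor is Nei's small-sample correction; both the factor
and the chromosome-based n are package choices where conventions
differ. A gene/population with zero blocks records all four block
features as missing — "no resolvable block structure" is treated as
absence of evidence, not as zero.

Block haplotype spectra use a multi-locus EM over all haplotype pairs
compatible with each individual's genotype (individuals with any
missing call in the block are excluded). Blocks wider than 8 SNPs are
solved by partition-ligation: halves are solved recursively, then a
final EM runs over the 64 highest product-frequency concatenated
candidates; individuals compatible with no candidate pair are dropped
from the ligation step. This is an approximation that can miss rare
recombinant haplotypes in very wide blocks.

## TagSNP features

Tag selection is greedy pairwise set cover: a SNP covers itself and
every SNP with r² ≥ 0.8; the SNP covering the most uncovered SNPs is
chosen repeatedly (ties to the lower column index) until all are
covered. The coverage property is asserted on every run. Pairs with
undefined r² count as r² = 0, so monomorphic-adjacent SNPs tag
themselves. No multi-marker (haplotype) tests are performed — the
transferability statistics below are defined purely in pairwise r²
terms.

Transferability of population B's tags into population A: a SNP in A
is captured if its r² with at least one B-tag **strictly exceeds**
0.8, with r² computed in population A (the capturing population's own
LD is what matters in practice, and the strict inequality follows the
definition of capture; selection uses ≥ 0.8 — the boundary case
differs only on exact ties). captured_percent is over all of A's SNPs
for the gene; avg_max_r2 averages the best tag r² over captured SNPs.
Tags filtered out of A by QC are unusable there, mirroring real
transferability loss.

## Differences, matrices and set scores

Per gene, feature and unordered population pair, one difference value:

- vector features (per-SNP frequencies; per-pair r², D′): mean
  absolute difference over units defined in both populations;
- scalar features (block number/size/density, diversity, tag percent):
  absolute difference — the m = 1 case of the same formula; the tag
  percent difference is divided by 100 so all tag-family differences
  live in [0, 1];
- FST: already pairwise, the record for pair (i, j) is the gene θ
  itself;
- directed transferability: mean shortfall from perfect transfer over
  the two directions, ((perfect − v_A→B) + (perfect − v_B→A))/2,
  scaled by the perfect value (100 for captured percent, 1 for average
  maximum r²). If one direction is missing the other is used alone.
  The symmetrization is an explicit package convention; storing raw
  directed values is available instead.

Missing values propagate: a feature missing in either population
yields a missing record, never zero. Records assemble into symmetric
matrices with zero diagonals; reference summaries report Tukey
quartiles (linear interpolation) and the percentile rank of a queried
pair as the fraction of values strictly below it.

Gene-set (pathway / GO category) scores are unweighted means of
member-gene difference values, computed per feature and pair; genes
with missing values are excluded and counted. Total record
cardinality is entities × features × C(populations, 2), which the
pipeline reproduces exactly when nothing is missing.

## Synthetic data

The generator emulates HapMap-like multi-population data.
Per-population allele frequencies follow the Balding–Nichols model:
ancestral p ~ Uniform(0.05, 0.95), population frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F); F = 0 copies p exactly. LD comes from a
haplotype-pool scheme: each gene is tiled by blocks of `block_length`
SNPs, each population draws a pool of `haplotypes_per_block`
haplotypes from its frequencies, and each diploid samples two pool
haplotypes — strong LD within blocks, equilibrium between them.
`haplotypes_per_block=None` removes the pool (independent Bernoulli
chromosomes), which is the exact Balding–Nichols genotype model used
for FST parameter-recovery checks; a finite pool adds a bottleneck
that inflates differentiation beyond F, so recovery runs use the
infinite-pool mode.

Default study conditions, chosen once as a realistic desk-scale
stand-in: 3 populations × 40 diploids, 20 genes × 32 SNPs over 20 kb
(~1.6 SNPs/kb), F = 0.05 (continental-scale differentiation), one
gene-spanning pool of 6 haplotypes (human gene regions typically carry
few common haplotypes), 2% missing calls. The full-pipeline
record-count check uses 50 genes and no missingness, with the default
QC applied — per-population MAF filtering removes pool-monomorphic
sites, so every retained SNP is informative in every population.

What the generator does **not** emulate: recombination-map-driven
block boundaries, demographic history (bottlenecks, admixture),
selection, genotyping-error structure, and allele-frequency spectra
skewed toward rare variants. Passing tests therefore demonstrate
correctness of the estimators and pipeline plumbing under a controlled
model, not calibration against real HapMap panels; published
HapMap-scale contents (e.g. genome-wide SNP counts) are out of reach
of desk-scale synthetic data by design.

## Numerical choices and degenerate inputs

- EM tolerance 1e-8 (max frequency change), cap 1000 iterations;
  deterministic LE initialization everywhere.
- HWE p-values computed in log space (lgamma), with a 1 + 1e-12
  relative slack when comparing outcome probabilities to the observed
  one, guarding against ties lost to rounding.
- θ undefined (both populations monomorphic, or zero denominator) →
  NaN, excluded from gene ratios; all-NaN genes → missing.
- Zero blocks → block features missing; single-haplotype spectra →
  H = 0; fewer than 2 chromosomes → H = 0.
- Tie-breaks: reference-minor-allele ties track alt; tag-selection
  ties take the lower SNP index. Both make reruns bit-identical,
  which the pipeline asserts (byte-identical TSVs for identical
  inputs and config).

## Known limitations

- Two-population FST only (the pairwise design needs nothing more);
  no haplotype-based FST.
- EM finds a stationary point; with the deterministic initialization
  this is reproducible and, on all tested instances, at least as good
  as exhaustive grid search, but global optimality is not guaranteed
  in pathological cases.
- Partition-ligation truncates the candidate haplotype space for
  blocks wider than 8 SNPs.
- Phased input is not used even if present; sex chromosomes,
  multi-allelic sites and liftover are out of scope.
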