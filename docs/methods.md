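# Methods

`domestiscan` re-implements the bespoke computational stages of a crop
population-transcriptomics analysis: SNP-level QC and kNN imputation,
diversity/LD statistics, two selective-sweep region callers, a per-sample
introgression scan with tree confirmation, a mixed-model association engine
for eQTL mapping and binary-trait GWAS, distant-eQTL hotspot and
master-regulator inference, and iGA regulatory-network construction. This
note documents the models, the numerical choices and the synthetic-data
generator that every end-to-end test runs against.

## Genotype model and data containers

Genotypes are alternate-allele counts in {0, 1, 2} with −1 for missing;
intervals are 0-based half-open internally and converted at the VCF/GFF
boundary. MAF, missing rate and heterozygote rate are computed over
non-missing calls only. Phased haplotypes, when present, must sum to the
genotype at every non-missing entry.

### Variant filters

Sites pass only when mapping quality, total depth and site quality are all
≥ 30, the site is biallelic and more than 3 bp from any indel record
(including indels that themselves fail filters). Per-genotype: homozygous
calls need > 3 supporting reads (read literally as ≥ 4) and site quality
> 20; heterozygous calls need ≥ 2 reads per allele and genotype quality
> 20; failing genotypes are set missing rather than dropping the site.

## kNN imputation

For a missing call at (sample s, site j): every other sample is scored by
the fraction of identical non-missing genotypes over the `w` flanking SNPs
nearest to j; the `k` most similar samples that are called at j vote with
weight similarity^(−p) (p ≤ 0, so a more negative exponent sharpens the
weighting — the published tool's `p` semantics are not documented, so this
is an emulation of the printed grid's ordering, not a bit-level
replication); the entry is filled only when the winning genotype's weight
fraction reaches `r`. Sites with missing rate > 0.8 are never imputed. The
tuning sweep masks a fraction of observed calls within each of ten
missing-rate decile categories (bin edges are not stated in the original
procedure; deciles with a ≤ 10 % bottom bin are used) and scores every
grid point; the default grid is w ∈ {20, 30, 50, 65, 80} × p ∈ {−5, −7,
−9, −11} × k ∈ {3, 5, 7, 9} × r ∈ {0.5, 0.6, 0.7, 0.8} (320 points). Best
per category = max accuracy, ties to higher filling rate, then grid order.

## Diversity, differentiation, LD

* π per window: Σ over sites of the unbiased per-site heterozygosity
  n/(n−1)·2p̂(1−p̂), divided by window length in bp (a callable-length
  override exists because transcript-derived SNPs cover only genic
  sequence). This equals the mean pairwise haplotype difference per bp,
  which the tests verify by brute force.
* π ratio: per-window wild/cultivated ratio; windows with zero denominator
  are flagged undefined and excluded from quantile ranking.
* Fst: Weir–Cockerham (1984) variance components per SNP; window values
  are ratios of summed components, never means of ratios. A Hudson
  estimator is available as an option.
* LD r²: squared Pearson correlation of unphased genotype codes over
  pairwise-complete samples (composite LD), with MAF ≥ 0.05, missing
  ≤ 0.25 and heterozygote-fraction ≤ 0.88 site filters and a 5 Mb maximum
  pair distance, mirroring the upstream tool's settings.
* LD decay: 1-kb distance-bin means; the curve maximum is the mean r² of
  pairs within 1 kb; the curve is made monotone by a cumulative minimum
  before thresholding (raw bin means are noisy); half-decay distance is
  the first bin midpoint at or below half the maximum, ∞ if never reached.
* Background LD: the 95 % quantile of r² over random inter-chromosomal
  SNP pairs; the distance at which the (smoothed) intra-chromosomal curve
  falls to that level calibrates the eQTL grouping gap.

## Sweep callers

The domestication caller takes any per-window score track — windowed
Weir–Cockerham Fst by default; externally computed composite-likelihood
scores can be imported as TSV, and a cross-population EHH score is provided
— and (1) merges adjacent windows in the top 20 % of scores, (2) keeps
merged regions whose mean member score is in the top 5 % of region scores
(mean, not max: the source procedure averages scores before merging, and
ranking by region mean is the reading adopted here), and (3) intersects
with regions merged from the top 50 % of wild/cultivated π-ratio windows.
The horticultural-type caller averages per-SNP scores in 200-kb windows
(100-kb step), z-normalizes genome-wide, merges windows with z > 2.33 (the
one-sided normal critical value for P ≤ 0.01) and intersects with π-ratio
regions the same way. Quantiles are computed over defined windows only.

The EHH machinery defines EHH(d) as the probability that two random
haplotypes carrying the focal core allele are identical from the focal SNP
out to distance d; each side is traced until EHH < 0.05 and iHH is the
trapezoidal integral over both sides. The cross-population score is
ln(iHH_ref / iHH_obj) with allele-frequency-weighted pooling over core
alleles; it is a stand-in statistic with the correct sign conventions, not
a replication of any published per-SNP score.

## Introgression scan

Per cultivated focal sample, 200-kb windows (20-kb step) count — over
homozygous calls only — matches between the focal genotype and (a) the
cultivated-group consensus (most frequent homozygous genotype, focal
excluded) and (b) the donor-group consensus. The window ratio is
C_cult / C_wild over all informative SNPs (sites where all three are
defined; an open design point is whether only consensus-discordant sites
should be counted — the all-informative reading matches the worked
examples this implementation is specified against, and makes the ratio ≤
0.5 rule demand genuinely donor-like windows). Windows with ratio ≤ 0.5
and ≥ 20 informative SNPs merge into candidate regions; each candidate is
confirmed on a neighbor-joining tree over 1 − IBS distances (negative NJ
branch lengths clamped to zero) by an automated monophyly rule: confirmed
iff the smallest clade containing the focal sample and a donor leaf
contains no leaf from any other group. Confirmed regions closer than
200 kb merge. NJ replaces the original maximum-likelihood trees and the
automated rule replaces manual inspection; both substitutions are
deliberate for reproducibility at desk scale.

## Association engine

Kinship is the Gram matrix of genotypes standardized by √(2p(1−p)) with
per-SNP mean imputation of missing calls. Responses are normal-quantile
transformed (ranks/(n+1), average ties — the +1 offset avoids infinite
quantiles). Outlier samples are flagged beyond 2.5 SD on any of the first
three PCs of the log2(x+1) expression matrix; hidden expression factors
are the first 10 PCs of the transformed matrix, used as fixed covariates
(a PCA stand-in for factor-analysis confounder models). Variance
components are estimated once per response by REML on the spectrum of the
covariate-projected kinship (grid on log λ plus bounded refinement; a flat
restricted likelihood — e.g. K = I — returns the σ²_g = 0 boundary), and
every SNP is then tested by GLS under the fixed covariance σ²_g·K +
σ²_e·I, i.e. the standard two-step mixed-model approximation that makes
genome-by-transcriptome scans feasible. With K = I this reduces exactly to
ordinary regression, which the tests assert to 1e−8.

Significance thresholds are α/m (Bonferroni at α = 0.05; "suggestive" at
α = 1). Significant SNPs are grouped into loci by chaining consecutive
significant SNPs within 4.7 Mb and r² > 0.1 (both calibrated from
background LD); groups need ≥ 3 members, and the lead SNP has the minimum
p. Binary traits use the same linear mixed model.

## Hotspots, master regulators, iGA networks

Distant eQTLs are blocks whose interval does not overlap their gene
(half-open abutment counts as distant). Hotspots: lead-SNP positions are
scanned with 400-kb windows (step = window/10); each window's count is
tested against Binomial(N, window/genome) and Benjamini–Yekutieli
adjusted at 0.05; significant windows merge. This is a statistically
equivalent stand-in for specialized hotspot-scan software — the window
size and the adjustment are the interface that matters.

Master-regulator candidates must lie in a hotspot, carry their own local
eQTL and correlate (log10(FPKM+1) Pearson) beyond thresholds with at least
one gene whose distant eQTL maps to that hotspot. The default thresholds
are the operating point (0.39, −0.28); `pcc_threshold` can derive
permutation-based values, but a label-shuffling null destroys the shared
structure among genes and yields much narrower thresholds (≈ ±1.96/√n),
so the fixed operating point is the default.

iGA: genes ranked by correlation with a candidate regulator (descending
for activation, ascending for repression — both directions are run since
networks contain negative regulation); PC value = minimum hypergeometric
upper tail over prefixes ending at a pathway member (classic iGA
restriction). A gene in a merged distant-eQTL region is kept as regulator
when PC < 0.01/(expressed genes in the region); edges go to pathway
members inside the optimal prefix and carry the correlation sign. Seed
expansion admits genes whose |PCC| exceeds a permutation threshold
(P < 0.01) with at least three seed genes. The ranking universe is all
expressed genes, and merged-region gene counts include expressed genes
only (both open points decided here).

## Synthetic-data generator

Each chromosome is tiled by 200-kb blocks; a panel of 6 founder
haplotypes per block is drawn with U-shaped (Beta(0.2, 0.2)) allele
frequencies, and with probability 0.5 a variant repeats the previous
variant's founder pattern — emulating the tight clusters of
near-perfectly linked SNPs that transcript-derived variant sets contain.
Samples draw two founders per block from group-specific weights obtained
by a Balding–Nichols-style Dirichlet perturbation of the uniform weights
with drift intensity F (defaults: 0.10 wild, 0.35 per cultivated
subgroup); 95 % of block draws are selfed (one founder copied twice),
matching a predominantly autogamous crop whose accessions are
near-homozygous inbreds. A per-allele error rate of 1e−3 keeps swept or
monomorphic windows from having exactly zero diversity, as real call sets
do. Fixed lineage-private allele flips (`species_divergence`) model
distinct wild species; the default wild group is a progenitor (no flips),
while introgression-donor species in the benchmarks use 0.65, consistent
with panels where most SNPs are private to the distant wild relatives.

Default population: one wild group (30) plus four cultivated subgroups
(45 each; the 180 cultivated samples form the association mapping panel).
Sweeps restrict affected cultivated groups to a reduced founder subset
(reduction 1.0 → monomorphic); introgression tracts replace recipient
haplotypes with draws from the donor group's panel and weights.

Expression: y_g = μ_g + β_cis·x_g + Σ_m β_trans(m,g)·r_m + ε on log2
scale, with abundance 2^y − 1 truncated at 0. Defaults: 30 % of genes
cis-driven at |β_cis| = 1.5, σ = 0.25, two master regulators with 40
targets each at |β_trans| = 0.3 (so a distant effect explains roughly a
third of a target's variance — distant effects are modest relative to
local ones). Cis anchors are placed on variants that segregate (MAF ≥
0.05) in the cultivated mapping panel, and master targets are drawn > 2 Mb
from the master so their eQTLs are genuinely distant. The binary trait is
a liability threshold model over six causal variants with liability effect
4.0 per allele and 50 % prevalence; causal variants are drawn from the
least group-structured half of the common variants, reflecting traits
that segregate within every subgroup rather than between them.

### What the generator does not emulate

Read-level noise and mapping artifacts; allele-specific expression; gene
families/paralogy; recombination-map heterogeneity (LD is block-uniform);
realistic site-frequency spectra from demography (drift is a one-step
perturbation, not a genealogy); linkage between blocks beyond structure;
expression count noise (log-normal only). Passing recovery tests therefore
demonstrates the scan logic and its calibration under the assumed
statistical structure, not performance on raw sequencing data.

## Benchmark problem sizes

The benchmark flows in `domestiscan.evaluate` (used by the test suite and
`scripts/acceptance.py`) keep the study-scale sample structure (30 wild +
180 cultivated; SNP density ≈ 330/Mb, i.e. the generator default of
20,000 variants per 60 Mb) but shrink the genome so a full pass takes
about a minute:

* cis-eQTL recall: 6,600 variants / 2×10 Mb, 200 genes, 40 scored.
* sweep recovery: 5,000 variants / 2×10 Mb, one 400-kb sweep
  (reduction 0.9), 20 replicates.
* introgression: 6,600 variants / 2×10 Mb, one 600-kb tract from a
  divergent donor (divergence 0.65), 20 replicates plus per-replicate
  non-carrier scans for specificity.
* master regulators: 10,000 variants / 2×25 Mb, 150 genes (gene spacing
  wider than one LD block, matching genome-scale gene-to-LD ratios), two
  masters × 40 targets, 10 replicates.
* heritability: REML on 200 replicate responses at true h² = 0.5.
* calibration: 250 phenotype permutations × 40 widely spaced SNPs each
  (10,000 pooled p-values). A single permutation scanned against all SNPs
  cannot be tested for uniformity at this n: conditional on one permuted
  phenotype all tests share its projection onto the structure axes, so the
  pooled-permutation design is what "uniform under the permutation null"
  means operationally.

## Known limitations

* The per-SNP haplotype score is a stand-in; imported score tracks should
  be preferred when replicating composite-likelihood scans.
* The hotspot scan's smoothing differs from the cited external tool; only
  window size and FDR control are matched.
* PCA hidden factors are cruder than factor-analysis models; with strongly
  non-Gaussian confounding their detection-power gain is smaller.
* The binary-trait model is a linear LMM on 0/1 outcomes; liability-scale
  effect sizes attenuate accordingly (roughly the factor z²/(K(1−K))).
* The kNN imputer is an emulation of the published tool's interface, not
  a reimplementation of its code.
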