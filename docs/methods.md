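# Methods

## Scope and data model

introscan detects genomic segments whose local affinity contradicts an
accession's whole-genome group assignment (introgression) in a diploid,
biallelic SNP panel. The universal substrate is a samples × sites matrix of
ALT-allele dosages in {0, 1, 2} with a missing marker; VCF positions are
1-based at the boundary, while all internal interval arithmetic (block
grids, BED output) is 0-based half-open. Sites pass the standard filters
when their minor-allele frequency, computed over non-missing alleles only,
is strictly greater than 0.05 and their missing fraction strictly smaller
than 0.40; both boundaries are exclusive, so a site at exactly the
threshold is removed, and filtering is idempotent. A site at 1-based
position p belongs to block ⌊(p−1)/B⌋ of its chromosome; the tree and
D scans use B = 500 kb, admixture mapping B = 200 kb.

## Synthetic data generator

The generator exists to provide ground truth at desk scale, not to model
rice demography. Subpopulation allele frequencies follow the
Balding–Nichols model: an ancestral frequency p ~ Beta(a, b) per site
(default a = b = 0.8, giving a U-shaped frequency spectrum), then each
branch with drift parameter F ∈ (0, 1) draws
Beta(p(1−F)/F, (1−p)(1−F)/F). Nested divergence is encoded by a two-level
tree: groups listed under an internal branch (default: temperate and
tropical japonica under a japonica branch) drift from the branch frequency
rather than the root. Defaults per branch: outgroup ("african") F = 0.5,
indica and the japonica branch F = 0.15, the two japonica subgroups
F = 0.05 — ordering the divergence outgroup ≫ (indica vs japonica) ≫
(temperate vs tropical). Genotypes are Binomial(2, p_group) per accession
and site, positions are uniform without replacement, missing calls are
independent Bernoulli (default rate 0.02). Default scale: 4 groups × 40
accessions, 3 chromosomes × 5 Mb × 2500 sites — sized so that every
simulation-based check runs in seconds to minutes.

Introgression is planted as whole-tract replacement: for each carrier, all
dosages inside the tract are redrawn as Binomial(2, p_donor), emulating a
homozygous introgressed segment; carriers are an independently drawn subset
of the recipient group (default fraction 0.3). Carriers' tract genotypes
are independent draws, i.e. the tract has no single founder haplotype;
consequences for the classification rule are discussed below.

What the generator deliberately omits: linkage disequilibrium beyond the
tract structure, recombination and tract-length variation, genotype
likelihood/low-coverage error models, and selection. Passing tests
therefore demonstrate correctness of the statistics and the detection
logic under drift + planted gene flow — not robustness to LD, reference
bias, or call-rate artifacts in real resequencing panels.

The simulated phenotype is
y = effect·z(causal block) + 0.5·(mean donor ancestry across blocks) + N(0, noise_sd),
where z is the ground-truth donor dosage (0/1). The middle term is a mild
global-structure confounder; its coefficient (0.5) was fixed once so that
an association model *without* structure control is visibly miscalibrated
while the mandatory global-ancestry covariate restores calibration.

## Phylogenetic-tree method

Per block, the allele-sharing distance d(i,j) = Σₛ|gᵢ−gⱼ| / (2·n_shared)
is computed over jointly non-missing sites (the complementary kinship
1 − d is reported alongside). Blocks with fewer than `min_snps = 10`
polymorphic sites, or with an accession pair sharing no site, are NO_CALL
and excluded from all downstream testing.

Trees are built by canonical Saitou–Nei neighbor joining, which is exact on
additive distances. Negative branch lengths are clamped to zero with the
deficit transferred to the sister branch (preserving the pair's summed
length); ties in the Q criterion are broken by the lexicographically
smallest clade labels, so the topology is fully deterministic.

Classification: an accession of the recipient group is called introgressed
from the donor iff

1. strictly more than k/2 of its k nearest non-self leaves by patristic
   distance (restricted to donor ∪ recipient members; k = min(5, donor
   size); distance ties broken by leaf name) belong to the donor, **and**
2. its mean patristic distance to the donor group is strictly smaller than
   to the rest of its own group.

Condition 2 — the displacement condition — is the package's own refinement
of a pure nearest-neighbour rule. Without it, the method mirror-images:
true carriers are genuinely donor-like inside the block, so donor-group
accessions can find several carriers among their nearest neighbours purely
by exchangeability and get called in the reverse direction (in planted
simulations, up to a third of the donor group at some seeds). A genuine
carrier is far from its own group core while a confused donor accession is
not, so condition 2 removes the artifact without costing forward-direction
sensitivity; planted unidirectional tracts then yield zero reverse calls
across seeds.

Significance: the null permutes, independently per recipient accession, its
per-block call vector across all called blocks — preserving each
accession's genome-wide introgression load while breaking block structure.
The reference distribution is the maximum per-block count over
permutations; block p = (1 + #{perm max ≥ observed}) / (n_perm + 1), and a
block is significant at p ≤ α (family-wise control). Contiguous significant
blocks merge into regions. Defaults: n_perm = 1000, α = 0.05; α < 1/n_perm
is rejected. Two descriptive tests accompany the scan: the Pearson
correlation and OLS slope between the two directions' per-block counts, and
a 2×2 Pearson chi-square (1 df, no continuity correction) of calls ×
annotation overlap for enrichment against interval tracks (repeats,
sweeps); degenerate tables (zero margin, zero variance) are reported as
undefined rather than forced to a number.

## D statistic

Group allele frequencies are ALT-dosage sums over non-missing genotypes; a
site missing all data in any role population is unusable. Per site,
abba = (1−p₁)p₂p₃(1−p₄) and baba = p₁(1−p₂)p₃(1−p₄); a window's
D = (Σabba − Σbaba)/(Σabba + Σbaba), undefined (NA, never 0) on a zero
denominator. D is antisymmetric under a P1/P2 swap and insensitive to sites
with p₃ = 0 or p₄ = 1. ALT dosage is used as the derived allele by default:
with a strongly diverged, nearly fixed outgroup the (1−p₄) factor makes
orientation matter only through O. `polarize_by_outgroup=True` re-orients
sites so the outgroup major allele is ancestral.

Per-window significance uses a delete-one jackknife over the window's
usable sites (≥ 10 required; SE = 0 flags Z as signed infinity). The
default of one chunk per site is appropriate for the LD-free generator; a
chunk count parameter coarsens the jackknife to damp local LD in real
data. The genome-wide D uses a block jackknife over groups of 5
consecutive windows (2.5 Mb at the default grid), requiring ≥ 10 such
blocks. Peaks are windows with |Z| ≥ 3, merged when contiguous and
annotated by the sign of D (negative = excess P1–P3 sharing, i.e. P3 → P1
under unidirectional flow).

At the default desk scale (~190 filtered sites per 500 kb window, 30%
carriers) the window-level Z at a planted tract fluctuates around −2 to −3
across seeds: the window statistic is noticeably noisier than the tree
method, whose block-level recall/precision is ~1.0 under the same
conditions. This mirrors the qualitative behaviour expected at full panel
scale (denser sites sharpen D peaks considerably) and is reported honestly
by the acceptance script as a median over replicate datasets.

## Diversity and Fst

π per block and group is Σₛ 2p̂(1−p̂)·n/(n−1) divided by block length
(no callability mask is modelled, so block length — not callable length —
normalizes), with n the non-missing allele count; blocks with no usable
site are NA. Differentiation uses Hudson's estimator as a ratio of
averages: N = (p_A−p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1),
D = p_A(1−p_B) + p_B(1−p_A), Fst = ΣN/ΣD, NA when ΣD = 0. For two groups
drifted independently at F from a shared ancestor this estimator recovers
F (the simulation check at F = 0.2 lands within ±0.01 of the Monte-Carlo
expectation). Planted tracts depress recipient–donor Fst locally, the
signature used to corroborate tree-method calls.

## Admixture mapping

Local ancestry is estimated by a supervised two-panel binomial likelihood:
q ∈ [0, 1] maximizes Πₛ Binom(gₛ; 2, q f_A,s + (1−q) f_B,s) over a block's
informative sites (panel frequencies defined and unequal; ≥ 10 required,
else NA), with panel frequencies recomputed leaving the target out when it
belongs to a panel. The log-likelihood is concave in q, so a vectorized
golden-section search on [0, 1] to tolerance 1e-4 finds the maximum;
boundary solutions (q = 0, 1) are reached naturally. This replaces an
external unsupervised ancestry program so the pipeline is self-contained
and directly testable; an externally produced ancestry matrix can be
supplied as a TSV instead. Only two-way ancestry is supported.

Association is per-block OLS: phenotype ~ intercept + block dosage +
global mean ancestry (always included, as the minimal structure control) +
optional user covariates, with a two-sided t test on the dosage
coefficient; constant-dosage or rank-deficient designs are NA. The genomic
inflation factor λ = median(t²)/median(χ²₁) is reported over all blocks. A
kinship random effect is deliberately out of scope at this panel scale.

## Numerical and degenerate-input conventions

- Missing dosage sentinel −1; MAF/frequency computations never impute.
- Frequencies are clipped away from {0, 1} by 1e-9 (Beta parameters) or
  1e-6 (likelihood) to avoid log-of-zero; clipping is far below any
  reported precision.
- Undefined statistics propagate as NA (D with zero denominator, Fst with
  zero denominator, correlation under zero variance, chi-square with a zero
  margin); infinite jackknife Z (SE = 0) is flagged as ±inf, never NaN.
- All tie-breaks (NJ joins, nearest-neighbour ordering) are lexicographic
  in accession/clade names; all randomness flows through explicit seeds, so
  identical seed + configuration reproduces outputs bit for bit.

## Known limitations

- No LD or recombination in the generator; detection power on real
  low-coverage panels will differ, especially for the window-level D.
- The tree method's classification is a declared rule (k-NN majority +
  displacement), not a reconstruction of any published clustering
  criterion; block-level calls near tract edges are only as sharp as the
  grid.
- Per-bp π and Fst use block length, not callable length.
- Admixture mapping assumes two source panels and fixed-effects structure
  control only.
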