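# Methods

This note documents the models behind `magicpop`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions that were genuinely open.

## Breeding simulation

Meiosis follows the Haldane model: the crossover count on a chromosome of
genetic length L Morgans is Poisson(L), crossover positions are uniform, and
there is no interference or obligate chiasma. A gamete alternates between the
two parental homologs at the crossover points, starting from a random
homolog. A 16-founder funnel crosses founders pairwise over four generations
(2-way, 4-way, 8-way, 16-way); the 16-way F1 is then selfed by single-seed
descent, `n_selfing = 7` generations by default so finished lines are F8
material from an F1.

Two classical consequences are used as end-to-end checks. First, junction
density: each homolog of the 16-way F1 has passed through three meioses in
which every crossover joins distinct ancestries, contributing ~3 junctions
per Morgan, and the selfing phase contributes ~2 more (as in biparental
RILs), giving ~5 junctions per Morgan — over a 36.6-Morgan genome, ~183
junctions per finished line. Simulations here give 5.0 per Morgan at F8
(4000 lines) and ~182 junctions per RIL (1000 lines, 21 chromosomes).
Second, residual heterozygosity halves every selfing generation from 100% at
the 16-way F1 (whose homologs carry disjoint founder sets), so F8 lines are
2⁻⁷ ≈ 0.78% heterozygous. Residual heterozygosity sits in rare long blocks,
which makes the genome-fraction estimator heavy-tailed; measuring it to
±0.05% needs on the order of 10⁴–10⁵ line-Morgans, hence the 8000-line,
10-Morgan configuration used in the test.

Junctions are counted per homolog after fusing adjacent same-founder blocks,
chromosome ends excluded; where a line is not yet fixed the two homolog
counts are averaged.

`expand_population` applies random bijections of founder labels to every
mosaic and re-projects genotypes from the panel. Breakpoints, the genetic
map and linkage are untouched; only which founder carries which segment
changes, so per-line junction counts are invariant and allele frequencies
are preserved in expectation because the funnel design is exchangeable in
the founders.

## Synthetic founder panels and traits

Founder genomes are partitioned into blocks (default 5 Mb) and the 16
founders split into k haplotype groups per block, k drawn from a
distribution over {1..4} (default mass 0.15/0.40/0.30/0.15), reflecting a
panel in which most loci carry at most three or four haplotypes. Within a
block, members of a group are genotypically identical. Every site in a
k ≥ 2 block segregates among the k haplotypes — panel sites represent SNPs
called among the founders, so columns constant across all haplotypes are
not represented. This has a useful consequence: two distinct haplotypes
mismatch at a majority of block sites, which is what makes them separable
by both clustering and the two-state segmentation below. Group haplotypes
are kept distinct by rejection sampling, so the truth records equal the
realized haplotype counts exactly.

Default desk-scale dimensions are 3 chromosomes × 2000 sites × 1 Morgan
(60 Mb); the block-length distribution of real panels is not pinned by any
published value we rely on, so block length is a free parameter.

Traits follow y = μ + Σ β·g + polygenic + ε. The polygenic term is a dense
Gaussian effect vector over a random 10% of sites, rescaled to the declared
variance — a polygenic mixture of a few large and many small effects. When a
target h² is declared, the residual variance is set from the realized
genetic variance as Vg(1−h²)/h², so the target is met in-sample by
construction and recovered by regression-based estimators to within
sampling error.

The yield/protein generator plants antagonistic pleiotropy: a set of shared
QTLs receives effects of opposite sign on the two traits, mixed with
private polygenic scores to hit a declared genetic correlation (default
−0.8). Traits are expressed in population-sd units. An optional awn locus
shifts carriers perpendicular to the realized phenotypic trend by a
declared amount; trait QTLs are kept out of LD range of the awn locus
(±1000 site indices ≈ 0.5 Morgans at default density) so the planted
perpendicular shift is the only awn-linked signal. Even so, single-seed
recoveries of the shift scatter by ~±0.1 sd because the fitted trend angle
varies; tests therefore average over seeds.

Coverage is Poisson: for founder f with genome-wide mean m_f (reads per
target base), a gene of length ℓ samples Poisson(m_f·ℓ)/ℓ, matching
read-count sampling; planted deletions have expected and sampled coverage
exactly 0. Per-target-base coverage removes gene length as a confounder
before the founder-mean normalization in the deletion index.

## Haplotype diversity

Per-gene clustering computes absolute (Manhattan) distances between founder
rows and cuts a complete-linkage dendrogram so every within-cluster pair has
similarity 1 − d/m ≥ threshold (default 0.95). Complete linkage makes the
fcluster distance cut exactly the max-pairwise-distance criterion.

The pairwise segmentation is a two-state Viterbi path: in the SAME state a
matching site scores +s and a mismatch −s (the DIFF state reverses the
signs), and each state change costs T (defaults s = 1, T = 200). The
symmetric emission was chosen so the two states are exchangeable and the
limits are clean: as T → ∞ the result is one segment carrying the majority
relation; as T → 0 the per-site relation. Ties break toward staying in
state (fewer segments) and then toward SAME. Optimality is verified against
exhaustive enumeration for vectors up to 14 sites.

Per-site haplotype counts join founders connected by SAME relations and
count connected components, not cliques: mutually inconsistent dense
relations collapse toward one haplotype rather than inflating the count,
which is the desired behaviour where local variation is self-contradictory.

## Mixed-model association

The trait covariance is V = Kσg² + Iσe², K = GG′/p from standardized
tagging-marker dosages (greedy windowed pruning at R² > 0.99). Variance
components are maximum-likelihood: K is eigendecomposed once and the
profile likelihood optimized over log(σe²/σg²) on a bounded interval
(the EMMA device); μ and σg² have closed forms given the ratio. Whitening
uses A⁻¹ = U diag(1/√(σg²wᵢ + σe²)) U′, so A² = V exactly; the transformed
intercept A⁻¹1 is no longer constant and is carried through every
regression. A single global GRM is used; the scanned chromosome is not
excluded (a leave-one-chromosome-out GRM can be supplied via the `K`
argument of `stepwise_qtl`).

SNP tests are 1-df t-tests on the whitened data, computed in log space so
extreme signals do not underflow (logP capped at 320). Haplotype tests
regress on the 16 founder dosage columns; the sum-to-one constraint makes
one column redundant given the intercept, so one founder is dropped and the
F-test numerator df taken from the realized design rank (15 when full
rank). Permutation thresholds shuffle the whitened phenotype — exchangeable
under the fitted null — rescan, record the genome-wide maximum logP, and
take the empirical (1−α) quantile over n_perm = 1000 permutations
(α = 0.05 by default).

Calibration caveat: when variance components are estimated from the same
phenotype and the GRM is built from the scanned markers, the threshold is
conservative if markers are few relative to lines (the trait's polygenic
signal is partially absorbed into the fitted V — proximal contamination).
In the regime the method is designed for (tagging markers ≫ lines, e.g.
~2000 markers for ~120 lines in the calibration test, mirroring the
55k-markers/504-lines shape of real analyses) the genome-wide type-I error
is 5% to within binomial error.

QTL intervals take all sites on the peak chromosome with logP within
d = max{2, 0.1x} of the peak x; SNP-based intervals are then extended on
each side by min(5 Mb, distance to the nearest outside SNP sharing a strain
distribution pattern with any highly associated site). SDPs are canonical
bit patterns of founder alleles, identified with their complements.
Stepwise mapping rescans after regressing the raw phenotype on all recorded
peak markers (variance components are refit on each residual phenotype so
later tests remain correctly whitened — a choice made for correctness since
either convention is defensible); it stops at the first non-significant
scan, on collinearity of a new peak with recorded ones, or when residual
variance is numerically zero. Loci merge across scans when intervals
overlap and share at least one SDP (union-find, so chains are transitive).
Fisher combination is χ² = −2Σln pᵢ on 2k df, computed in log space.

## Gene deletion scores

D_gf = (per-base coverage of gene g in founder f)/(founder f's mean
coverage), capped at 2 against capture-efficiency outliers; the index is
continuous (a binary version is a threshold away, but continuity preserves
partial-deletion information). S_ij = Σ_f H_ijf D_jf with founder dosages
taken at the gene midpoint — the within-gene aggregation choice matters
little at these gene lengths. GDS scans standardize gene columns, build the
relationship matrix from the GDS itself, and otherwise reuse the SNP-scan
machinery; genes whose logP reaches 90% of a supplied co-located SNP peak
are flagged.

## Genomic prediction

Ridge, LASSO and elastic net are fit on standardized dosages with the
shrinkage weight chosen by inner cross-validation on the training split
only (10-fold, minimum-CV-error rule, no 1-SE rule; path of 30 candidate
weights). Accuracy is the mean Pearson correlation between predicted and
observed values over repeated 90/10 splits (50 rounds by default; fold
assignments are seeded and stored). Theoretical extremes stack every
positive coefficient at its marker's observed maximum standardized dosage
and every negative one at its minimum.

Ridge↔BLUP equivalence: with K = GG′/p and fitted (σg², σe²), ridge on the
GLS-centered phenotype at penalty λ_ridge = p·σe²/σg² reproduces BLUP
predictions to machine precision — the familiar λ = σe²/σg² is the penalty
on the per-marker effect-variance scale, and the factor p converts it to
the ridge penalty for this marker coding. This identity is what ties ridge
prediction accuracy to trait heritability (accuracy ≈ √h² at best).

## Protein-yield deviation

Both traits are Z-scored with the sample sd (n−1; the convention is pinned
for determinism, and the statistic is invariant to affine rescaling of
either trait anyway). The trend is a symmetric Theil-Sen line: all pairwise
segment angles are folded onto the half-circle of undirected directions and
their circular (geodesic) median taken; the slope is its tangent. The
circular median minimizes summed geodesic distance on a circle of
circumference π, its cost function is piecewise linear with minima only at
data angles (evaluated in O(m log m) with prefix sums), and flat valleys are
resolved at their midpoint. Because reflections of the direction circle are
isometries, swapping the axes maps the fitted slope exactly to its
reciprocal — the property a simple linear median of angles does not have
once pairwise slopes span both signs. PYD is the signed perpendicular
distance (GPC_z − a − b·GY_z)/√(1+b²), positive above the trend (more
protein than the yield trade-off predicts).

## Introgression scan

Per-founder non-reference allele fractions are computed in 10-Mb windows
stepped by 5 Mb (each site lands in at most two windows). A window
qualifies for a given carrier set when the minimum carrier fraction exceeds
the maximum non-carrier fraction; maximal runs of qualifying windows become
calls whose boundaries are the union extent of their windows, so a call can
overhang a true segment by up to one window on each side. Carrier sets are
supplied (known introgressions); an exploratory top-k search per window is
available but flagged as such. Coverage is reported alongside but not used
in the automated rule, since how to weigh it against allele-fraction
evidence is qualitative. Segregation bias within a called region compares
expected founder counts (summed mean regional dosage per line) against the
uniform 1/16 expectation with a chi-square on 15 df.

## What the synthetic data do not emulate

No sequencing reads or base errors, no imputation machinery (founder
dosages are exact unless deliberately blurred at junctions), no selection
during breeding, no crossover interference, no shared funnels between lines
(each RIL gets an independent funnel, so family structure is weaker than in
a real population bred from 15 funnels), and block-exact founder haplotypes
with no intra-block mutation. Passing tests therefore demonstrate that the
algorithms are implemented correctly and calibrated under their stated
assumptions, not that they are robust to imputation error, shared-pedigree
confounding, or reference-bias artefacts in real data.

## Problem sizes

Defaults used in the test suite are chosen to keep the full run in a few
minutes on one CPU: 3×2000-site panels, 300–500 RILs, 200–400 permutations
per threshold, 200 replicate datasets for calibration, 4000/1000 RILs for
the junction statistics, and 8000 lines for the heterozygosity law.
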