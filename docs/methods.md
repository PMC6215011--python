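# Methods

## Data model

Genotypes are diploid biallelic SNP calls coded 0/1/2 (copies of the
alternate allele) with an explicit missing sentinel, carried in a
`GenotypeMatrix` together with individual ids, locus ids of the
reduced-representation `tag_position` form, and a per-individual group
label. GENEPOP is the interchange format: the writer emits the 3-digit
dialect (`001` reference, `002` alternate, `000000` missing, one POP block
per group); the reader accepts 2- and 3-digit codes and maps the smaller
observed allele code to the reference allele. A locus where only a single
code above `001` is observed is decoded as all-alternate, which makes the
write→read round trip the identity on every representable matrix.

Locus filtering retains loci genotyped in ≥ 50% of individuals with pooled
minor allele frequency ≥ 0.05 (both inclusive), then keeps one SNP per tag
(lowest position, ties lexicographic). MAF is computed over all individuals
jointly, matching a catalogue-level filter applied once before any split
design. Expected heterozygosity uses the small-sample correction
2p̂(1−p̂)·n_c/(n_c−1) with n_c called gene copies.

## Bayesian logistic-FST outlier model

For locus *i* and group *j*, with n_ij called gene copies and a_ij
alternate-allele copies:

    a_ij ~ BetaBinomial(n_ij, θ_ij p_i, θ_ij (1 − p_i)),
    θ_ij = 1/FST_ij − 1,
    logit(FST_ij) = δ_i α_i + β_j.

Priors: p_i ~ Uniform(0,1); α_i ~ N(0,1); β_j ~ N(−1,1);
Pr(δ_i = 1) = 1/(1 + prior_odds_neutral), default prior odds 10. These are
the published defaults of the reference formulation of this model family;
only the prior odds is a study-level setting.

The sampler is a Metropolis-within-Gibbs sweep, vectorized across loci:

* **p_i** — random walk with reflection at the (0,1) boundary (symmetric,
  so the uniform prior contributes nothing to the acceptance ratio);
* **α_i** — random walk on currently included loci with the N(0,1) prior
  ratio;
* **δ_i** — reversible-jump toggle. A birth proposes α* from the N(0,1)
  prior, so proposal and prior densities cancel and the acceptance ratio is
  the likelihood ratio times 1/prior_odds (times prior_odds for a death).
  No Jacobian appears because the prior draw matches the dimensions;
* **β_j** — scalar random walk per group with the N(−1,1) prior ratio.

Pilot runs tune per-locus proposal widths for p and α and per-group widths
for β toward acceptance rates in [0.25, 0.45] (width ×1.25 above, ÷1.25
below). After burn-in, `n_output` states are retained at the thinning
interval. The default configuration is the study-scale one (10,000 output ×
thinning 10, burn-in 10,000, 20 pilots × 10,000); `MCMCConfig.reduced()`
(400 output × thinning 2, burn-in 400, 4 pilots × 200) is the profile the
test suite and the acceptance script use — at the simulated effect sizes
(allele-frequency difference 0.9) the posterior for a planted locus saturates
within a few hundred sweeps, and the reduced profile reproduces the long-chain
inclusion probabilities to within Monte-Carlo error ~0.04.

q-values follow the posterior-probability convention: q_i is the mean of
(1 − P_j) over loci with P_j ≥ P_i, i.e. the expected FDR of the list
thresholded at locus *i*. Ties share the q of the last tied element.
Outlier sets use q ≤ threshold.

Missing genotypes are simply absent from a_ij/n_ij; no imputation enters the
likelihood. The model is written for J groups but exercised and tested only
for J = 2.

## Weir–Cockerham θ̂

Per locus, θ̂ = a/(a + b + c) from the among-group (a), among-individual
(b) and within-individual (c) variance components, with per-locus,
per-group sample sizes (missing calls excluded). Loci with an undefined
denominator (monomorphic, or a group without calls) yield NaN. The test
suite checks equality (1e-10) against an independently coded hierarchical
ANOVA oracle on random small instances.

## PCA scan

Each SNP is standardized as (g − 2p̂)/√(2p̂(1−p̂)) with missing entries
contributing zero after centering, then regressed (with intercept) on the
leading K PC score vectors. The K z-statistics per SNP are combined into a
robust Mahalanobis D² using a minimum-covariance-determinant estimate with
support fraction 0.75, so that outlier loci cannot inflate the null
covariance. D² is rescaled by the genomic inflation factor
λ = median(D²)/median(χ²_K) and referred to χ²_K; q-values are
Benjamini–Hochberg. K comes from an automated Cattell scree rule: the
largest index whose eigenvalue drop exceeds τ (default 0.1) of the range of
the eigenvalues under consideration. The pipeline applies the rule to the
leading `pca_k_max` (default 10) eigenvalues — the visible part of a scree
plot — because on a full near-Marchenko–Pastur spectrum the trailing
rank-deficient eigenvalue creates a spurious terminal "elbow".

## Structure diagnostics

The GRM is the allele-frequency-standardized (VanRaden-type) estimator
G = ZZᵀ/(2Σp̂(1−p̂)) with mean-imputed missing calls; it is invariant to
allele relabeling and individual order. The relatedness tree applies
Saitou–Nei neighbor joining to the induced squared-Euclidean distance
d(x,y) = G_xx + G_yy − 2G_xy; negative branch lengths are clamped to zero
with the deficit moved to the sister branch, preserving pairwise path
lengths, so additive matrices are reproduced exactly.

Cluster number is chosen by k-means (25 restarts, fixed seed) on the PC
scores with BIC(k) = n·ln(WSS_k/n) + k·ln n, ties toward smaller k. The
clustering uses the **full** score space: in a high-dimensional isotropic
cloud a split can only remove a ~1/d fraction of the within-cluster sum of
squares, so the k·ln n penalty correctly selects k = 1 under panmixia,
whereas on a handful of components k-means always carves noise. This BIC
clustering together with PCA stands in for a variational admixture model as
the "number of clusters" check; admixture-proportion estimation is out of
scope.

## Split-half replication and nulls

Balanced designs reuse the full minority morph (34) against each half of a
random disjoint bipartition of the majority morph (31 + 31). Randomized
designs draw two disjoint uniform sets of 34 from all 96, ignoring labels —
disjoint equal groups mirror the balanced geometry. After subsetting, loci
are re-checked against the call-rate/MAF thresholds; per-run dropped loci
are recorded and intersections are taken over the common retained set.
Each run's chain seed is the base seed plus the run index.

Overlap statistics: expected shared count n₁n₂/L; exact hypergeometric
upper-tail probability of the observed overlap; and both top-locus
probabilities — (1/L)² for a pre-specified locus topping two independent
uniform rankings, and 1/L for the two top loci merely coinciding. The two
interpretations answer different questions, so the report carries both.

## Morphometrics

Morphs are split by two-means on the forewing:body ratio (25 restarts,
fixed seed); the threshold is the midpoint of the cluster means. Dimorphism
requires a strict positive gap between the clusters' ratio ranges *and* at
least 10% of records in each cluster: 1-D k-means clusters are contiguous,
so range non-overlap alone is vacuous, and a near-empty cluster is an
outlier measurement, not a morph. The wing model is Gaussian OLS of
forewing length on body length, sex, altitude (continuous meters; the three
sampling zones are 90/130/200 m) and morph class, with constant regressors
dropped with a warning. A categorical-altitude variant can be fit by
recoding the column before the call.

## Synthetic data

`simulate_genotypes` emulates a post-filter GBS matrix for 34 + 62
individuals at 6,843 loci by default. Neutral loci share one ancestral
frequency per locus drawn uniform on [0.05, 0.95] — a flat spectrum that
mimics the effect of a MAF ≥ 0.05 filter without asserting a
site-frequency model. Both groups draw binomial(2, p) genotypes from that
shared frequency (panmixia); an optional `background_fst` adds
Balding–Nichols drift, default 0. Planted loci (default 3) use
group-specific frequencies 0.05 vs 0.95 — a near-fixed difference, the
"island of divergence" signature. Each genotype is independently missing
with rate 0.1 (within the ≥ 50% call-rate regime); missingness is
independent of genotype and group by construction. An option emits two
SNPs per tag to exercise the one-SNP-per-tag filter.

`simulate_morphometrics` draws the forewing:body ratio from class-specific
truncated normals: mean 1.06 (dispersion 0.15) on support [0.70, 1.50] for
macropterous and mean 0.26 (dispersion 0.28) on support [0.02, 0.55] for
micropterous. The bounds encode morphological limits (vestigial wings are a
small positive fraction of body length; full wings at least body-sized) and
reproduce the complete separation of observed ratio distributions that
unbounded normals with these dispersions would violate. The dispersions are
interpreted as per-individual SDs by default; `dispersion_is_se=True`
reinterprets them as standard errors of class means (SD = value·√n), since
either reading of a published "±" is possible. Body length is normal per
sex (females larger: 10.5 vs 8.5 mm, SD 0.9), forewing = ratio × body +
N(0, 0.12) measurement noise, and altitude is drawn uniformly from the
three zones, independent of morph.

What the generator does **not** emulate: read depth and allele dropout,
genotyping error, linkage between loci, inbreeding, spatial or familial
relatedness structure, and any real site-frequency spectrum. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated sampling model, not robustness to those
real-data artifacts. One visible consequence: mean heterozygosity of the
simulated matrix (~0.37) is higher than typical empirical GBS values,
because the flat frequency spectrum lacks the rare-allele excess of real
data.

## Numerical choices and problem sizes

* Beta-binomial log-likelihoods via `scipy.special.betaln`; the constant
  binomial coefficient is dropped (it cancels in every acceptance ratio).
* Proposal widths clipped to [1e-4, 10]; initial p from the empirical
  pooled frequency with a half-count prior.
* The simulation-based suite uses 2,000-locus scenarios, the reduced chain
  profile and 20 seeds for the calibration and power properties; single-run
  examples use 300–500 loci. These sizes give Monte-Carlo error well below
  the tested margins while keeping the suite fast.
* `filter_loci` keeps individual order and genotype values untouched;
  operations never mutate their input matrix (the pipeline writes derived
  files only).
* Degenerate inputs fail loudly: empty matrices, all-missing individuals,
  zero-call loci, monomorphic loci passed to the Bayesian scan, k or K
  bounds exceeding the data, non-symmetric distance matrices.

## Known limitations

* The Bayesian model assumes unlinked biallelic loci and two groups;
  multi-group scans, island-model hierarchies and haploid data are out of
  scope.
* q-value calibration is inherited from the posterior probabilities; with
  short chains the q-values of mid-probability loci carry Monte-Carlo noise
  of a few percent.
* The scree rule and BIC clustering are heuristics; on data with subtle
  structure they can disagree, and both are reported.
* The NJ implementation is O(n³) — fine for ≤ a few hundred individuals.
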