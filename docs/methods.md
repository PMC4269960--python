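# Methods

## The model

gsblup implements univariate genomic prediction with the GBLUP /
RR-BLUP mixed model. After phenotype preprocessing, each individual
carries one value per trait and the model is

    y = mu·1 + g + e,   g ~ N(0, K·sigma_g^2),   e ~ N(0, I·sigma_e^2)

where y is the vector of preprocessed phenotypes, mu the population
mean, g the additive genetic values, K the realized additive
relationship matrix computed from genome-wide marker dosages, and e
independent residuals. Narrow-sense heritability is reported as
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). Because y is a vector of
per-genotype means (entry means), this h^2 is on the entry-mean scale,
not the plot scale; it is reported as-is.

### Relationship matrix

Dosages are taken on the [0, 2] scale (the number of copies of the
counted allele). With sample allele frequencies p_j, the centered matrix
is W = M − 2p and

    K = W W' / c,   c = 2 Σ_j p_j (1 − p_j),

summing over polymorphic markers only (VanRaden's first method, the
convention of the rrBLUP ecosystem). Monomorphic markers carry no
relationship information and are excluded from both W and c. Because
the centering frequencies come from the sample itself, W is
column-centered, K1 = 0, and two useful identities follow exactly: the
GLS estimate of mu equals the arithmetic mean of y, and the GEBVs sum
to zero.

### REML by spectral decomposition

Variance components are estimated by restricted maximum likelihood,
parameterized by the ratio lambda = sigma_e^2 / sigma_g^2. The data are
rotated into the orthogonal complement of the intercept (an orthonormal
basis U0, built once by QR), K is eigendecomposed there — eigenpairs
(xi_i, u_i), i = 1..n−1 — and with eta_i = u_i' y the profiled
restricted log-likelihood is

    l_R(lambda) = −½ [ (n−1) ln(2π σ̂g²) + Σ_i ln(xi_i + lambda) + (n−1) ],
    σ̂g² = (1/(n−1)) Σ_i eta_i² / (xi_i + lambda).

One O(n³) eigendecomposition per fit makes each likelihood evaluation
O(n), so the 1-D search over ln lambda ∈ [−20, 20] (bounded Brent,
tolerance 1e−8) is essentially free. The bounded minimizer never
samples the interval endpoints, so after the interior search the
likelihood is evaluated at both bounds explicitly and the best point
wins; a boundary optimum (h² numerically 0 or 1) is reported with a
warning flag, not an error — at small n the sampling distribution of
ĥ² genuinely puts mass on the boundary. Eigenvalues more negative than
−1e−10 relative are an error; small negative values are clipped to zero
as PSD rounding noise.

From the optimum: σ̂e² = λ̂ σ̂g², μ̂ = GLS mean,
ĝ = K (K + λ̂I)⁻¹ (y − μ̂1), residuals ε̂ = y − μ̂ − ĝ (an exact
decomposition), and the dual coefficients α = (K + λ̂I)⁻¹(y − μ̂1) are
stored for the marker back-solve.

### Marker effects and candidate prediction

Per-marker additive effects are the ridge back-solve û = W'α / c, which
satisfies W û = ĝ to machine precision (the GBLUP/ridge identity;
verified at 1e−8 in the tests). Selection candidates are scored by
centering their dosages with the *training* frequencies —
w = m − 2p_train — and GEBV = w·û over the markers shared with the
training panel. The training population defines the model's coordinate
system, so candidate frequencies are never used. Effects of training
markers the candidates lack are dropped (no rescaling), with a warning
reporting the overlap; overlaps below 0.5 (configurable) are refused
outright.

## Phenotype preprocessing

Plot-level observations from designed trials (RCBD, alpha lattice,
augmented) are reduced to genotype means with a linear mixed model fit
by REML: genotype as a fixed effect (cell-means coding, so the estimate
is directly the adjusted genotype mean on the phenotype scale) and
replications and/or incomplete blocks as random intercepts, blocks
nested in replications when both are recorded. The restricted
likelihood is profiled over the variance ratios theta_k =
sigma_k²/sigma_e² and maximized over log theta ∈ [−12, 12] (bounded
Brent for one component, Powell for two); the GLS genotype means are
computed at the optimum with a dense Cholesky solve. The augmented
design is modeled identically to the alpha lattice — genotype fixed,
block random — with unreplicated entries contributing single
observations. Trials with design UNKNOWN, or with no
replication/block information, fall back to the per-genotype arithmetic
mean; so does a trial whose residual degrees of freedom would be
nonpositive, where the mixed model is unidentifiable. Rows missing the
trait value are dropped first and genotypes left with no observation
are omitted. When several trials are combined, adjustment happens
within each trial first and the per-genotype values are then averaged,
unweighted, over the trials in which the genotype appears.

An independent check: statsmodels MixedLM on an unbalanced RCBD fixture
reproduces the adjusted genotype means to ~1e−5.

## KNN imputation

Missing dosages are filled from the k (default 5) nearest individuals.
Distance between two individuals is the Euclidean distance over the
markers observed in both, scaled by sqrt(m / m_shared) so that sparsely
overlapping pairs are not spuriously close; ties break by ascending row
index. Neighbors missing the target marker are skipped in favor of the
next nearest; if no reachable neighbor has data there, the column mean
is used. Imputed dosages stay continuous (rounding would discard
information and nothing downstream requires integrality) and the output
is placed on the canonical [0, 2] scale. A matrix with no missing cells
passes through untouched. Imputation quality itself is deliberately not
asserted anywhere — the method is pinned by an exhaustive brute-force
oracle, not by a claim about accuracy.

## Cross-validation

Accuracy is estimated by seeded k-fold cross-validation (default k=10):
individuals are shuffled once and split into near-equal folds (the
n mod k larger folds fall where the shuffle puts them); each fold in
turn is held out while kinship, variance components and marker effects
are refit on the remainder, *including* the centering frequencies and
scale constant, so nothing leaks from the validation set; held-out
GEBVs are predicted by the marker-effect route and the fold's Pearson
correlation with the observed adjusted phenotypes is recorded.
Accuracy is the mean over folds. A fold with zero variance on either
side yields an undefined correlation, which is excluded from the mean
(setting it to 0 would bias toward zero) with a mandatory warning.
KNN imputation, when needed, is done once before CV, not per fold.

## Synthetic populations

The simulator provides the inputs for every test. Genotypes are
unlinked biallelic markers: per-marker allele frequency
p ~ Uniform(0.05, 0.5) by default (a GBS-like site-frequency spread; no
linkage disequilibrium, no population structure), dosages
Binomial(2, p) per individual. Traits are purely additive: n_qtl
markers drawn uniformly get N(0, 1) effects, and Gaussian noise is
calibrated against the *realized* breeding-value variance so
var(tbv)/(var(tbv)+σe²) equals the requested h² exactly per dataset —
sharper recovery tests at small n than calibrating to the expected
variance. h²=0 degenerates to pure N(0, 1) noise with all breeding
values zero. Trials place each genotype once per replication with
N(0, block_sd²) intercepts (per replication for RCBD, per incomplete
block of block_size genotypes nested in replications for
alpha-lattice/augmented) plus N(0, plot_sd²) plot noise. Everything is
deterministic given the seed.

Because the simulated markers are unlinked and the architecture purely
additive, passing tests demonstrate correct inference under the model's
own assumptions; they say nothing about LD structure, dominance,
epistasis, genotype-by-environment interaction or structured
populations in real data.

## Verification problem sizes

The statistical checks run at the sizes the methods are meant for while
staying cheap: the REML optimizer is compared against a dense
2001-point grid oracle at n=30 (where explicit inverses are exact
enough); the route identities at n=50, m=200; heritability recovery as
the mean over 20 replicates at n=300, m=1000, 50 QTL; cross-validation
behavior over 5–10 replicates at n=200–300. At these sizes the whole
suite runs in well under a minute. The dense REML oracle is written in
contrast form (difference matrix L with L1 = 0) rather than profiling
the intercept through 1'(K+λI)⁻¹1: the two are the same restricted
likelihood up to a λ-free constant, but the contrast form remains
accurate when the optimum sits at a boundary and K+λI is
ill-conditioned.

## Known limitations

- Univariate models only; multi-trait runs fit one model per trait and
  combine ranks through the selection index.
- The entry-mean h² overstates plot-level heritability when trials are
  replicated.
- Expected cross-validated accuracy is bounded by the n/(n + Me)
  information limit; at n=300 with 1000 unlinked markers and h²=0.5 it
  is ≈0.29, so single replicates fluctuate by ±0.05 — accuracy figures
  from one CV pass should be read with that noise in mind.
- The KNN distance scaling is this package's own choice (pinned by the
  brute-force oracle); other implementations may weight overlap
  differently.
- File formats are the package's plain-text TSV/CSV conventions; VCF
  and PLINK inputs are out of scope.
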