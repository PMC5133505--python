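# Methods

## Model and test

`wustat` tests, per gene region, the null hypothesis that phenotype
similarity between pairs of unrelated individuals is unrelated to their
genetic and/or expression similarity. The statistic is a weighted U
statistic

U = Σ_{i≠j} f(a_i, a_j) · g(t_i, t_j) · h(y_i, y_j),

with the phenotype kernel h the outer product of centered, tie-averaged
ranks scaled by their sample variance (n−1 denominator), and f, g Gaussian
similarities of the burden score and of expression. Modes G / T / GT set
g ≡ 1, f ≡ 1, or neither. Because the ranks are standardized by the sample
variance, the identity Σ_{i≠j} h(y_i, y_j) = −(n−1) holds exactly (also
under ties), and U with f ≡ g ≡ 1 equals −(n−1) identically — both are
enforced by tests.

Binary phenotypes (e.g. hypertension status) are handled identically:
cases share one averaged rank and controls another. Validity does not rest
on a distributional model for the phenotype but on permutation symmetry,
which the binary coding satisfies.

### Burden score

a_j = Σ_k w_k v_{jk} / (2 Σ_k w_k) with w_k = 1/√(p_k(1−p_k)), v the
minor-allele dosage. SNVs are recoded to the minor allele when the
alternate-allele frequency exceeds 0.5; MAF = 0 SNVs must be (and in the
screen are) removed beforehand. Missing dosages are imputed to the SNV's
mean dosage 2·MAF by default; a listwise option marks affected samples
instead so callers can drop them. a_j is monotone in every dosage and
confined to [0, 1] (property-tested).

## Null distribution

Writing z for the centered ranks scaled to unit sample variance and M for
the elementwise product f∘g with zeroed diagonal, U = zᵀMz. Under
permutation of the phenotype, z satisfies Σz_i = 0 and Σz_i² = n−1
*exactly*; the null model treats z as uniform on that sphere. With
λ_1..λ_{n−1} the eigenvalues of PMP (P = I − J/n) restricted to the
sum-zero subspace, U/(n−1) is a χ²-weighted mean, and the ratio-of-
quadratic-forms identity gives

P(U ≥ u) = P( Σ_i (λ_i − u/(n−1)) χ²_{1,i} ≥ 0 ),

a tail probability of a linear combination of χ²₁ variables. This is
evaluated by numerical inversion of the characteristic function
(Gil-Pelaez/Imhof form of the Davies method; details below).

Why the sphere matters: at the default bandwidth the similarity matrices
are within O(1/n) of constant, so M ≈ (J − I) + δ with a tiny fluctuation
δ. The (J − I) part contributes a permutation-*constant* term to U
(zᵀ(J−I)z ≡ −(n−1) given the two constraints). A null model that treats
the per-eigenvector χ² components as independent — e.g. U ≈ Σλ(χ²−1) with
λ from PMP and z modeled as sum-zero Gaussians — assigns that constant
block variance 2(n−1) it does not have, and in simulation its rejection
rate at α = 0.05 was 0.000 with median p = 1.0. The spherical construction
removes the spurious variance structurally: adding c to every eigenvalue
shifts u by c(n−1) and cancels in the weights λ_i − u/(n−1). It also makes
the test exactly invariant to affine rescalings of the similarity matrix,
which is what keeps the near-degenerate (rare-variant, wide-bandwidth)
regime calibrated: to first order the Gaussian kernel with a huge
bandwidth is an affine function of −(a_i−a_j)², so the test behaves like a
squared-distance-kernel test at full power and correct size. Validation on
simulated data (n = 142, rare-heavy MAF spectrum): Pearson r ≥ 0.999
between −log10 asymptotic and −log10 permutation p-values, per-mode type-I
error within the 99% binomial band of 0.05 at 2,000 replicates, and
KS-uniform null p-values.

The remaining approximation is the usual permutation-CLT one — projections
of permuted rank scores onto eigenvectors are treated as Gaussian — which
is certified by the built-in permutation oracle
(`permutation_pvalue`, p = (1 + #{U_perm ≥ u}) / (B + 1), seeded and
vectorized).

Degenerate cases: an all-zero mixture (M = 0) and a permutation-constant
statistic (all weights λ_i − u/(n−1) at numerical zero, e.g. a constant
expression probe in mode T) raise a degenerate-test signal; the screen
records such entries with missing p and a reason, and never aborts.

### Characteristic-function inversion

P(Σλ_iχ²₁ ≥ x) is computed from the Gil-Pelaez/Imhof integral
½ + (1/π)∫₀^∞ sin θ(u)/(u ρ(u)) du with
θ(u) = ½Σ arctan(λ_i u) − xu/2 and ρ(u) = Π(1 + λ_i²u²)^{1/4}. The
integrand is split into non-oscillatory factors times cos(xu/2) and
sin(xu/2) and integrated with QUADPACK's oscillatory (QAWF) rules, which
handle the slowly decaying, oscillatory tail with extrapolation across
cycles. Two numerical safeguards matter:

- **Scale normalization.** The weights are divided by √Σλ² (and x with
  them) before integration; the tail probability is scale invariant, but
  without this the quadrature misses the relevant frequency range entirely
  when the weights are ~1e−5 (near-degenerate kernels) and silently
  returns p ≈ 0.5.
- **Fallback.** Requested accuracy is 1e−6; if the integrator reports a
  larger error estimate or a non-finite value, a shifted-gamma
  approximation matched to the first three cumulants (κ₁ = Σλ, κ₂ = 2Σλ²,
  κ₃ = 8Σλ³, mirrored for negative skew) is used and recorded as
  `moment_fallback` in the result's diagnostics.

Verified against χ²_k survival functions (k = 1, 2, 5, 10; agreement
~1e−10) and against 10⁶-draw Monte Carlo for mixed weights (within Monte-
Carlo error). Weights below 1e−10 of the largest are truncated only inside
the integrator, never before forming the ratio weights — truncating the
spectrum first would erase the signal of near-degenerate kernels. p-values
are floored at 1e−14 to avoid reporting integrator underflow as exact zero.

## Kernels and tunable parameters

- `bandwidth_denominator` (default `None` → 2N, N = sample count): the
  exponent denominator of both Gaussian kernels. With burden scores in
  [0, 1] and n ≈ 142 this makes f ∈ [e^{−1/2N}, 1] ≈ 1 — the kernel acts
  as an affine image of negative squared distance. This is implemented as
  the default deliberately; the null construction above makes size and
  power insensitive to it, but the parameter is exposed for sensitivity
  analyses.
- `standardize_expression` (default on): expression units are arbitrary
  and the shared denominator is scale sensitive, so t is scaled to zero
  mean / unit sample variance before the kernel. A constant vector maps to
  zeros (hence an all-ones kernel), which keeps mode G bitwise identical
  to mode GT with constant expression.
- `standardize_burden` (default off): same option for the burden score,
  off by default to keep the published form of f.

## Covariates, PCs, FDR

The adjustment mechanism is OLS residualization of the phenotype on
intercept + covariates + principal components, followed by ranking of the
residuals — the simplest mechanism consistent with a rank kernel, applied
identically to binary phenotypes (linear-probability residuals).
Rank-deficient designs are an error. `genotype_pca` provides
EIGENSTRAT-style scores: dosage columns centered and scaled by √(p(1−p)),
top-k left singular vectors scaled by the singular values, sign-fixed by
the largest loading; precomputed PCs can be supplied instead (columns
named `PC*` in the phenotype CSV). Benjamini–Hochberg FDR is applied per
phenotype and per mode across all regions (the stratification is recorded
in the output metadata); a brute-force BH implementation is kept as a test
oracle.

## Regions and filters

Regions are 1-based closed intervals; the testing window is
[start − flank, end + flank] with flank 5,000 bp by default, closed on
both boundaries (the inclusiveness of the boundary is a convention fixed
and documented here; tests pin it). Flanks ignore strand. BED input
(0-based half-open) is converted at parse time; GFF3 gene features are
read via gffutils. An SNV may belong to every region covering it. Filter
order: regions with no matched probe are discarded, MAF = 0 SNVs (on the
analysis sample) are dropped, and regions left without SNVs are discarded;
a reconciliation report accounts for every input region and is checked
exactly on a handcrafted 5-gene toy (`toy_filter_study`). A region with
multiple probes yields one record per (region, probe) pair.

## Synthetic data generator

`simulate_study` emulates the study conditions the test targets: n = 142
unrelated samples; per-gene SNV counts uniform on 115..411 (the middle
half of observed gene-region sizes in whole-genome data); MAF mixture 80%
Uniform(0.001, 0.01) and 20% Uniform(0.01, 0.5), with zero-carrier columns
redrawn so every SNV is polymorphic in sample; expression
t = γ·(standardized burden) + N(0,1); phenotype
y = β_g·(standardized burden) + β_t·t + 0.05·(age−50) + 0.5·sex + N(0,1);
binary status thresholded at the empirical quantile for a 30% prevalence.
Defaults β_g = β_t = 0.15, γ = 0.5 give per-gene power ≈ 0.7–0.8 at
n = 142 — strong enough to measure power differences between modes,
realistic for a well-powered eQTL-mediated gene effect. Effects act
through the standardized burden score so that power calibrations align
with the statistic under test. The planted-gene screen demonstration uses
β_g = β_t = 0.4, γ = 0.7, calibrated so the planted gene tops a 100-gene
screen reliably.

Deliberately not modeled: linkage disequilibrium within regions, family
structure, population stratification (a separate two-subpopulation helper
exercises PCA), genotyping error, and expression batch effects. Passing
tests on this generator therefore show correctness and calibration of the
statistic under exchangeable nulls with independent variants; they do not
show robustness to LD-induced kernel structure or to confounding beyond
what OLS-on-PCs removes.

## Determinism and output

All simulation and permutation randomness flows through explicit
`numpy.random.Generator` seeds; screens are deterministic given inputs
(ordering by (chrom, bp1, gene_id, probe_id)) and invariant to input row
and sample order up to floating-point reordering. Output TSVs embed a
header comment with package version, seed, and a hash of the kernel/run
configuration.

## Known limitations

- The asymptotic null relies on a permutation CLT; for very small n
  (≲ 30) or extremely localized kernels (a single ultra-rare carrier) the
  permutation oracle should be preferred — it is one flag away
  (`test-gene --permute B`).
- Relatedness is not modeled; the test assumes exchangeable samples.
- Multiallelic VCF records are skipped, not split.
- The T mode inherits whatever normalization the expression matrix came
  with beyond the internal standardization; batch correction is upstream.
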