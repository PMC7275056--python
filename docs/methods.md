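# Methods

## Model

`mtar` tests, gene by gene, whether any of `m` rare variants is associated
with any of `K` traits, using only per-trait summary statistics. For trait
`k`, the inputs are the variant-level score vector `U_k` (from the null
generalized linear model of the trait on covariates) and its covariance
`V_k`, or equivalently effect estimates and standard errors from which
`U_k ≈ β̂/se²` and `V_k ≈ diag(V)^{1/2} R diag(V)^{1/2}` are reconstructed
with an LD correlation matrix `R`. Writing `β̂_k = V_k⁻¹U_k` and stacking
trait-major, `β̂ | β ~ N(β, Σ)` where the diagonal blocks of `Σ` are
`V_k⁻¹` and, when traits share samples, the (k,k′) block is
`ζ_kk′ V_k⁻¹ diag(V_k)^{1/2} R diag(V_k′)^{1/2} V_k′⁻¹`.

`ζ_kk′` is the covariance of null-variant Z-scores between traits k and k′
induced by sample overlap. For two quantitative traits it equals
`n_C · cor(Y_k, Y_k′) / √(n_A n_B)`; for two binary traits a count-based
analogue holds; for unknown overlap it is estimated as the sample
correlation of genome-wide Z-scores over LD-pruned (r² < 0.01 within
500 kb), common (MAF ≥ 0.01) variants with P ≥ 0.05 in every trait. `ζ` is
distinct from the genetic correlation `C`, which describes shared genetic
architecture and is a user input, never estimated here.

The genetic effects are modelled as zero-mean random effects with
covariance `σB`, `B = B₂ ⊗ B₁`. `B₁ = W₁Ω₁W₁` has exchangeable correlation
`ρ₁` among variants (ρ₁ = 0 is the SKAT limit, ρ₁ = 1 the burden limit)
and Beta(1, 25)-density MAF weights by default. `B₂ = W₂Ω₂W₂` has
off-diagonal correlation `ρ₂C_kk′` (iMTAR structure: heterogeneous at
ρ₂ = 0) or `ρ₂C_kk′ + (1 − ρ₂)` (cMTAR structure: homogeneous at ρ₂ = 0);
`W₂` holds 0/1 trait-selection indicators. For fixed `ρ = (ρ₁, ρ₂)` the
variance-component score statistic is `Q_ρ = β̂ᵀΣ⁻¹BΣ⁻¹β̂`, a mixture of
χ²₁ variables under H₀ with weights the eigenvalues of `Σ⁻¹B`.

iMTAR and cMTAR combine the nine `p(Q_ρ)` over the grid
`{0, 0.5, 1}²` with the Cauchy method (`T = mean tan{(0.5 − p)π}`,
combined `p = 0.5 − arctan(T)/π`). cctP Cauchy-combines the 2K per-trait
SKAT and burden P-values; minP is `2K · min(p)` capped at 1; MTAR-O
Cauchy-combines cMTAR, iMTAR and cctP.

## Mixture-of-χ² tail probabilities

`quadform_pvalue` inverts the characteristic function numerically
(Davies-style midpoint rule). The spacing is set from a Chernoff bound so
that aliasing images carry mass below a tenth of the accuracy target
(default 1e−9 absolute); the series is truncated where either the
integrand-envelope bound or the remainder of a two-term
integration-by-parts expansion of the tail integral falls below a quarter
of the target, and in the latter case that expansion is added as an
analytic tail correction. The correction matters for low-rank spectra
(e.g. the ρ₁ = 1 burden limit, whose kernel has rank K), where the
integrand decays as slowly as `u^{−(1+r/2)}`; it cuts the node count by
one to two orders of magnitude. Equal-weight spectra use the exact scaled
χ² survival function. When the inversion result is at or below ~50× the
accuracy target the Kuonen saddlepoint approximation is used instead
(better relative accuracy deep in the tail, typically within a few
percent); a Liu moment-matched noncentral χ² is the last resort. The
method actually used is recorded in the result and surfaced in pipeline
diagnostics. Validation: exact χ² forms, a Ruben series of central χ²
CDFs, a recursive-conditioning quadrature oracle, and Monte Carlo.

## Numerical choices

- Eigenvalues below `1e−10 × λ_max` are treated as zero; small negative
  eigenvalues from asymmetric numerics are clipped.
- P-values of exactly 1 are clamped to `1 − 1e−16` before tangents; below
  `1e−16` the tangent uses its asymptote `1/(pπ)`; combined P-values for
  very large `T` use `1/(πT)`.
- `Σ` is symmetrised and repaired by eigenvalue clipping; the ζ matrix is
  additionally rescaled to restore its unit diagonal. Singular `V_k` gets
  a ridge of `1e−8 × mean(diag V_k)` (escalated tenfold until usable),
  with a warning; ridge events are counted in diagnostics.
- Variants polymorphic in only some traits are handled by index deletion
  on the union variant set: the affected rows/columns are removed from
  that trait's block of `β̂`, `Σ` and `B`. This is a deliberate,
  documented simplification of the exact adjustment for partially
  polymorphic variants; it is exact when the traits share the variant set.
- Harmonisation matches on (chrom, pos, ref, alt); swapped alleles flip
  the sign of `U` (or `β̂`) and set `MAF := 1 − AF`; strand-ambiguous A/T
  and C/G variants are kept with a warning; variants absent from the LD
  reference are dropped with a logged count.
- The simulation study computes quadratic-form P-values at 1e−6 absolute
  accuracy — ample for the rejection rates studied — while the per-gene
  analysis path keeps the 1e−9 default.

## Synthetic data

The generator emulates the study design used to characterise the tests:
three continuous lipid-like traits in three cohorts
(N₁, N₂, N₃) = (3000, 3500, 2000) with partial trait availability
(default: cohort 1 measures all traits, cohort 2 traits {1, 2}, cohort 3
trait {3}), inducing the sample overlap handled by `ζ`. Phenotypes follow
a multi-response regression with a binary Bernoulli(0.5) covariate
(effect 0.1), a standard-normal covariate (effect 0.2), and residual
covariance `[[1, 0.1, 0], [0.1, 1, −0.1], [0, −0.1, 1]]`. Genetic effects
on causal variants (20% or 50% of the gene) are
`β_kj = s_j^snp · s_k^trait · d · |log₁₀ MAF_j|`, with the five trait
patterns (0,0,1), (0,1,1), (0,−1,1), (1,−1,1), (1,1,1), fixed or random
variant signs, and `d` a required parameter chosen so the power is
moderate at the significance level studied. The genetic-correlation input
for the worked examples is the published lipid matrix
(LDL,HDL) = 0.09, (LDL,TG) = 0.35, (HDL,TG) = −0.61.

Genotypes come from a pool of 100 haplotypes over 1 Mb whose site
frequencies follow a 1/x spectrum truncated to (0, 0.05]; each subject
sums two haplotypes drawn with replacement, a gene is a 3 kb window
(default 10 rare variants), and LD arises from finite-pool resampling.
This replaces a calibrated coalescent simulator: the pool reproduces
rare-variant allele-frequency shape and within-gene LD but not
fine-mapped human LD patterns or recombination-rate variation, so passing
tests demonstrate statistical calibration and power ordering under a
realistic-scale design, not agreement with any particular human locus.
Per-trait summary statistics are combined across cohorts by fixed-effects
meta-analysis (sum of U, sum of V) before testing.

Study sizes used by the shipped test suite and acceptance script: type-I
calibration uses 10⁵ null replicates at α = 0.01 on a 10-variant gene
(100 gene regions, phenotypes redrawn per replicate); power orderings use
2000 replicates per pattern at α = 10⁻³; the ζ-recovery check uses 10⁵
null variants with phenotypes redrawn every 500 variants so the empirical
estimator converges to the analytic target rather than to its
phenotype-conditional value.

## Calibration behaviour worth knowing

At α = 0.01 with 10⁵ null replicates of the shipped calibration study,
cctP (0.0104) and minP (0.0099) sit inside the 95% binomial band of 0.01,
while the grid-combined tests run a few percent anti-conservative (iMTAR
0.0107, MTAR-O 0.0111, cMTAR 0.0112; band upper edge 0.0106). The
direction and size of these deviations follow from the combination rule
itself: the Cauchy approximation `0.5 − arctan(T)/π` is a tail
approximation that is slightly anti-conservative at moderate significance
levels under strong positive dependence — nine grid P-values are nearly
duplicates of each other, and MTAR-O compounds two layers of the
approximation — while Bonferroni (minP) leans conservative under positive
dependence. The same pattern appears in a no-overlap design where `Σ` is
exactly block-diagonal, and single grid points in isolation are
calibrated, so it is not an artefact of the overlap covariance or of the
tail-probability machinery. At the small α relevant for genome-wide scans
(here checked at α = 10⁻³; the tests are designed for α ~ 10⁻⁶) the
approximation error shrinks and rejection rates are at or below nominal.

Similarly, the omnibus pays a robustness premium in power: across the
shipped pattern studies MTAR-O tracks within a few points of the best
test for every pattern (and is itself the best when no single structure
matches), but where one component dominates — e.g. cctP under a
single-associated-trait pattern — MTAR-O sits ~5 points below it, more
than Monte-Carlo noise at 2000 replicates. Averaging tangents over three
components dilutes a lone strong signal by construction.

## Known limitations

- Binary-trait score statistics use the standard logistic information;
  no small-sample or unbalanced case-control correction is applied.
- Mixed quantitative/binary pairs have no analytic ζ; use the empirical
  estimator.
- Related subjects (mixed-model scores), imputation-quality filtering and
  multi-allelic decomposition are out of scope.
- The empirical ζ estimator assumes enough (≥ 1000 by default) null
  variants survive filtering.
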