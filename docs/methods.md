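# Methods

## Generative model for summary statistics

Genotypes are standardized to unit variance, so per-SNP effects β live on
the standardized scale and a trait's SNP heritability is h² = Σⱼ βⱼ². Given
an LD correlation matrix R and sample size N, simulated z-scores follow the
standard summary-statistics model

    z = √N · R β + η,   η ~ N(0, (1 + N·a)·R),

where `a ≥ 0` injects confounding so that the LDSC intercept target is
1 + N·a, and the noise of different traits is correlated at each SNP with
coefficient r₀ (sample overlap). Effects for a trait pair come from the
four-component mixture π₀/π₁/π₂/π₁₂ with per-causal variances σ₁², σ₂² and
shared-component correlation ρ₁₂. More than two traits are composed from
declared pairwise mixtures on disjoint SNP pools plus optional trait-
specific backgrounds; a full 2^T-component model is out of scope.

LD ground truth is block-equicorrelated: consecutive blocks of L SNPs share
a within-block correlation ρ drawn per block (uniform range or a discrete
set). This gives exact LD scores ℓ = 1 + (L−1)ρ², exact per-SNP r²
histograms, and block-factorizable noise, while producing the ℓ-variation
the regressions need. Everything is reproducible from a single integer
seed; dosage panels read from disk go through the same `LdInfo` container
(windowed Pearson correlations, mean imputation of missing dosages,
optional finite-sample r² bias correction r² − (1−r²)/(n−2) floored at 0).

What the generator does *not* emulate: allele-frequency-dependent effect
sizes (no MAF structure — effects are standardized-scale), liability-scale
case/control traits (observed scale only, outputs labelled accordingly),
long-range LD beyond a block, imputation error, and INDELs. Tests passing
on this generator show the estimators are correct *under their own model
assumptions*; they do not certify behaviour under real-data pathologies
(stratification beyond the intercept model, MAF-LD correlation, etc.).

## LD score regression

Univariate fit: two-step weighted least squares of z² on ℓ. Step 1 uses
weights 1/max(ℓ,1); step 2 re-weights by 1/[max(ℓ,1)·(pred)²] with pred the
step-1 fitted mean floored at 0.1 (two steps, not full iteration, for
determinism). h² is the slope coefficient of N·ℓ/M; the intercept is free.
A chi-square cap is available (`max_chisq`) but off by default at desk
scale. Uncertainty is a delete-one jackknife over contiguous equal-count
SNP blocks (default 200), computed from per-block normal-equation pieces so
leave-one-out solves are exact and O(blocks).

Bivariate fit: z₁z₂ regressed on √(N₁N₂)·ℓ/M with cross-regression weights
1/[max(ℓ,1)·(s₁s₂ + c²)], where s₁, s₂, c are the *step-1* fitted means of
the two univariate and the cross regressions. Using step-1 predictions
makes a trait paired with itself reduce exactly to the univariate
regression, so self-r_g = 1 to machine precision. r_g = ρ̂_g/√(ĥ²₁ĥ²₂) with
the full ratio re-estimated in every jackknife resample; non-positive
heritability raises an estimation error rather than propagating NaN. The
r_g p-value is two-sided normal on r_g/se.

Stratified fit: z² regressed jointly on {N·ℓ(j,c)} with a free intercept,
ℓ(j,c) = Σ_k r²_jk·a_kc. A baseline all-SNPs category is appended unless
the constant vector already lies in the annotation column space (appending
it to an exact partition would make the design singular). Conditioning is
checked on the correlation-scaled normal equations; genuinely collinear
categories trigger a small ridge (1e-8 on the normalized diagonal) with a
warning. Enrichment_c = (h²_c/h²)/(M_c/M) with h²_c = Σⱼ a_jc·(Σ_c' τ_c'
a_jc'); its SE comes from pushing each jackknife τ-vector through the same
functional. Coefficient p-values are one-sided upper on τ/se(τ).

## Bivariate causal mixture

The characteristic function of (z₁ⱼ, z₂ⱼ) factorizes over LD neighbours.
With neighbour r² values binned (20 equal bins on [0,1]; the self term
r² = 1 is kept separate and exact),

    log cf(t₁,t₂) = Σ_b n_b·log[π₀ + π₁g₁ + π₂g₂ + π₁₂g₁₂](r²_b) + noise,

where g₁ = exp(−N₁σ₁²r²t₁²/2), g₂ likewise in t₂, g₁₂ carries the
2ρ₁₂√(N₁N₂σ₁²σ₂²)r²t₁t₂ cross term, and the noise term is the Gaussian cf
with variances σ₀² per trait and correlation ρ₀. Densities come from
discrete Fourier inversion on a 256-point grid spanning ±max(15, 1.1·max|z|)
per axis; all Gaussian exponents are assembled in log space and clipped at
0, so the cf never overflows. Inversion ripple is clipped at zero with the
clipped mass reported; an edge-mass estimate above 1e-3 raises a grid
error advising expansion. The likelihood interpolates the per-histogram-
group density at the observed z (bilinear).

**Composite likelihood on pruned SNPs.** The per-SNP likelihood treats
SNPs as independent, which inside an LD block they are not; summing over
all SNPs inflates likelihood-ratio differences by roughly the block size
and produces spurious overlap evidence. The likelihood is therefore
evaluated on one randomly chosen SNP per LD block (block draws *are*
independent), the same device the field's mixture tools use via random
pruning. Each selected SNP keeps its full neighbour histogram, so no LD
information is discarded from the model — only redundant data points.

**Sequential fit.** Univariate margins (π_u, σ_u², σ₀²) are maximized by
Nelder–Mead on (logit, log, log) coordinates from a documented 3-point
multistart (π_u ∈ {1e-4, 1e-3, 1e-2}, implied h² 0.2, σ₀² = 1.05); σ₀² is
parameterized as 1 + exp(·), keeping it ≥ 1. The bivariate stage then
optimizes only (π₁₂, ρ₁₂, ρ₀) with π₁₂ ∈ [0, min(π_u1, π_u2)] via a
sigmoid transform and the margins pinned (π₁ = π_u1 − π₁₂ etc.). Because
(π₁₂, ρ₁₂) are unidentified at the π₁₂ = 0 boundary, the fitted overlap
model must beat the no-overlap model by 2 log-likelihood units (an AIC
margin for 2 extra parameters) or the fit is snapped to the boundary and
flagged — this also resolves optimizer stalls on the flat ridge near zero.
Standard errors are a parametric bootstrap of the bivariate stage (default
20 refits on data re-simulated from the fitted model with the margins held
at their fitted values, matching the sequential design); the boundary
breaks Hessian normality, so no curvature-based SEs are offered.

**Polygenicity (n90).** Causal squared effects are σ²·χ²₁. The number of
effective variants explaining 90% of heritability is π_c·M·P(X > t) with t
solved from E[X·1(X>t)]/E[X] = 0.9 (the partial expectation of χ²₁ equals
the χ²₃ upper tail, found by root-bracketing); the result is scale-free in
σ² and evaluates to ≈ 0.4446·π_c·M. A degenerate equal-effects option
returns 0.9·π_c·M. Venn tables report n90 of each margin and of π₁₂ (the
headline), plus the raw π₁₂·M count.

**Conditional Q-Q.** For thresholds τ ∈ {1, 0.1, 0.01, 0.001} on the
conditioning trait, sorted −log₁₀ p of the primary trait against uniform
expected quantiles; the scalar enrichment shift is the median −log₁₀ p
difference between the strictest nonempty stratum and the full set.

## Adaptive gene tests

The SPUs statistic is read as the γ₁-norm of absolute z-scores (the printed
power-sum form is ill-defined for odd γ on signed z); a signed power-sum
compatibility mode (Σ z^γ, no root) is available via a flag. γ = ∞ (max
statistic) is supported but off by default since the working grid is
Γ = {1, 2, 4, 8} for both SNP and trait powers.

The null bank draws Z_b = V^{1/2} X L_Rᵀ with X standard normal — matrix
normal with vectorized covariance kron(V, R). R is the panel correlation of
the gene's SNPs and V the genome-wide trait correlation, both eigenvalue-
floored at 1e-8; V uses its symmetric square root so the null law is
equivariant under trait relabelling. One bank serves the whole grid: per
cell, p_obs = (1 + #{T_b ≥ T_obs})/(B+1), and each draw's own minimum-p over
cells is ranked against the observation's to give the adaptive p — all
p-values live in [1/(B+1), 1] by construction. The bank is streamed in
chunks to bound memory.

V is estimated as the Pearson correlation of trait z-scores over LD-pruned
SNPs with max |z| < 2 across traits (signal exclusion). Truncating the
margins at ±c attenuates a null correlation by the truncated-normal
variance factor 1 − 2cφ(c)/(2Φ(c)−1) ≈ 0.774 at c = 2 (first order), so
the raw estimate is divided by that factor before PSD flooring.

The staged schedule (default 10³, 10⁴, 10⁵, 10⁶) re-runs a gene at the
next B whenever the multi-trait p or any per-trait p falls below 5/B, so
only promising genes pay for fine resolution; the same schedule serves
aSPUs and MTaSPUsSet. Per-gene seeds are the master seed plus a CRC32 hash
of the gene id, making the scan independent of gene order. Genes wider
than 500 SNPs are truncated with an audit entry (pruning to r² < 0.1
upstream makes this rarely bind).

Gene-level significance is α/G with G the number of genes actually tested
(the analysis drivers print the rounded threshold via the significant-
figures convention, e.g. 0.05/9886 → 5.06×10⁻⁶ at 3 figures). The
pleiotropic flag requires the multi-trait test *and* at least one
single-trait test to pass; the novel flag additionally requires absence
from the user-supplied known-association lookup.

## Reporting

Bonferroni thresholds are rounded to significant figures (not decimals).
Gene-set over-representation uses the upper hypergeometric tail
P(X ≥ k) with the query required to be a subset of the background and each
set intersected with the background first; Benjamini–Hochberg is the
default adjustment (bonferroni available). Overlap counts are rendered on
the K scale with two decimals ("0.21K"). All table emitters are
deterministic byte-for-byte given identical inputs.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive; BED input is converted at read time.
- Palindromic (A/T, C/G) SNPs are dropped during harmonization rather than
  frequency-resolved (frequency columns are not assumed); non-palindromic
  strand flips are complement-matched; irreconcilable alleles drop the SNP.
- Pruning windows and steps are counted in SNPs; on a violating pair the
  later-position SNP is dropped (deterministic tie-break).
- Monomorphic panel SNPs are rejected at construction; missing dosages are
  mean-imputed per SNP.
- WLS weight floors (ℓ at 1, fitted means at 0.1) prevent sign flips and
  division blow-ups in the weight updates.
- Monte-Carlo p-values always carry the +1 numerator correction, so they
  are valid (never zero) at any B.
- Problem sizes in the test-suite and acceptance runs (M = 30–50k SNPs,
  N = 20–50k samples, 5–50 replicates, B up to 10⁵–10⁶ only where a floor
  must be resolved) are chosen so each check has the statistical power its
  tolerance needs while the full suite stays a few minutes on one CPU.

## Known limitations

- Observed-scale heritability only; no liability transformation for
  case/control traits.
- The free cross-intercept is the only sample-overlap correction in the
  bivariate LDSC fit.
- Mixture SEs condition on the fitted univariate margins; marginal
  uncertainty is not propagated into the bivariate bootstrap.
- The adaptive-test bank is shared across grid cells (the standard
  efficiency trick); p-values are valid but cells are positively
  correlated, so the adaptive p typically runs 1.5–4× the best cell's p at
  a 16-cell grid rather than tight to it.
- Exact seed-level invariance of the multi-trait p under trait relabelling
  is impossible with one shared Gaussian bank; the invariance holds in law
  and is tested at Monte-Carlo accuracy.
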