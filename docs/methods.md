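# Methods

`rge` simulates and detects gene–environment correlation (rGE) across
families and geographic regions, and quantifies how controlling for regions
changes polygenic-score decompositions, SNP heritability and genetic
correlations. This note records the models, the generative assumptions, the
numerical choices, and the limits of what the synthetic experiments show.

## The generative model

A study is parameterized by `SimConfig`. All phenotypes are built to have
total variance ≈ 1, so variance-fraction parameters are directly
interpretable.

**Genotypes.** M SNPs in LD blocks of size B. Within a block all SNPs share
one allele frequency drawn from `maf_range`, and haplotypes follow a copying
model: per haplotype and block a template allele A ~ Bern(p) is drawn, and
each SNP copies A with probability √r or draws fresh, giving pairwise allele
correlation exactly r inside the block and 0 across blocks. `ld_block_r` is
either one r for all blocks (then the LD score l_j = 1 + (B−1)r² is a known
constant, the closed form in `true_ld_scores`) or a (lo, hi) pair from which
a per-block r is drawn uniformly, producing the varying LD scores LD score
regression needs. Parents are in Hardy–Weinberg equilibrium; children receive
one parental haplotype per block per parent (no recombination within blocks),
which preserves LD and yields the expected sibling genotype correlation of
0.5. Causal effects are i.i.d. normal, scaled so the genetic value has
variance `h2_direct` in expectation.

**Polygenic scores.** The observed score uses weights equal to the true
effects plus independent Gaussian noise with total score variance
`pgs_noise`, a stand-in for out-of-sample GWAS weight error with closed-form
attenuation: corr(PRS, Y)² = h2²/(h2 + pgs_noise) when Y is purely genetic
plus noise.

**Regions.** K regions on a near-square grid with rook adjacency. Regional
SES mixes a smooth spatial gradient (weight 0.6 by default) with white noise
and is standardized exactly (mean 0, variance 1, ddof 0); the gradient makes
regional SES spatially autocorrelated, as in real geography, which is what
the Moran's I diagnostic is for.

**Sorting (the rGE channels).** Couples are ranked by a standardized latent
`w_passive · z(midparent genetic value) + noise` and mapped monotonically
into K equally sized regions ordered by SES — the passive channel. Adults are
re-ranked by `a · z(midparent) + w_active · z(own score − family mean) +
noise` and mapped the same way into current regions — the active (migration)
channel. The persistence coefficient `a` defaults to `w_passive` (birth
sorting persists at the passive strength) and can be overridden. Equal-size
rank binning is the simplest monotone mechanism with tunable strengths; its
one side effect is noted under Limitations.

**Phenotypes.** Y = genetic value + `delta_nurture` · z(midparent) +
region_load · SES(current region) + family environment + residual, with the
residual scaled so Var(Y) ≈ 1, plus small fixed sex (0.10) and age (0.05)
effects. The trait menu spans the qualitative classes of interest: an
SES-like trait (full rGE: nurture, region load 0.45, shared effects), an
adiposity-like trait (negative genetic overlap with the SES score,
negative region load), and a blood-cell-like trait (no rGE). Defaults
(h2 = 0.3, w_passive = w_active = 0.5, var_region = 0.2, var_family = 0.2,
pgs_noise = 0.3, K = 100, M = 1000) are chosen for detectability at desk
scale, not demographic realism.

## Sibling decomposition (models 1–5)

Five random-intercept models split the PRS–phenotype association into
within-family, between-family and between-region parts; m_j and m_k are
family and region mean scores, w = PRS − m_j the within-family deviation:

1. Y = α₀ + β·PRS + γ_j + ε
2. Y = α₀ + β_W(PRS − m_j) + β_B·m_j + γ_j + ε
3. Y = α₀ + β_W(PRS − m_k) + β_B·m_k + γ_j + γ_k + ε
4. Y = α₀ + β_W(PRS − m_j − m_k) + β_BF(m_j − m_k) + β_BR·m_k + γ_j + γ_k + ε
5. Y = α₀ + β_W(w − w̄_k) + β_B·w̄_k + γ_j + γ_k + ε

Sex and age are fixed covariates in every model. Model 4's within column
subtracts both means, so the three PRS columns obey c1 + c2 + 2·c3 = PRS
exactly — not a textbook three-level centering; it is kept as specified and
the identity is what the tests assert. Region membership uses the current
address by default (birth region behind a flag). Pairs missing a phenotype
are dropped for that trait.

**Fitting.** Family and region intercepts are crossed (siblings can live in
different regions). The fitter profiles the REML criterion over the variance
ratios λ_f = σ²_f/σ²_ε, λ_r = σ²_r/σ²_ε on the log scale with Nelder–Mead
(xatol = fatol = 1e-8), solving each evaluation through the normal-equation
matrix M = ZᵀZ + diag(1/λ) with a Schur complement on the (small) region
block — O(n + q_f·K + K³) per evaluation. Fixed-effect covariance is the GLS
expected-information form σ²_ε(XᵀV⁻¹X)⁻¹. A ratio at the boundary
(λ < 1e-7) is reported as a zero component and the fit flagged singular.
The fitter reproduces R lme4's REML estimates, SEs and variance components
to ≥4 decimals on a shared fixture (tested via Rscript), and collapses to
OLS when the true components are zero. P-values are one-sided in the
direction of the estimate by default (two-sided behind a flag). Marginal and
conditional R² follow var(Xβ̂)/(var(Xβ̂)+σ²_f+σ²_r+σ²_ε), with the random
variances added to the numerator for the conditional version.

An independent oracle, the sib-difference regression ΔY ~ ΔPRS + Δsex + Δage
without intercept, estimates the same within-family slope as model 2 in
balanced pairs and is used as a cross-check, never as the implementation.

## Bootstrap contrast (models 2 vs 4)

Sampling units are sibling pairs; each replicate resamples F families with
replacement (each copy treated as a distinct family), recomputes all family
and region means, re-estimates both models, and records the difference in
β_W. The SE is the SD of those differences; (Δ/SE)² is referred to χ²(1).
By default the REML variance ratios stay at their full-sample estimates and
only the GLS fixed effects are re-solved per replicate; the point estimates
are identical to the REML fits, the ratio re-estimation contributes only
second-order noise to a fixed-effect contrast, and the fast path is ~50×
cheaper (`refit_variance=True` restores full re-profiling). Replicates whose
fit fails are skipped and counted; >10% failures flags the result.
Individual-level resampling exists behind a flag for sensitivity, not as the
default — it breaks the within-family contrast.

**Calibration and a degenerate corner.** With region environments present
but genetically uncorrelated (the relevant null), the χ²(1) test rejects at
5.2% over 250 replicates (400 pairs, 500 bootstraps each). If there are *no*
region effects of any kind, β_W2 − β_W4 becomes a second-order degenerate
statistic (its SD scales as 1/n rather than 1/√n) and the pairs bootstrap
overestimates its SD by a roughly constant factor ≈1.8 — the classic
degenerate-statistic bootstrap failure, reproducible with plain OLS. The
test is then conservative (near-zero rejections), never anticonservative.

## Region-controlled association scans

Scans regress the phenotype on each SNP with sex, age, genotype PCs and
dummy variables for all but one region (birthplace, current address, or
both; reference level = largest region; regions under `min_region_n`
drop their individuals, default 100). The covariate block is absorbed once
via QR projection (Frisch–Waugh–Lovell) and each SNP is regressed on the
residualized phenotype with the joint-model residual df, which equals full
joint OLS to 1e-8 (tested). PCs come from an exact SVD of the standardized
dosage matrix with a deterministic sign convention (largest-magnitude
loading positive), unit-variance scores; the synthetic default is 10 PCs
since simulated structure is low-dimensional. The cohort generator emits
unrelated individuals (one offspring per simulated family), so OLS is
correctly specified and no sparse-GRM random effect is fitted. An
ill-conditioned covariate block (condition number > 1e8, e.g.
latitude/longitude alongside correlated PCs) raises a warning rather than
being "fixed". Moran's I uses the standard (n/S0)·zᵀWz/zᵀz form with a
permutation test by default (normal approximation with randomization
moments behind a flag).

## LD score regression and change tests

Empirical LD scores sum bias-corrected r² (r² − (1−r²)/(N−2), self term
included) over each LD block of a reference panel. h² is the slope of the
weighted regression of χ² on l_j times M/N with a free intercept; weights
are 1/max(l,1) with one update from the provisional fit,
w = 1/(max(l,1)·Ê[χ²]²) — full iterative weighting is deliberately not
re-derived. Genetic covariance regresses z₁z₂ on l_j (slope·M/√(N₁N₂));
r_g = gencov/√(h²₁h²₂), undefined (flagged) if either h² ≤ 0, clipped to
±1.25 for display only. Standard errors are delete-one-block jackknives over
min(200, M/10) contiguous SNP blocks; the r_g jackknife recomputes all three
regressions per deleted block so the delete-one values honor the dependence
between numerator and denominators.

**Change tests.** Scans with and without region dummies share the sample, so
their h²/r_g estimates are strongly dependent. `delta_test` requires the two
fits to share SNPs and blocks, differences the delete-one estimates
block-by-block, and uses the jackknife SE of those differences for a Z test
— a desk-scale stand-in for Genomic SEM's dependence-aware difference SE.
BH-FDR is applied across traits.

**Heritability scale convention.** A scan on a region-residualized trait
measures h² against the reduced residual variance, which mechanically
*inflates* corrected h² even when regions carry no genetic signal. The
pipeline therefore rescales each condition's h² (point estimate, SE and
delete-one values) by var(y | condition covariates)/var(y | base
covariates), so every condition's h² refers to the same total phenotypic
variance. r_g is invariant to this rescaling. Under the no-rGE null this
makes the h² change test well calibrated (null z SD ≈ 1.0 empirically); with
rGE on, the decrease signature is preserved.

## Pipeline

`run_all` simulates one region layout and SNP-effect set shared by two
cohorts — sibling pairs for the decomposition track, unrelated individuals
for the GWAS track — runs both tracks, and writes tab-delimited reports plus
a JSON run log (seed, config hash, package versions). Every number in the
reports is recomputed from the stage outputs; a fixed seed reproduces every
file bit-for-bit. A full default synthetic run completes in well under 15
minutes on one CPU.

## Problem sizes used in the tests

Chosen so the whole suite runs in a few minutes on one CPU: sibling-PRS and
sorting checks at 20,000 pairs with M = 1,000; estimator/oracle agreement at
10,000 pairs; bootstrap type-I calibration at 250 null replicates × 500
bootstraps with 400 pairs and K = 9; LDSC h²/r_g recovery at N = 10,000,
M = 2,000; variance-component recovery at 10,000 pairs; qualitative
signature runs at 4,000–5,000 families, M = 1,000, K = 100 with three seeds
per signature. The jackknife-vs-empirical-SD check uses 12 replicates, so it
is asserted loosely (±50%).

## Known limitations

- The equal-size rank binning gives regions deterministic populations; real
  region sizes vary. Together with the no-region-effect corner this is where
  the bootstrap's degenerate-statistic conservatism shows.
- Block jackknives (and equally Genomic SEM's jackknifed sampling
  covariances) only see genome-replication noise. A change in r_g driven by
  realized person-level environment shared across all SNP blocks is
  invisible to them; empirically the r_g change test is conservative on
  average (null z SD ≈ 0.45) with occasional under-coverage. The h² change
  test does not show this (null z SD ≈ 1.0).
- The r_g point estimate is noisy whenever the denominator h² estimates are
  small; flags rather than truncation are used.
- No assortative mating, no realistic demography or recombination maps, two
  siblings per family, autosomes only, Gaussian phenotypes only. Passing
  synthetic tests shows the estimators and tests behave as designed under
  this generative model, not that real data meet its assumptions.
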