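# Methods

## Model

Each SNP j in an LD-pruned panel contributes an estimated log-odds ratio
`y_j` of its derived allele (natural-log scale) and an empirical sampling
variance `v_j` (the squared standard error). The model is a two-group
mixture: with probability 1 − π the SNP is null and `y_j ~ N(0, v_j)`; with
probability π it is associated and `y_j | β_j ~ N(β_j, v_j)` with
`β_j ~ g`. The mixing distribution g is left unspecified and represented by
probability masses `p = (p_1, …, p_B)` on a fixed grid of nonzero points.
SNPs are treated as independent, which is an approximation justified by LD
pruning at r² > 0.1; fitting unpruned panels is possible but relaxes that
assumption (the stratified-fit path warns about it).

Assumptions worth keeping in mind: the within-SNP asymptotic normality of
`y_j` (adequate for the large case-control studies this is meant for, less
so for very rare variants or tiny studies); a shared g across all SNPs of a
panel (stratified fits relax this by splitting the panel); and effects
expressed as *marginal* log-odds ratios of the pruned SNPs, not of
underlying causal variants.

## Estimation

(π, p) maximise the marginal likelihood via EM. The E-step computes each
SNP's posterior component probabilities `r0_j` (null) and `r_jb` (grid
point b); the M-step sets `π ← mean_j (1 − r0_j)` and
`p_b ← Σ_j r_jb / Σ_j (1 − r0_j)`. The schedule has three stages:

1. **Candidate sweep.** From a uniform g, run 200 full EM iterations for
   each starting value π₀ ∈ {0.1, …, 0.9} and keep the run with the highest
   final log-likelihood; its final π is `π_init`. Ties go to the smaller
   candidate (conservative about polygenicity).
2. **Mass warm-up.** Reset g to uniform, freeze π = `π_init`, and iterate
   mass updates until the relative log-likelihood change per iteration is
   below 5·10⁻⁵ (0.005%) or 200 iterations. The monitored scalar here is
   the likelihood because π is frozen and cannot move; the stage can be set
   to cap-only with `stage2_rel_tol=None`.
3. **Final EM.** From (`π_init`, `g_init`), update both until the relative
   change of π per iteration is below 0.005% or 2000 iterations.

No smoothing penalty is applied to g: the iteration caps are the smoothing
mechanism (early-stopped nonparametric EM of the smoothing-and-roughening
type — more iterations give rougher estimates). π is clipped to
[10⁻¹², 1 − 10⁻¹²] so relative-change stopping stays defined. The whole
procedure is deterministic: identical data and configuration give
bit-identical results.

### Numerics

The m×B matrix of kernel densities `N(y_j; b, v_j)` is precomputed once per
dataset in log space and row-rescaled by its maximum component, because with
`v_j ~ 10⁻⁴` tail densities underflow double precision; mixture sums are
formed on the rescaled values with a log-sum-exp fallback for any row whose
rescaled mixture still vanishes. Cached and direct density evaluation agree
to rounding error (tested). One EM iteration then reduces to two
matrix-vector products, so a full fit of m = 20,000 SNPs on the 120-point
grid takes seconds on one CPU.

Degenerate inputs: if the E-step leaves no non-null mass at all, the M-step
sets π = 0 and leaves the masses unchanged, with a warning rather than an
exception. Rows with missing or non-positive variance are rejected at load
time, not imputed. Fits on fewer than ~100 SNPs warn.

## Uncertainty

Standard errors for π̂ (and V̂) use a parametric bootstrap: each replicate
redraws every SNP from the fitted model (non-null with probability π̂,
effect from ĝ, observation `N(β, v_j)` with the observed `v_j`) and refits
with the complete three-stage schedule, so replicate spread includes
initialisation effects; warm starts would understate it. Replicate RNG
streams are spawned from the master seed, making results independent of
execution order. The reported SE is the sample SD of the replicates
(default 100). V̂ replicates reuse the observed frequencies and prevalence;
their uncertainty is not resampled.

## Posterior summaries

With (π̂, ĝ) as prior, each SNP gets `p_nonnull = 1 − r0` and the posterior
mean effect `Σ_b b·r_b` (the null component contributes zero). Because the
prior is estimated from the whole panel, posterior means are shrunken and
serve as winner's-curse-adjusted effect estimates; ranking uses a threshold
on |posterior mean| (default 0.05), with ties broken by SNP id for
determinism.

## Liability-scale variance

A SNP's effect β, derived allele frequency p and disease prevalence K map
to liability-scale explained variance under the threshold model. Genotype
penetrances follow the additive dosage logistic model
`φ_x = expit(α + βx)`; α solves the prevalence constraint
`Σ_x h_x φ_x = K` over Hardy–Weinberg genotype frequencies (safeguarded
vectorised Newton with a bracketing fallback; tolerance 10⁻¹³ on α,
verified below 10⁻¹⁰ on the prevalence residual). Genotype liability means
are recovered from penetrances through the normal threshold; the location
anchor is arbitrary and chosen as T = Φ⁻¹(1 − K), which the variance is
invariant to (tested against an oracle anchored elsewhere). The
between-genotype variance v\* is rescaled to the unit-total-variance
liability scale as `v = v*/(1 + v*)`. Per SNP,
`v̂_j = π̂ · Σ_b p̂_b · v(b, p_j, K)`, and V̂ is the sum over SNPs with
usable frequencies (others are skipped and counted). The helper that
divides (V̂ + excluded-region share) by family heritability is plain
reporting arithmetic.

## Synthetic data

The generator emulates a balanced case-control GWAS: DAFs uniform on
(0.05, 0.95) (a common-variant chip panel; configurable), a fraction
`pi_true` of SNPs non-null with effects from a chosen distribution (default
N(0, 0.03²)), and case-control sampling noise at given n. Two mechanisms:

* **asymptotic** (default): `y ~ N(β, v)` with the 2×2 allele-count Wald
  variance `v = 1/(2 n_case p̃q̃) + 1/(2 n_control pq)`, where the
  case-side frequency `p̃ = p·e^β / (1 − p + p·e^β)` is the logistic shift
  of the population frequency;
* **genotype**: explicit binomial allele counts in cases (frequency p̃) and
  controls (frequency p), Wald log-OR with `1/a + 1/b + 1/c + 1/d` variance
  and a Haldane–Anscombe 0.5 correction on empty cells. This serves as the
  ground-truth check of the asymptotic shortcut; the two agree in
  distribution at GWAS-scale n (tested by Kolmogorov–Smirnov).

Prevalence never enters the generator — case-control sampling conditions on
status — and the generator produces no LD, no selection-driven DAF
structure, no population stratification and no allele-frequency-dependent
effect sizes. Passing tests therefore demonstrate correct behaviour under
the model's own assumptions on independent common SNPs, not robustness to
those real-data features.

## Problem sizes used in the test suite

The validation experiment is run at m = 20,000 SNPs and 10 replicates
(n = 100,000 cases/controls), where the mean fitted π lands within ±0.02 of
the simulated 0.1; bootstrap comparisons use panels of 1,000–9,000 SNPs
with 6–12 replicates, sizes at which the factor-of-two agreement with a
fresh-data Monte Carlo check is already stable. The EM-optimality check
uses two-point grids so the (π, p₁) surface can be searched exhaustively.

## Limitations

* π and g describe marginal effects of near-independent pruned SNPs; they
  are conservative about the number and effects of causal variants in LD.
* The grid bounds (±0.3) must cover the true effect range; effects beyond
  ±0.3 would pile mass at the boundary.
* The stage-2 stopping rule monitors the likelihood (π is frozen there); an
  iteration-cap-only variant is available.
* V̂ SEs hold frequencies and prevalence fixed.
* Choosing the prevalence K is up to the user (typically from prior
  literature); estimates of V scale with that choice.
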