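# Methods

This note documents the statistical models behind `weevilstats`, the
assumptions they make, the defaults they ship with, and the places where a
design choice was genuinely open.

## Setting

A randomised-block biocontrol trial against the large pine weevil
(*Hylobius abietis*): freshly cut conifer stumps receive one of four
treatments — untreated control, full-dose entomopathogenic fungus (EPF),
full-dose entomopathogenic nematode (EPN), or half doses of both combined
("HalfMix") — replicated across blocks. Efficacy is measured two ways:
destructive sampling (bark removal, scoring each weevil's developmental
stage and infection outcome in situ) and emergence trapping (per-stump
season totals of emerging adults). Traps also collect non-target
invertebrates, giving trap × taxon community matrices for a safety
analysis.

## Contingency analysis (`weevilstats.contingency`)

Record-level destructive data are cross-tabulated (treatment × infection
outcome; developmental stage × infection outcome) and tested for
independence with the classical Pearson chi-square statistic
χ² = Σ (O−E)²/E, E_ij = row_i·col_j/n, with no continuity correction.
Per-cell departures are reported as standardized residuals
Z_ij = (O_ij − E_ij)/√E_ij, flagged against ±1.96; this Pearson form is the
default because its squares sum exactly to χ² (the margin-adjusted variant
(O−E)/√(E(1−r/n)(1−c/n)) is available via `residual_type="adjusted"`).
Effect size is Cramér's V = √(χ²/(n·min(r−1, c−1))).

Zero-margin levels raise an error rather than being dropped silently:
discarding a category changes the degrees of freedom and must be the
caller's explicit decision.

## Bliss independence synergy (`weevilstats.bliss`)

Two agents act independently when survival probabilities multiply, so the
expected combined infection rate is

  I_Bliss = I_EPF + I_EPN − I_EPF·I_EPN.

The observed combined-arm rate I_NF is compared with the expectation
through the deviation statistic χ²_Bliss = (I_NF − I_Bliss)²/I_Bliss,
referred to a 1-df chi-square distribution, and the synergy score
S = I_NF − I_Bliss is classified Synergy/Additive/Antagonist by sign
(strict sign by default; a tolerance band is available).

Two conventions needed fixing because the trial has no half-dose
single-agent arms:

* **Half-dose rates.** The default derives I_EPF and I_EPN by halving the
  full-dose arm rates (linear low-dose scaling); using the full-dose rates
  unchanged is available via `half_dose_convention="full"`.
* **Mortality definition.** The default numerator counts every non-alive
  outcome, including indeterminate deaths (`any_death`); `agent_specific`
  restricts to the arm's own kill category for sensitivity analysis.

A caution worth stating plainly: χ²_Bliss carries no sample-size scaling,
so it is a *descriptive* deviation measure, not a calibrated test. Under a
true independence null its p-values concentrate near 1 rather than being
uniform (our null simulations at 60 weevils per arm give mean p ≈ 0.93 and
essentially no rejections at the 0.05 level). It can only lose power, never
inflate false synergy claims, but its p-values should not be read as
ordinary test p-values.

When run per block, rates are estimated within each block; blocks missing
any of the three required arms are skipped with an explicit warning, and
the pooled observed rate equals the count-weighted mean of the block rates.

## Emergence model (`weevilstats.emergence`)

Per-stump counts are modelled as NB2 negative binomial with log link:
E[y] = μ, Var[y] = μ + μ²/θ, log μ = β₀ + block effect + treatment effect,
treatment coded against the control. Two block treatments are offered:

* `block_mode="fixed"` (default): block indicator coefficients, exact
  maximum likelihood via full-likelihood optimisation, fully deterministic.
* `block_mode="random"`: Gaussian random intercept b ~ N(0, σ²), integrated
  out block-by-block with a Laplace approximation (scalar Newton inner
  optimisation per block, quasi-Newton outer optimisation over β, log θ,
  log σ). This mirrors the GLMM formulation standard for such trials.

The treatment effect is tested by the likelihood-ratio statistic
2(ℓ_full − ℓ_null) on 3 df against fits of the same block mode. A known
limitation, quantified in our simulations: with fixed block indicators the
LRT is anti-conservative at trial scale (null rejection ≈ 0.12 at 20
blocks and 4 arms, because 19 incidental parameters are estimated from 80
observations), while the random-intercept mode is calibrated (≈ 0.05).
Fixed mode remains the default for determinism and exactness of the
likelihood; calibration-sensitive inference should use random mode, and
the test suite checks the type-I error in that mode.

Estimated marginal means are response-scale predictions per treatment —
averaged over the observed block coefficients in fixed mode, evaluated at
b = 0 in random mode (the median block; a note is warranted because the
mean of a log-normal block distribution sits above its median) — with
delta-method standard errors.

Dunnett many-to-one contrasts report the relative emergence ratio
exp(β_t) per treatment. Adjusted p-values are computed by Monte-Carlo
integration: the probability that max_j |Z_j| of a zero-mean multivariate
normal with the contrasts' estimated correlation matrix exceeds the
observed |z| (default 100,000 draws, fixed seed). This is dimension-
agnostic and testable against the closed-form Šidák limit when the
correlation is the identity; the estimate is floored at the unadjusted p
so Monte-Carlo noise can never make adjustment anti-conservative.

## Community analysis (`weevilstats.community`)

Distances: Sørensen (default; Bray–Curtis on presence/absence), Bray–Curtis
on counts, or Euclidean. Sørensen matches the documented default of the
multivariate software ecologists typically use for MRPP. A pair of all-zero
traps has undefined Bray–Curtis/Sørensen distance and is set to 0 with a
warning.

PCoA follows the classical Gower construction: double-centre −½D² about
row/column means, eigendecompose, scale eigenvectors by √λ for positive
eigenvalues. Negative eigenvalues (possible for semi-metric distances) are
reported and their axes dropped; no Cailliez/Lingoes correction is applied
by default. Proportions explained are relative to the positive-eigenvalue
total.

MRPP compares the observed weighted mean within-group distance
δ_obs = Σ_g C_g · mean(within-group distances), C_g = n_g/N by default
((n_g−1)/(N−k) behind a flag), with a permutation null that relabels traps
preserving group sizes (default 9,999 permutations, seeded). The
chance-corrected within-group agreement is A = 1 − δ_obs/δ_exp and the
p-value uses the add-one estimator (1 + #{δ_perm ≤ δ_obs})/(1 + B), which
is never zero. Under random grouping A is centred on 0; A = 1 iff all
within-group distances vanish.

Univariate comparisons (total abundance, taxon richness) use classical
one-way ANOVA.

## Synthetic data (`weevilstats.simulate`)

The raw field records are unpublished, so the generator emulates their
statistical shell; the defaults are the published summary tables, not free
dials:

* per-treatment infection-outcome probabilities = the published
  within-treatment proportions (e.g. HalfMix 49/51/2/6 of 108);
* stage probabilities = the published population structure
  (244/123/32 of 399);
* emergence rate ratios vs control = the published relative emergence
  ratios (fungi 0.468, nematodes 0.322, halfmix 0.393);
* depth locations per outcome = the published per-outcome depth means
  (negative = below ground), Normal with scales (6–8 cm) spanning the
  published ranges; distance-to-bole is zero-inflated exponential because
  the published medians are 0 with positive means.

Quantities the trial never reports were fixed once at field-realistic
values and not revisited: control emergence mean 20 adults/stump (the
operational suppression threshold in this literature), NB2 dispersion
θ = 5 (moderate overdispersion), block SD 0.3 on the log scale (±35%
block-to-block emergence variation), ~10 weevils found per stump
(399 weevils / 40 stumps in the destructive arm), Poisson per-stump totals,
distance zero-inflation 0.6, and a 9-taxon broad community with a few
dominant groups (means 1–20 per trap-season).

One root seed drives everything; each dataset draws from its own fixed
substream (`SeedSequence(seed, spawn_key)`), so generating one dataset
never perturbs another and fixtures are reproducible bit-for-bit.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatial structure among stumps, weevil phenology
and within-season emergence timing, overdispersion or correlation in the
community counts beyond Poisson, treatment effects on infection depth, and
any block-by-treatment interaction.

## Numerical choices

* NB2 fits run BFGS from a Poisson-fit start; the boundary case α → 0
  (underdispersed data) trips the optimizer's convergence flag even with a
  vanished gradient, so convergence is accepted when the score is below
  1e-4, with a simplex + polish fallback and a numerical-Hessian covariance
  when the optimizer provides none.
* The LRT clamps tiny negative statistics (optimizer noise) to 0 and raises
  beyond −1e-6.
* Probability vectors must sum to 1 within 1e-9; PCoA eigenvalues within
  1e-8 of the largest-magnitude eigenvalue are treated as zero.
* All Monte-Carlo procedures (MRPP, Dunnett) take explicit seeds and record
  their draw counts in their result objects.

## Problem sizes used in the test suite

Distributional checks run at ~10⁵ records (destructive), 10⁴–2×10⁴ blocks
(emergence moments), 500 blocks (ratio recovery within ±0.05), 1,000
replicates at 20 blocks (LRT type-I error, random mode), 200 null
simulations (MRPP A), and exhaustive enumeration on 6-item MRPP instances.
These sizes put Monte-Carlo error comfortably below the asserted
tolerances while keeping the default suite in the minutes range.
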