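# Methods

This note documents the statistical machinery behind `ipvalign`: the models,
the estimators, the numerical choices, and what the synthetic-data checks do
and do not establish.

## Generating model

All synthetic data come from a unidimensional two-parameter probit
item-response model. In group *g*, the latent trait is
η ∼ N(α_g, ψ_g) and

P(y_j = 1 | η) = Φ(λ_jg η − τ_jg).

Marginally, P(y_j = 1) = Φ((λ_jg α_g − τ_jg) / √(λ_jg² ψ_g + 1)), and the
tetrachoric correlation between items i and j is
λ_i λ_j ψ / √((λ_i²ψ + 1)(λ_j²ψ + 1)). Both closed forms are exported and
used as independent oracles in the tests.

Two preset designs are provided:

- `dhs_like_preset` emulates the scale of a 36-country domestic-violence
  survey module: invariant loadings in [0.65, 0.98], single-item base
  prevalences of 7.5–17% (physical-violence items) or 15–45% (controlling
  behaviours), group trait means drawn N(0, 0.5²), trait variances
  U(0.75, 1.3), item missingness 1% (< 2% by contract), and respondent-level
  sampling weights U(0.5, 1.5) with unit mean. The thresholds are calibrated
  so that the simulated share of women endorsing *any* item sweeps the wide
  national ranges seen in such surveys (checked empirically in the tests:
  roughly 9–74% for the physical set). The base rates of the rarest items
  are kept at or above ~7.5%: genuinely rare acts (1–4%) routinely produce
  groups with zero endorsements at a few hundred respondents per group, a
  documented cause of convergence failure in exactly this kind of analysis,
  and the preset is meant to be estimable at desk scale.
- `invariance_benchmark_spec` is the fully invariant design used for
  procedure-quality benchmarks (loadings evenly spaced over [0.65, 0.95],
  moderate prevalences 15–45%, means N(0, 0.5²), unit variances). Moderate
  prevalences keep every pairwise 2×2 margin well populated at n = 500.

The generator treats respondents as independent within group; cluster or
stratum sampling designs are not emulated, so all standard errors downstream
are respondent-level linearization or model-based quantities, not
design-based ones.

## Group-specific factor analysis (limited information)

Estimation is the standard two-stage route for binary factor analysis:
weighted probit thresholds Φ⁻¹(1 − p̂_j); pairwise tetrachoric correlations
by profile maximum likelihood (univariate thresholds fixed, bivariate-normal
orthant probabilities via Owen's T function, pairwise deletion for missing
data, a 0.5 continuity correction added to all four cells when one is
empty); then an unweighted-least-squares one-factor fit to the tetrachoric
matrix.

The discrepancy statistic is mean-scaled: with residual projection
U = I − Δ(ΔᵀΔ)⁻¹Δᵀ and Γ the asymptotic covariance of the estimated
correlations, χ² = n·F̂·df / tr(UΓ). Γ is approximated as diagonal, using
each correlation's profile-likelihood variance; the covariances *between*
correlation estimates are neglected. This is a deliberate simplification:
the statistic has the right expectation under the model and orders misfit
correctly (the properties the adequacy gate needs), but its tail calibration
is approximate. The baseline model for CFI/TLI is the independence model.
RMSEA = √(max(0, (χ²−df)/(df(n−1)))). With J = 3 the model is saturated and
all indices are reported undefined.

Loadings are reported on both scales: standardized (correlation-metric,
used by the 0.35 adequacy benchmark) and as probit slopes
a_j = λ_j/√(1−λ_j²) (the scale of the generating model and of the
full-information fits). The factor's reflection indeterminacy is fixed by
requiring a positive loading sum. A fit touching |λ| ≥ 0.995 is flagged as a
Heywood case and fails the gate. Because a one-factor exploratory model has
no rotational freedom, the exploratory and confirmatory stages share one
solution; the pipeline reports the gate at both stages to mirror the
conventional sequential workflow.

## Exact invariance (full information)

Multiple-group marginal maximum likelihood with Gauss–Hermite quadrature
(21 nodes by default; refining to 41 nodes changes the log-likelihood by
less than 10⁻³ per observation on preset data, which the tests check).
Respondents are collapsed to unique response patterns per group; missing
items drop out of the pattern likelihood (missing-at-random); sampling
weights multiply log-likelihood contributions (pseudo-ML). Analytic
gradients are used throughout; per-group covariances of (λ, τ) for the
configural model come from a sandwich estimator (finite-difference Hessian
of the analytic gradient, outer products of per-pattern scores weighted by
squared sampling weights).

Identification per level:

| level      | loadings | thresholds | α_g            | ψ_g            |
|------------|----------|------------|----------------|----------------|
| configural | free     | free       | 0 (all)        | 1 (all)        |
| metric     | shared   | free       | 0 (all)        | free, ref = 1  |
| scalar     | shared   | shared     | free, ref = 0  | free, ref = 1  |

Each level is nested in the previous one, so log-likelihoods are ordered
and χ²-difference tests apply with df equal to the parameter-count
difference (2JG, J + JG + G−1, and 2J + 2(G−1) parameters respectively).
Loadings are constrained positive (the construct's indicators are all
positively keyed). The default link is probit, matching the generator; a
logistic link is available and recovers probit slopes up to the usual ≈1.7
scale factor (tested). Starting values come from the limited-information
fits (configural) or from the previous rung (constrained levels), with two
deterministic restarts on failure. The sequential decision rule declares the
highest level whose test against the previous rung is non-significant at
α = 0.05.

## Alignment optimization

Starting from the configural parameters (λ⁰, τ⁰), alignment re-expresses
each group on a common trait scale with free mean and variance:

λ_jg = λ⁰_jg/√ψ_g,  τ_jg = τ⁰_jg + λ⁰_jg α_g/√ψ_g,

which leaves every group's response distribution exactly unchanged (verified
to 10⁻⁸ in the tests). The (α, ψ) minimize the total simplicity loss

F = Σ_j Σ_{g1<g2} √(n_g1 n_g2) [f(λ_jg1 − λ_jg2) + f(τ_jg1 − τ_jg2)],
f(x) = (x² + ε)^¼, ε = 0.01,

whose nearly flat tails favour solutions with many exactly matching
parameters and a few free deviations. The loss is non-convex; minimization
is multi-start L-BFGS (identity start, a moment-based start from average
threshold offsets, and seeded random perturbations; 10 starts by default)
with analytic gradients.

**Scale identification.** The textbook "FIXED" convention pins the reference
group's (α, ψ) at (0, 1) and optimizes everything else. At desk-scale noise
this is numerically treacherous: because f grows only like √|x|, *commonly
inflating every non-reference variance* shrinks all O(G²) non-reference
pairwise loading differences while mismatching the single reference at a
bounded cost, and for large G and noisy configural estimates (binary items,
a few hundred respondents per group) this degenerate direction is an actual
descent direction from the identity start. A gain/cost calculation shows the
pathology disappears at the sample sizes of full national surveys (thousands
per group) — which is presumably why it goes unremarked in applied work —
but at n_g = 500 with 36 groups the optimizer slides to variance estimates
an order of magnitude too large. `ipvalign` therefore identifies the
variance scale during optimization by anchoring the geometric mean of the
factor variances (Σ_g log ψ_g = 0), which removes the degenerate direction
from the feasible set, and afterwards re-expresses the solution in the
reference-group metric (reference at mean 0, variance 1). Flags,
correlations and all significance tests are invariant to that
recalibration; the reported `total_loss` is the constrained optimum's, which
never exceeds the identity assignment's loss. A related practical
consequence: heavy *same-signed* loading perturbations across many groups
are partially confounded with the variance scale and degrade alignment —
mixed-sign or threshold non-invariance is detected much more cleanly.

**Flagging.** Aligned-parameter standard errors come from the configural
sandwich covariances by the delta method (treating α̂, ψ̂ as fixed, the
usual simplification). For each item and parameter type, the invariant set
is grown greedily: seed with the least-significant pair, then repeatedly add
the group whose minimum pairwise p-value against the current members is
largest, as long as all its pairwise tests are non-significant at α = 0.01
(configurable); ties break by label order; if every pair differs, the
singleton with the largest group is kept. Groups outside the set are flagged
non-invariant. Percentages use the transparent J·G (per type) and 2·J·G
(overall) denominators, computed in exact rational arithmetic and rounded
half-up to one decimal.

**R² invariance index.** Per item and parameter type,
R² = 1 − Var_g(observed − implied)/Var_g(observed), floored at 0, where the
implied configural values are λ̄_j√ψ_g and τ̄_j − λ̄_j α_g with λ̄, τ̄ the
invariant-set weighted averages. Undefined (NaN) when the configural
parameter does not vary across groups.

**Monte-Carlo quality check.** Each replication regenerates data from the
aligned solution's parameters (unit weights), refits the configural model,
realigns (4 starts, for speed), and records the correlation across groups
between generating and re-estimated factor means; replication-level fit
failures are excluded and counted. A mean correlation of at least 0.98
indicates reliable factor means. On the fully invariant 36-group benchmark
(n_g = 500) the package attains ≈ 0.99.

## Ranking comparison

Groups are ranked by aligned factor means and by weighted any-item
prevalence, with normal-approximation CIs at 99.9% (guarding the many
pairwise comparisons). Factor-mean ranking SEs are parametric-bootstrap
standard deviations over the Monte-Carlo replications, computed after
centring each replicate on its panel mean so the reference group also
carries uncertainty. Clusters are contiguous in rank: scanning downward, a
new cluster starts when a group's CI fails to overlap every CI in the
current cluster. Rank concordance uses the matched-pairs signed-rank test
with zero-difference exclusion and midranks; the null distribution is exact
(tie-aware enumeration over sign assignments) for up to 15 informative
pairs, else normal with tie and continuity corrections. Convergent validity
is the product-moment correlation of aligned means with prevalence columns
(rank correlation available).

## Problem sizes and defaults

Simulation-based tests and the acceptance script run at 36 groups × 500
respondents (procedure-quality benchmarks), 6–10 groups × 800–2000
(recovery and detection checks), chosen so the whole battery completes in a
few minutes on one CPU while keeping every estimator in its asymptotic
operating range. Key defaults: benchmarks (0.35, 0.08, 0.95, 0.95, 25%);
probit link; 21 quadrature nodes; ε = 0.01; flagging α = 0.01; ladder
α = 0.05; ranking CI 99.9%; 10 alignment starts; 10 Monte-Carlo
replications.

## What the synthetic checks do and do not show

Passing tests establish that the estimators recover the generating model's
parameters, that the invariance tests are calibrated, and that flagging
detects injected non-invariance with high precision and recall — *under the
generating model*: independent respondents, missing-at-random item
nonresponse below 2%, unidimensionality, probit response curves, and
respondent-level weights. They do not establish robustness to clustered
sampling designs, informative missingness, multidimensional constructs,
extremely rare items (1–4% prevalence, where small groups produce empty
margins), or response styles that vary by group. Real-survey applications
should treat the adequacy gate and the Monte-Carlo check as necessary, not
sufficient, evidence.
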