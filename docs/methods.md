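# Methods

## Data model and temporal ordering

A cohort is a long-format table with one row per subject-wave and columns
`id, t, S, R, <covariates>, A, Y`. Within a wave the variables are ordered
S, R, X, A, Y. Death is monotone and truncating: after S = 0 no further
values exist and R = 0; a non-response wave (R = 0) carries no X/A/Y.
Survival status is required at every wave for every subject. Missing values
are empty CSV cells, held internally as NaN; flags are integers. Waves are
1-based and equally indexed; calendar time is not modeled. Intermittent
response (R = 0 then R = 1) is accepted in data — the missingness assumption
conditions on the full response history — although the shipped generators
produce monotone dropout only.

Covariates are typed `continuous`, `binary`, or `baseline`. Baseline
covariates (age at entry, sex, …) are constant within subject, never get a
sequential model, and enter every conditioning set exactly once.

## The sequential factorization

One regression model is fitted per factor, each on the risk set its
conditional defines, restricted to rows with the full conditioning history
observed (complete-case within factor):

| factor | link | conditioning set |
|---|---|---|
| survival s_k (k ≥ 2) | probit | y-, a-, x-, r-histories through k−1 |
| response r_k | probit | same, given survival at k |
| covariate x_k (per component, schema order) | Gaussian/probit | histories through k−1, r through k, earlier components of wave k |
| treatment a_k | Gaussian | histories with x through k, r through k |
| outcome y_k | Gaussian | histories with a and x through k |

Degenerate factors (no deaths, no dropout, single-class targets, empty
predictor sets) collapse to empirical constants rather than forcing a
sampler run. Predictor columns that are constant on a risk set are dropped
before fitting (for example, all-ones response-history columns under
monotone dropout among completers). Treatment history is conditioned on by
the models while not being part of the "history" object proper.

## Soft BART sampler

Each factor is a sum of B trees plus intercept. Per MCMC iteration and
tree: (1) one grow/prune Metropolis–Hastings move with leaf parameters
integrated out analytically (split variable drawn from the current q,
split point uniform on the scaled predictor range); (2) a random-walk move
on the log of the per-tree gating bandwidth (exponential prior, scale 0.1
of the unit predictor range); (3) a conjugate multivariate-normal draw of
the leaf vector. Then the residual variance is drawn from its scaled
inverse-χ² conditional (ν = 3, scale anchored so the prior puts 0.9 mass
below the sample SD) and the split prior's state is updated from the
forest's split counts.

Defaults follow standard BART practice: depth-d split probability
0.95·(1+d)⁻², maximum depth 8, leaf sd 0.5/(k√B) with k = 2 on the
outcome scaled to [−0.5, 0.5] (3/(k√B) for probit latents), B = 50 trees.
The bandwidth is one parameter per tree, shared across its internal nodes.
Hard-BART mode replaces the logistic gate by the indicator and skips the
bandwidth move — the b → 0 limit on the same code path. Binary outcomes use
probit latent augmentation; predictions pass through the standard-normal
CDF. Chains run independently with seeds `seed + chain` and are pooled
after warm-up; identical configurations and seeds reproduce draws exactly.

Numerical choices: the integrated structure score is computed from a
Cholesky factor of the L×L leaf-precision matrix (L = number of leaves),
with a closed form for single-leaf trees; gate arguments are clipped at
±35 before exponentiation; a zero-variance outcome returns a constant
forest with a warning.

## Split-selection priors

*Uniform* — fixed q = 1/P. *DART* — q ~ Dir(α/P,…,α/P) with
α/(α+ρ) ~ Beta(0.5, 1), ρ = P. *LDART* — the longitudinal grouping prior
described in the README: w ~ Beta(1, 1) splits current vs past mass (the
least-informative default; the temporal sparsity structure lives in the
concentration schedule, not in w); v^t ~ Dir(η/P_t); u over past waves
carries a general Dirichlet prior Dir(α_1/(t−1),…,α_{t−1}/(t−1)); each
v^k ~ Dir(φ^k/P_k). Hyperpriors: η and φ^k as in DART with ρ = group size;
α_j/(α_j + ρ_j) ~ Beta(c_j, 1) with ρ_j = t and c_j = 1 − 0.5(t−j)/(t−1),
which makes earlier waves stochastically sparser (c_1 = 0.5 always; the
schedule for t = 4 is 1/2, 2/3, 5/6).

The (w, v, u) layers are conjugate given split counts. All concentration
parameters are updated by Gibbs draws on a 64-point discretization of the
transformed scale α/(α+ρ) ∈ (0, 1) — tuning-free and exactly normalizable;
any sampler targeting the same conditional would do. Components drawn as
exact zeros by a tiny-concentration Dirichlet are floored at 1e−12 and
renormalized. In a factor's conditioning set, the "current" group is the
latest wave present (for a survival model at wave k that is wave k−1)
together with all baseline columns; with a single wave present the prior
degenerates to DART, as it should. A `lastwave` mode restricts every factor
to its current-wave (+baseline) predictors under a DART prior — this
restriction is applied pipeline-wide, which is this package's reading of a
"last-time-point-only" comparator.

## G-computation

For each selected posterior draw, N* pseudo-subjects are simulated forward:
baseline covariates resampled jointly with replacement from the observed
baseline rows (an optional Bayesian-bootstrap mode draws the resampling
weights from a flat Dirichlet, propagating baseline-distribution
uncertainty); per wave, survival and response sampled from their probit
means, covariate components in schema order, the natural value of treatment
A* from the treatment model (the observational treatment model doubles as
the natural-value model under the no-direct-effect assumption), the regime
rule applied, and the outcome sampled. Substantive variables are generated
for all alive pseudo-subjects regardless of the simulated response flag;
the simulated response history enters downstream models as predictors.

The shift δ_t is drawn once per wave per posterior draw (shared across
pseudo-subjects), so intervention uncertainty propagates with posterior
uncertainty; δ ≤ 0 is added to A* (a downward shift) only when A* > τ.
The trajectory noise stream depends only on (seed, draw) and the shift
stream is separate, so a null intervention (τ = ∞ or a point-mass zero
shift) reproduces the natural course *exactly* under shared seeds — the
package's strongest internal consistency check.

Two reported quantities are Rao-Blackwellized to cut Monte-Carlo error at
fixed N*: the survivor mean averages the outcome model's posterior-mean
surface over pseudo-survivors (intermediate-wave outcomes are still sampled
with noise, since they feed later models), and ψ averages the final-wave
survival probability over those alive at T−1. Both coincide in expectation
with their purely sampled versions. Draws with zero survivors are excluded
with a warning.

## Estimands and sensitivity analysis

PCIE is the difference of survivor means. SAIE applies the printed
adjustment `Δ{ψ* + λ(U − ψ*)}(1 − 1/U)`, U = min{1, ψ*/ψ0}, evaluated on
each posterior draw as-is — the stochastic-monotonicity constraint
ψ* ≥ ψ0 is *not* enforced per draw, since enforcing it would zero the
adjustment identically. λ and Δ are drawn once per posterior draw from
triangular priors (defaults λ ~ Tri(0.5, 1, 1); Δ's upper bound is supplied
in outcome units), independent of the data draws. Note that with Δ > 0 and
U < 1 the printed adjustment is negative (SAIE below PCIE); a
`flip_shift_sign` flag negates it for users preferring the opposite
location-shift convention — the formula is implemented as printed, the flag
only exposes the alternative. Summaries are posterior means with
equal-tailed 95% intervals (linear-interpolation quantiles).

## Synthetic benchmark

Five predictors × four waves; per predictor a Gaussian copula with unit
variances and banded covariances (0.4², 0.2², 0.1² by lag — the squared
convention is the default, `copula_square=False` uses the unsquared values),
margins mapped to Uniform(0,1); outcome Normal(Σ_t c_t ·Friedman(x_t), 10)
at the last wave; monotone dropout with retention expit[h_j Σ_{t<j} Σ_p x],
h = (0.75, 0.4, 0.25). Scenario weight vectors (wave order c_1..c_T):
A = (0.25, 0.5, 0.75, 1), B = (0, 0, 0, 1), C = (0.25, 0.25, 0.25, 0.25).
Under this design the realized average per-wave dropout among the
previously retained is about 13.6% (the retention model mildly selects
high-retention subjects over waves), i.e. roughly the intended ~15%.

The truth oracle is the Monte-Carlo mean of the Friedman surface over fresh
predictor draws (the noise is mean-zero), cross-checked against numerical
quadrature for the single-wave scenario. `oracle_model_set` plugs the
generator's exact conditionals (copula conditional normals, the true
retention model, the true outcome surface) into the same simulation engine,
isolating G-computation correctness from model fit. `run_benchmark` reports
relative absolute bias ×100 of the mean estimate across replicates, RMSE,
and 95% credible-interval coverage per model label (LDART, SBART, SBART-l1,
HDART, HBART; 50 trees each).

## Synthetic aging cohort

The end-to-end testbed emulates a prospective memory-and-aging study: eight
5-year age cohorts (35–70 at entry), four waves at 5-year intervals; sBP
follows an AR(1) in age and a latent frailty index with baseline SD ≈ 22
mm Hg (two SDs matching the −44 mm Hg shift-prior bound); memory (0–76)
declines with attained age, frailty and hypertensive sBP, with one
age-by-hypertension interaction; the terminating event (death or dementia,
treated as one) has a probit hazard in age, lagged sBP and frailty; dropout
is monotone logistic. Intercepts are calibrated so that about 18% experience
the terminating event and total attrition is about 38% over follow-up, with
memory-boundary truncation under 2%. All equations are linear/probit, so
`embedded_truth` integrates the generator by plain Monte Carlo under any
regime, giving reference values for survivor means, ψ and the PCIE.

What passing tests on these generators show — and what they do not: they
demonstrate correct algebra, a correctly targeted sampler (see below),
engine-level G-computation correctness, and effect recovery under a
data-generating process that is smooth, low-dimensional and correctly
ordered temporally. They do not establish performance under model
misspecification beyond tree-representable nonlinearity, non-monotone
missingness, measurement error, or informative (not-at-random) dropout.

## Problem sizes used by the shipped checks

The reference simulation protocol (2000 replicates, 1200 warm-up + 2000
saved thinned by 4, 48 chains) is a cluster-scale computation. The shipped
suite runs the same code paths at sizes a single workstation core handles
comfortably, as the package's own verification tier: Scenario A (n = 250,
LDART) at 10 replicates with 100 warm-up + 50 saved draws, N* = 2000 and 20
posterior draws per G-computation; Scenario B (n = 250) at 5 paired
replicates for the hard-vs-soft comparison; end-to-end PCIE recovery at 10
replicates of an n = 350 cohort with 25 trees; simulation-based calibration
with 60 prior replicates of a 5-tree, n = 30 model, testing rank uniformity
of σ and of the surface at a fixed input at α = 0.005. Tolerances scale
with the Monte-Carlo error these sizes imply; full-fidelity replication is
available through `run_benchmark`/the CLI by raising the same knobs.

## Known limitations

* Categorical predictors with more than two levels are not supported.
* No heteroscedastic or multinomial BART variants; no inverse-probability
  or doubly robust estimators; no continuous-time survival or competing
  risks (the terminating event is single and absorbing).
* Complete-case risk sets discard subjects with intermittently missing
  history from later-wave factors rather than integrating over the missing
  values.
* The always-survivor analysis uses no covariate-conditional principal
  strata; λ and Δ are scalar.
* Parallelism is per-chain only; the benchmark harness is serial.
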