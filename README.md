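# gfbart

Bayesian G-computation with **soft BART** ensembles for longitudinal cohorts
with death and dropout, featuring a **longitudinal grouped Dirichlet
split-selection prior (LDART)** and mortal-cohort causal estimands for an
**incremental threshold intervention** on a continuous treatment.

## Who this is for

Epidemiologists and biostatisticians who want to ask questions like *"what
would long-term memory look like if everyone with systolic blood pressure
above τ had it shifted downward at each visit?"* in prospective cohort data
where subjects die, develop terminal conditions, or drop out — settings
where a randomized trial is infeasible and where naive conditioning on
survival biases the answer.

## The model

Data arrive in waves t = 1..T in the temporal order S, R, X, A, Y per wave:
survival flag, response (participation) flag, time-varying confounders,
continuous treatment, continuous outcome. The observed-data distribution is
factorized sequentially and every factor is modeled with a **soft Bayesian
additive regression tree** ensemble,

    μ(d) = μ₀ + Σ_{b=1}^{B} g(d; T_b, M_b),

where each tree routes an input probabilistically: at a node splitting on
variable j at point c, the input goes right with probability
ψ((d_j − c)/b) for a logistic ψ and per-tree bandwidth b, so the fitted
surface is smooth and the b → 0 limit recovers classical (hard) BART.
Binary targets use a probit link with latent-variable augmentation.

Split variables are drawn from a probability vector **q** with a sparsity
prior. Besides uniform q and the exchangeable Dirichlet (DART) prior
q ~ Dir(α/P, …, α/P) with α/(α+ρ) ~ Beta(a, b), the package provides the
longitudinal grouping prior: predictors are split into the *current*-wave
group (baseline variables included) and one group per *past* wave, with

    q_j = w · v_j^t                     (current predictors)
    q_j = (1 − w) · u^k · v_j^k        (past-wave-k predictors)

and ordered Beta hyperpriors on the group concentrations,
α_j/(α_j + ρ_j) ~ Beta(c_j, 1) with **c_j = 1 − 0.5 (t − j)/(t − 1)** — so
predictors measured longer before the response are a priori sparser.

**G-computation.** Counterfactual means are computed by Monte-Carlo: resample
baseline covariates, then simulate survival, response, covariates, the
*natural value of treatment* A*, the (possibly intervened) treatment, and the
outcome forward wave by wave through one posterior draw of all models. The
incremental threshold regime leaves A* ≤ τ untouched and shifts A* > τ down
by a random δ ~ Triangular(L, L, 0).

**Estimands.** For survivors at the last wave,

    PCIE = E[Y_T(g*) | S_T(g*)=1] − E[Y_T(g0) | S_T(g0)=1]        (prognostic)
    SAIE = PCIE + Δ {ψ* + λ(U − ψ*)} (1 − 1/U),  U = min{1, ψ*/ψ0}  (etiological)

where ψ^g is the survival probability under regime g, λ ∈ [0, 1] indexes
stochastic monotonicity (λ = 1 deterministic monotonicity, λ = 0
independence) and Δ is the cross-stratum outcome difference; both carry
triangular priors and are drawn per posterior iteration.

## Worked example

```python
import numpy as np
from gfbart import (fit_sequential, gcomp_estimates, combine_draws, summarize,
                    RegimeSpec, SensitivitySpec, TriangularPrior,
                    McmcConfig, BartHypers)
from gfbart.cohort import FixtureConfig, generate_cohort

cohort = generate_cohort(FixtureConfig(n=400, seed=11))   # synthetic aging cohort
models = fit_sequential(cohort, "ldart",
                        McmcConfig(n_warmup=80, n_save=40, thin=2, seed=3),
                        BartHypers(n_trees=25))

g0 = RegimeSpec("natural_course")
gstar = RegimeSpec("incremental_threshold", tau=140.0,
                   shift_prior=TriangularPrior(-44.0, -44.0, 0.0), start_wave=2)
d0 = gcomp_estimates(models, g0,    n_star=1000, n_draws=15, seed=21)
ds = gcomp_estimates(models, gstar, n_star=1000, n_draws=15, seed=21)

sens = SensitivitySpec(delta_prior=TriangularPrior(0.0, 3.5, 3.5))
summary = summarize(combine_draws(d0, ds, sens, seed=1))
print(summary["pcie"], summary["psi_gstar"])
```

Output (posterior mean and equal-tailed 95% credible interval):

```
{'mean': 0.530, 'lower': 0.034, 'upper': 0.900}
{'mean': 0.856, 'lower': 0.805, 'upper': 0.886}
```

Reading: shifting hypertensive sBP (> 140 mm Hg) downward by up to 44 mm Hg
from wave 2 onward raises expected end-of-follow-up memory among survivors
by about half a point (95% CrI 0.03–0.90; the generator's true PCIE for this
configuration is 0.40), and raises the probability of surviving
dementia-free to the last wave from about 0.83 to 0.86.

A command-line interface mirrors the library:

```bash
gfbart simulate-cohort --n 800 --seed 1 --out cohort.csv
gfbart gcompute --cohort cohort.csv --config cfg.yaml --regime shift --tau 140 \
       --nstar 10000 --draws 100 --seed 1 --out gstar.csv
gfbart estimate --draws-g0 g0.csv --draws-gstar gstar.csv \
       --delta-prior 0,3.5,3.5 --out summary.json
gfbart benchmark --scenario A --n 250 --reps 200 --models ldart,sbart,hbart \
       --seed 1 --out table.csv
```

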