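# bayesord

Penalized Bayesian cumulative-logit (proportional-odds) regression with
spike-and-slab variable selection, for ordinal responses measured alongside
high-dimensional covariates — the p ≫ n setting of, e.g., screening gene
expression for features monotonically associated with an ordered prognostic
risk group (favorable < intermediate < adverse).

Frequentist penalized ordinal models (LASSO and relatives) give point
estimates conditional on a tuned penalty and no hypothesis test for "is this
coefficient zero?". `bayesord` instead places shrinkage priors on the
coefficients of

```
logit P(Y ≤ k | x) = α_k − β′x,   k = 1, …, K−1,   α_1 < … < α_{K−1},
```

samples the joint posterior by MCMC, and tests each feature with a Bayes
factor. Four hierarchies are provided:

* **Model I** — Bayesian LASSO: `β_j | λ ~ DE(0, 1/λ)`, `λ ~ Gamma(a, b)`.
* **Model II** — spike-and-slab normal:
  `β_j | γ_j ~ (1−γ_j) N(0, σ₀²) + γ_j N(0, σ₁²)`.
* **Model III** — spike-and-slab LASSO:
  `β_j | γ_j, λ ~ (1−γ_j) DE(0, 1/λ₀) + γ_j DE(0, 1/λ)`.
* **Model IV** — indicator regression (Kuo–Mallick): predictor
  `Σ_j γ_j β_j x_ij`, so `γ_j = 0` drops the feature from the likelihood.

with `γ_j ~ Bernoulli(π_j)` and `π_j` fixed or `Beta(c, d)`. Selection uses
`B₁₀` = posterior odds / prior odds, rejecting when `B₁₀ > 5`: a point null
`γ_j = 0` (Models II–IV) or an interval null `|β_j| ≤ ε` (`|γ_jβ_j| ≤ ε`
for Model IV) with `ε = 0.10` — prior odds in closed form, posterior odds
from the pooled MCMC draws. 95% equal-tailed / HPD credible-interval
selection, Gelman–Rubin PSRF diagnostics, SD-quantile pre-filtering, and a
latent-logistic synthetic-data generator round out the toolkit. See
`docs/methods.md` for the full model account.

## Worked example

```python
from bayesord import (MCMCConfig, PriorSpec, bayes_factor_table, fit,
                      score_selection, select_features, simulate)

# 300 samples, 50 standardized features, ordinal response with 3 levels;
# features 1-5 carry effects ±1.5 through the latent-logistic mechanism
data, truth = simulate(n=300, p=50, K=3, support_size=5, effect=1.5, seed=101)

prior = PriorSpec(model="IV", t=0.05)            # informative: ~5% inclusion
config = MCMCConfig(n_chains=3, n_burnin=500, n_adapt=500,
                    thin=1, n_saved_total=6000, seed=101)
samples = fit(data, prior, config)

results = select_features(bayes_factor_table(samples))   # gamma test, BF > 5
for r in results:
    print(f"{r.feature_id:12s} BF={r.bf:9.1f} posterior_odds={r.posterior_odds:8.3f}")
selected = {r.feature_id for r in results}
print(score_selection(selected, truth, feature_ids=data.feature_ids))
```

prints

```
feature_1    BF= 228019.0 posterior_odds=12001.000
feature_2    BF= 228019.0 posterior_odds=12001.000
feature_3    BF= 228019.0 posterior_odds=12001.000
feature_4    BF= 228019.0 posterior_odds=12001.000
feature_5    BF= 228019.0 posterior_odds=12001.000
SelectionScore(sensitivity=1.0, fdr=0.0, n_selected=5)
```

All five true features are recovered with no false positives: their
inclusion indicators are 1 in every one of the N = 6000 saved draws, so the
continuity-corrected posterior odds saturate at `(N+½)/½ = 12001` and
`BF = 12001 × 19 ≈ 2.3·10⁵`, while the 45 null features stay far below the
`BF > 5` line. The same `samples` object feeds `convergence_report` (PSRF per
parameter) and `credible_interval`/`select_by_interval` for the
interval-based alternative.

The CLI mirrors the library:
`bayesord simulate|preprocess|fit|select|diagnose --help`.

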