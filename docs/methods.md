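# Methods

## Model

`bayesord` fits penalized Bayesian cumulative-logit (proportional-odds)
regression to an ordinal response `Y ∈ {1, …, K}` with a high-dimensional
covariate vector `x` (p ≫ n is the intended regime, e.g. standardized gene
expression against an ordered prognostic risk group):

    logit P(Y ≤ k | x) = α_k − β′x,   k = 1, …, K−1,
    α_1 < α_2 < … < α_{K−1}.

Equivalently, a latent variable `Z` with `Z − β′x` standard logistic gives
`Y = k` when `α_{k−1} < Z ≤ α_k`. Proportional odds is assumed, not tested.
Larger `β′x` pushes mass toward higher categories; all reporting follows
this `α_k − β′x` sign convention.

Four prior hierarchies provide shrinkage and variable selection:

| Model | coefficient prior | predictor |
|---|---|---|
| I  | `β_j | λ ~ DE(0, 1/λ)`, `λ ~ Gamma(a, b)` | `β′x` |
| II | `β_j | γ_j ~ (1−γ_j) N(0, σ₀²) + γ_j N(0, σ₁²)` | `β′x` |
| III| `β_j | γ_j, λ ~ (1−γ_j) DE(0, 1/λ₀) + γ_j DE(0, 1/λ)`, `λ ~ Gamma(a, b)` | `β′x` |
| IV | `β_j | λ ~ DE(0, 1/λ)`, `λ ~ Gamma(a, b)` | `(γ∘β)′x` |

with `γ_j ~ Bernoulli(π_j)` (Models II–IV) and `π_j` either a fixed constant
`t` or `π_j ~ Beta(c, d)` feature-wise, and `α_k ~ N(0, σ²_α)` subject to the
ordering constraint. In Models II/III the indicator only relabels the prior
mixture component — `β_j` stays in the likelihood either way; in Model IV
(the Kuo–Mallick construction) `γ_j = 0` removes `x_j` from the likelihood
entirely. This asymmetry is deliberate and tested.

### Defaults and what they mean

- `a = b = 0.1`: diffuse Gamma prior on the LASSO rate λ (prior mean 1,
  variance 10); selection performance is insensitive to it away from large
  values.
- `σ²_α = 10`: wide enough that the thresholds cover the plausible range of
  the latent variable when columns of `X` are standardized.
- `σ₀² = 0.01`, `σ₁² = 10`: spike/slab variances for Model II.
- `λ₀ = 20`: spike rate for Model III (spike SD ≈ 0.07).
- `π`: `t = 0.5` (uninformative), `t = 0.05`, `Beta(1, 19)`, or
  `Beta(0.01, 0.19)` — the latter three encode the belief that few features
  matter; all three have marginal inclusion probability 1/20.
- The threshold prior is exposed per-k (`sigma2_alpha`) but defaults to a
  single shared value of 10; we found no reason to vary it by k.

Defaults assume standardized features; `fit` warns otherwise.

## Sampling

`fit` runs slice-sampling-within-Gibbs (the non-conjugate conditionals have
no closed form; univariate slice sampling is tuning-free and mirrors what
general-purpose Gibbs engines do for these models):

- each `α_k` by slice sampling restricted to `(α_{k−1}, α_{k+1})`, so an
  ordering violation is impossible by construction;
- each `β_j` by slice sampling under its conditional prior; a Model IV
  coefficient with `γ_j = 0` has a flat likelihood and is drawn directly
  from its DE prior (the degenerate slice);
- `γ_j` by its conjugate Bernoulli conditional — a prior density ratio for
  Models II/III, a likelihood ratio times the prior odds for Model IV;
- `π_j ~ Beta(c + γ_j, d + 1 − γ_j)` (Beta hyperprior only);
- `λ ~ Gamma(a + m, b + S)` where `(m, S)` count and sum the absolute
  coefficients under the `DE(0, 1/λ)` prior (all p for Models I/IV; the slab
  subset for Model III).

Slice widths adapt toward the observed bracket lengths during the tuning
phase and freeze afterwards, so the post-warm-up kernel is a fixed Markov
transition leaving the joint posterior invariant. The hot loop is compiled
with numba; a seed gives bit-identical output, and chains differ only by
seed-derived initial states (empirical-logit thresholds with per-chain
jitter, β = 0, γ from its prior, λ = a/b).

The default protocol is 3 chains, 5000 burn-in, 5000 tuning sweeps, thinning
by 3, and 9999 saved draws in total, split evenly across chains
(3333/chain). The split, the warm-up order (tuning first, then burn-in),
and pooling chains for inference are this package's conventions.

## Variable selection

Two Bayes-factor tests per feature, with `B₁₀` = posterior odds / prior
odds and rejection when `B₁₀ > 5` (strict):

- **γ point null** (`H₀: γ_j = 0`), Models II–IV. Prior odds are marginal:
  `t/(1−t)` fixed, `c/d` under `Beta(c, d)`.
- **β interval null** (`H₀: |β_j| ≤ ε`, default `ε = 0.10`; Model IV tests
  the effective coefficient `|γ_j β_j|`), needed because a continuous prior
  puts no mass on `β_j = 0`. Closed-form prior tail probabilities:
  - Model I: `(b/(b+ε))^a` — the Gamma mixture of the DE tail
    `E_λ[e^{−λε}]`;
  - Model II: `(1−π̄)·2Φ(−ε/σ₀) + π̄·2Φ(−ε/σ₁)`;
  - Model III: `(1−π̄)·e^{−λ₀ε} + π̄·(b/(b+ε))^a`;
  - Model IV: `π̄·(b/(b+ε))^a` (the excluded branch sits at exactly 0,
    inside the null);

  where `π̄` is the marginal inclusion probability. These are re-derivations
  and are validated against brute-force prior simulation in the test suite
  and the acceptance script rather than assumed.

Posterior odds are estimated from the pooled post-warm-up draws with a
continuity correction, `(m + ½)/(N − m + ½)`, which keeps the Bayes factor
finite and symmetric when an indicator chain is all zeros or all ones; the
raw ratio is available via a flag.

Credible-interval selection (95% equal-tailed or HPD interval excluding
zero) is provided as the alternative criterion; HPD is the shortest
contiguous window of sorted draws and therefore assumes a unimodal
posterior — for Model IV the γβ posterior has an atom at zero, so any
appreciable exclusion probability pulls the interval onto zero.

## Diagnostics

Classical (non-split, non-rank-normalized) Gelman–Rubin PSRF,
`R̂ = sqrt(((n−1)/n·W + B/n)/W)`, matching the era of the protocol it
reproduces; a split variant is behind a flag. Values slightly below 1 are
estimator noise and reported as computed; two constant chains at one value
return 1 by convention, at different values `inf`. Binary indicator chains
make `R̂` ill-behaved, so γ draws are summarized by per-chain means instead.
The flagging cutoff defaults to 1.1 and is configurable.

## Synthetic data

`simulate` draws standardized features with exchangeable correlation `rho`
(default 0 — correlation exists to expose the multicollinearity/sign-flip
regime where credible intervals cover zero), a sparse coefficient vector
with `support_size` entries of magnitude `effect` and alternating signs
(real signatures run in both directions), and generates `Y` through the
latent-logistic mechanism itself. Category coverage is guaranteed by
redrawing the noise a bounded number of times. It does **not** emulate
probe-level noise, batch structure, or real expression covariance, so
passing recovery tests demonstrate correctness of the method under its own
generating assumptions, not field performance.

The reference synthetic study (used by the acceptance checks and
`scripts/acceptance.py`) is n = 300, p = 50, K = 3 with thresholds (−1, 1),
5 true effects of size 1.5, and a reduced protocol of 3 chains × 2000 saved
draws after 500 burn-in + 500 tuning sweeps per chain — sizes chosen so the
study exercises the p-greater-than-selection regime while remaining
desk-scale.

## Numerical choices and validation

- Logistic CDF evaluated in a branch-stable form (no overflow for
  |α_k − η| > 30); category probabilities that underflow to ≤ 0 return a
  −∞ log-likelihood rather than NaN.
- SD-quantile filtering uses sample SD (n−1), the linear-interpolation
  quantile, and keeps ties at the threshold so a maximal-variance feature
  is never dropped; with all SDs equal every column survives any `q`.
- Standardization is computed on the full supplied matrix (no train/test
  machinery), and is idempotent to 1e-10.
- Posterior exactness is verified on an (n=30, p=2, K=3) instance against
  an independent grid-integration oracle that enumerates the 2^p indicator
  configurations, integrates λ out of every DE layer in closed form, and
  refines each configuration's grid at its own scale. For Model IV the
  comparison uses the effective coefficients γ_jβ_j: the raw β_j marginal
  there has a polynomial tail of index a+p, so at p=2 its posterior SD does
  not exist.
- Kernel validity is additionally checked by successive-conditional
  (prior → data → one sweep) simulation with a two-sample KS comparison on
  thinned draws. The harness runs at `a = b = 1`: under the default
  Gamma(0.1, 0.1), log λ has prior SD ≈ 10 while the conjugate update moves
  it ~0.7 per sweep, so no fixed-scan kernel could traverse the prior in
  bounded sweeps — a power property of the harness, not a sampler defect;
  the code path exercised is identical.
- Monte-Carlo SEs for posterior summaries are computed by within-chain
  batch means, which (unlike naive ESS formulas) captures the
  autocorrelation contributed by rare indicator flips.

## Limitations

- Proportional odds is assumed; no score/Brant test, no stereotype-logit or
  probit alternatives.
- HPD intervals assume unimodality; multimodal posteriors are not split.
- The diffuse Gamma(0.1, 0.1) hyperprior makes the Model IV excluded-β
  marginals extremely heavy-tailed; individual β draws for never-included
  features can be numerically enormous. This is a property of the stated
  hierarchy; inference uses γ and γβ, which are unaffected.
- Posterior odds from finite chains saturate at `(N + ½)/½`; Bayes factors
  beyond that are indistinguishable.
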