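"""Bayes-factor variable selection and credible-interval alternatives.

Two hypothesis tests are supported for each feature j:

* ``gamma_null`` — H0: gamma_j = 0 vs H1: gamma_j = 1 (Models II-IV).
* ``beta_interval`` — the interval null H0: |beta_j| <= eps vs
  H1: |beta_j| > eps (Models I-III), or H0: |gamma_j beta_j| <= eps for
  Model IV, whose effective coefficient is gamma_j beta_j.  The interval
  form is needed because a continuous prior puts zero mass on beta_j = 0.

The Bayes factor B10 is the ratio of posterior odds to prior odds.  Prior
odds come from the closed forms below (marginalizing the hierarchy); the
posterior odds are estimated empirically from pooled post-warm-up MCMC
draws.  A feature is selected when B10 exceeds the threshold (default 5,
between "substantial" and "strong" evidence on the usual scale), with
strict inequality.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import Model, PriorSpec

__all__ = [
    "BFTest",
    "BFTestSpec",
    "BayesFactorResult",
    "prior_odds_gamma",
    "prior_prob_beta_exceeds",
    "prior_prob_gammabeta_exceeds",
    "posterior_odds",
    "bayes_factor",
    "bayes_factor_table",
    "select_features",
    "credible_interval",
    "select_by_interval",
]


class BFTest(str, enum.Enum):
    GAMMA_NULL = "gamma_null"
    BETA_INTERVAL = "beta_interval"


@dataclass(frozen=True)
class BFTestSpec:
    """Which hypothesis is tested and at what evidence threshold."""

    test: BFTest = BFTest.GAMMA_NULL
    epsilon: float = 0.10
    bf_threshold: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "test", BFTest(self.test))
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.bf_threshold <= 0:
            raise ValueError("bf_threshold must be positive")


@dataclass(frozen=True)
class BayesFactorResult:
    feature_id: str
    prior_odds: float
    posterior_odds: float
    bf: float
    rejected: bool
    test: BFTestSpec


def prior_odds_gamma(prior: PriorSpec) -> float:
    """Marginal prior odds P(gamma_j = 1) / P(gamma_j = 0).

    t/(1-t) for fixed pi; c/d under the Beta(c, d) hyperprior, since the
    marginal inclusion probability is c/(c+d).
    """
    if prior.model is Model.I:
        raise ValueError("Model I has no inclusion indicators")
    pbar = prior.pi_bar
    return pbar / (1.0 - pbar)


def _de_gamma_tail(a: float, b: float, epsilon: float) -> float:
    """P(|beta| > eps) when beta | lambda ~ DE(0, 1/lambda), lambda ~ Gamma(a, b).

    Conditionally P(|beta| > eps | lambda) = exp(-lambda eps); taking the
    Gamma expectation gives (b / (b + eps))^a.
    """
    return (b / (b + epsilon)) ** a


def prior_prob_beta_exceeds(prior: PriorSpec, epsilon: float) -> float:
    """Marginal prior P(|beta_j| > eps) for Models I-III.

    Model I  : (b/(b+eps))^a  (Gamma-mixed DE tail).
    Model II : (1-pibar) 2 Phi(-eps/sigma_0) + pibar 2 Phi(-eps/sigma_1).
    Model III: (1-pibar) exp(-lambda0 eps) + pibar (b/(b+eps))^a.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    model = prior.model
    if model is Model.IV:
        raise ValueError(
            "Model IV tests |gamma_j beta_j|; use prior_prob_gammabeta_exceeds"
        )
    if model is Model.I:
        return _de_gamma_tail(prior.a, prior.b, epsilon)
    if model is Model.II:
        pbar = prior.pi_bar
        t0 = 2.0 * stats.norm.sf(epsilon / math.sqrt(prior.sigma2_0))
        t1 = 2.0 * stats.norm.sf(epsilon / math.sqrt(prior.sigma2_1))
        return (1.0 - pbar) * t0 + pbar * t1
    pbar = prior.pi_bar
    spike = math.exp(-prior.lambda0 * epsilon)
    slab = _de_gamma_tail(prior.a, prior.b, epsilon)
    return (1.0 - pbar) * spike + pbar * slab


def prior_prob_gammabeta_exceeds(prior: PriorSpec, epsilon: float) -> float:
    """Marginal prior P(|gamma_j beta_j| > eps) for Model IV.

    gamma_j = 0 puts the effective coefficient at exactly 0, inside the
    null, so only the included branch contributes: pibar (b/(b+eps))^a.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if prior.model is not Model.IV:
        raise ValueError("only Model IV tests |gamma_j beta_j|")
    return prior.pi_bar * _de_gamma_tail(prior.a, prior.b, epsilon)


def _h1_count(samples, j: int, test: BFTestSpec) -> tuple[int, int]:
    """(# pooled draws satisfying H1, total pooled draws) for feature j."""
    if test.test is BFTest.GAMMA_NULL:
        if samples.gamma is None:
            raise ValueError(
                f"Model {samples.model.value} stores no gamma draws; "
                "the gamma test is unavailable"
            )
        draws = samples.pooled("gamma")[:, j]
        m = int(np.sum(draws == 1))
    else:
        eff = samples.pooled_effect(j)
        m = int(np.sum(np.abs(eff) > test.epsilon))
    return m, samples.n_pooled


def posterior_odds(
    samples,
    j: int,
    test: BFTestSpec,
    correction: bool = True,
) -> float:
    """Empirical posterior odds of H1 from pooled MCMC draws.

    With m of N draws in H1, the continuity-corrected estimate is
    (m + 1/2) / (N - m + 1/2), which stays finite and symmetric when a
    gamma chain is all zeros or all ones.  ``correction=False`` gives the
    raw m / (N - m) (inf when m = N).
    """
    m, N = _h1_count(samples, j, test)
    if N == 0:
        raise ValueError("no posterior draws")
    if correction:
        return (m + 0.5) / (N - m + 0.5)
    if m == N:
        return math.inf
    return m / (N - m)


def _prior_odds_for(prior: PriorSpec, test: BFTestSpec) -> float:
    if test.test is BFTest.GAMMA_NULL:
        return prior_odds_gamma(prior)
    if prior.model is Model.IV:
        p1 = prior_prob_gammabeta_exceeds(prior, test.epsilon)
    else:
        p1 = prior_prob_beta_exceeds(prior, test.epsilon)
    return p1 / (1.0 - p1)


def bayes_factor(
    samples,
    j: int,
    prior: PriorSpec | None = None,
    test: BFTestSpec | None = None,
    correction: bool = True,
) -> BayesFactorResult:
    """B10 = posterior odds / prior odds for feature j, with the decision."""
    prior = samples.prior if prior is None else prior
    test = BFTestSpec() if test is None else test
    if prior.model is Model.I and test.test is BFTest.GAMMA_NULL:
        raise ValueError("Model I has no gamma; only the beta interval test applies")
    po = posterior_odds(samples, j, test, correction=correction)
    pr = _prior_odds_for(prior, test)
    bf = po / pr
    return BayesFactorResult(
        feature_id=samples.feature_ids[j],
        prior_odds=pr,
        posterior_odds=po,
        bf=bf,
        rejected=bf > test.bf_threshold,
        test=test,
    )


def bayes_factor_table(
    samples,
    test: BFTestSpec | None = None,
    correction: bool = True,
) -> list[BayesFactorResult]:
    """Bayes factor for every feature, in column order."""
    test = BFTestSpec() if test is None else test
    return [
        bayes_factor(samples, j, test=test, correction=correction)
        for j in range(len(samples.feature_ids))
    ]


def select_features(results: list[BayesFactorResult]) -> list[BayesFactorResult]:
    """The rejected features, sorted by Bayes factor descending."""
    if not results:
        return []
    spec0 = results[0].test
    if any(r.test != spec0 for r in results):
        raise ValueError("all results must share one test spec")
    chosen = [r for r in results if r.rejected]
    return sorted(chosen, key=lambda r: r.bf, reverse=True)


def credible_interval(
    draws: np.ndarray, level: float = 0.95, kind: str = "ET"
) -> tuple[float, float]:
    """Equal-tailed or highest-posterior-density interval of scalar draws.

    ET uses empirical quantiles at (1-level)/2 and (1+level)/2.  HPD is the
    shortest contiguous window of the sorted draws containing
    ceil(level * N) of them — this assumes a unimodal posterior.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    kind = kind.upper()
    if kind == "ET":
        lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)
    if kind != "HPD":
        raise ValueError("kind must be 'ET' or 'HPD'")
    x = np.sort(draws)
    n = x.size
    m = int(math.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 + np.arange(n - m + 1)] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def select_by_interval(
    samples, j: int, level: float = 0.95, kind: str = "ET"
) -> bool:
    """True when the credible interval for feature j's effective coefficient
    (beta_j, or gamma_j beta_j for Model IV) excludes zero."""
    lo, hi = credible_interval(samples.pooled_effect(j), level=level, kind=kind)
    return not (lo <= 0.0 <= hi)
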