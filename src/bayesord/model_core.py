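"""Cumulative-logit (proportional-odds) model core.

The model for an ordinal response :math:`Y \\in \\{1, \\dots, K\\}` with
covariate vector :math:`x` is

.. math::

    \\log\\frac{P(Y \\le k \\mid x)}{P(Y > k \\mid x)}
        = \\alpha_k - \\beta' x, \\qquad k = 1, \\dots, K-1,

with strictly increasing thresholds :math:`\\alpha_1 < \\dots < \\alpha_{K-1}`.
Equivalently, a latent variable :math:`Z` with :math:`Z - \\beta'x` standard
logistic yields :math:`Y = k` when :math:`\\alpha_{k-1} < Z \\le \\alpha_k`.
Larger :math:`\\beta' x` pushes probability mass toward higher categories.

This module holds the shared domain types consumed by every sampler variant
and the likelihood itself; the four prior hierarchies live in
:mod:`bayesord.samplers`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Model",
    "OrdinalDataset",
    "PriorSpec",
    "ParameterState",
    "cumulative_prob",
    "category_probs",
    "log_likelihood",
]


class Model(str, enum.Enum):
    """The four penalized Bayesian ordinal regression variants.

    I   - Bayesian LASSO: beta_j | lambda ~ DE(0, 1/lambda), lambda ~ Gamma(a, b).
    II  - spike-and-slab normal: beta_j | gamma_j ~ (1-gamma_j) N(0, sigma2_0)
          + gamma_j N(0, sigma2_1).
    III - spike-and-slab LASSO: beta_j | gamma_j, lambda ~ (1-gamma_j)
          DE(0, 1/lambda0) + gamma_j DE(0, 1/lambda).
    IV  - indicator regression: linear predictor uses gamma_j * beta_j with
          beta_j | lambda ~ DE(0, 1/lambda).
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class PiMode(str, enum.Enum):
    FIXED = "fixed"
    BETA = "beta"


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic CDF, branch-stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class OrdinalDataset:
    """A standardized feature matrix with an ordinal response.

    Attributes
    ----------
    X : (n, p) float array
        Standardized features (each column mean 0, sample SD 1).
    y : (n,) int array
        Ordinal response coded 1..K.
    K : int
        Number of ordered categories, >= 2.
    feature_ids : tuple of str
        Column identifiers, length p.
    """

    X: np.ndarray
    y: np.ndarray
    K: int
    feature_ids: tuple[str, ...] = ()
    require_all_levels: bool = True

    def __post_init__(self) -> None:
        X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = X.shape
        if n < 1:
            raise ValueError("need at least one sample")
        if y.shape != (n,):
            raise ValueError(f"y has length {y.shape}, expected ({n},)")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if y.min(initial=self.K) < 1 or y.max(initial=1) > self.K:
            raise ValueError("y values must lie in 1..K")
        missing = set(range(1, self.K + 1)) - set(np.unique(y).tolist())
        if missing and self.require_all_levels:
            raise ValueError(
                f"every category 1..K must appear in y; missing {sorted(missing)}"
            )
        object.__setattr__(self, "_levels_missing", bool(missing))
        if not self.feature_ids:
            object.__setattr__(
                self, "feature_ids", tuple(f"feature_{j + 1}" for j in range(p))
            )
        elif len(self.feature_ids) != p:
            raise ValueError("feature_ids length must equal number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def is_standardized(self, tol: float = 1e-8) -> bool:
        if self.p == 0:
            return True
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=1)
        return bool(np.all(np.abs(mu) < tol) and np.all(np.abs(sd - 1.0) < tol))


@dataclass(frozen=True)
class PriorSpec:
    """Prior hierarchy for one model variant.

    Defaults are the values used throughout the analysis this package
    reproduces: a diffuse Gamma(0.1, 0.1) on the LASSO rate lambda, threshold
    variance sigma2_alpha = 10 (wide enough to cover the latent-variable
    range on standardized inputs), spike/slab variances 0.01 / 10 for the
    normal mixture, and spike rate lambda0 = 20 for the double-exponential
    mixture.  ``pi`` — the prior inclusion probability — is either a fixed
    constant ``t`` or Beta(c, d) feature-wise.
    """

    model: Model
    a: float = 0.1
    b: float = 0.1
    sigma2_alpha: float = 10.0
    sigma2_0: float = 0.01
    sigma2_1: float = 10.0
    lambda0: float = 20.0
    pi_mode: PiMode = PiMode.FIXED
    t: float = 0.05
    c: float = 1.0
    d: float = 19.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        object.__setattr__(self, "pi_mode", PiMode(self.pi_mode))
        for name in ("a", "b", "sigma2_alpha", "sigma2_0", "sigma2_1", "lambda0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.model is Model.II and not self.sigma2_0 < self.sigma2_1:
            raise ValueError("Model II requires sigma2_0 < sigma2_1")
        if self.pi_mode is PiMode.FIXED and not 0.0 < self.t < 1.0:
            raise ValueError("fixed pi requires t in (0, 1)")
        if self.pi_mode is PiMode.BETA and (self.c <= 0 or self.d <= 0):
            raise ValueError("Beta(c, d) hyperprior requires c, d > 0")

    @property
    def has_gamma(self) -> bool:
        return self.model is not Model.I

    @property
    def has_lambda(self) -> bool:
        return self.model is not Model.II

    @property
    def pi_bar(self) -> float:
        """Marginal prior inclusion probability P(gamma_j = 1)."""
        if not self.has_gamma:
            raise ValueError(f"Model {self.model.value} has no inclusion indicator")
        if self.pi_mode is PiMode.FIXED:
            return self.t
        return self.c / (self.c + self.d)

    def with_pi(self, pi: str | float) -> "PriorSpec":
        """Return a copy with the ``pi`` specification replaced.

        ``pi`` is a float (fixed t) or a string ``"beta:c,d"``.
        """
        if isinstance(pi, str) and pi.startswith("beta:"):
            c, d = (float(v) for v in pi[len("beta:"):].split(","))
            return replace(self, pi_mode=PiMode.BETA, c=c, d=d)
        return replace(self, pi_mode=PiMode.FIXED, t=float(pi))


@dataclass
class ParameterState:
    """One point in parameter space for a given model variant.

    ``gamma`` is present for Models II-IV, ``lam`` for Models I/III/IV, and
    ``pi`` is a per-feature vector only under the Beta hyperprior.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None = None
    pi: np.ndarray | float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(np.diff(self.alpha) <= 0):
            raise ValueError("alpha thresholds must be strictly increasing")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=np.int64)
            if not np.isin(self.gamma, (0, 1)).all():
                raise ValueError("gamma entries must be 0 or 1")
            if self.gamma.shape != self.beta.shape:
                raise ValueError("gamma and beta must have the same length")

    def validate_for(self, model: Model) -> None:
        model = Model(model)
        if model is Model.I and self.gamma is not None:
            raise ValueError("Model I state must not carry gamma")
        if model is not Model.I and self.gamma is None:
            raise ValueError(f"Model {model.value} state requires gamma")


def cumulative_prob(alpha_k: float, eta: float) -> float:
    """P(Y <= k | x) = logistic(alpha_k - eta) with eta = beta'x.

    Strictly increasing in ``alpha_k`` and strictly decreasing in ``eta``.
    """
    if not (np.isfinite(alpha_k) and np.isfinite(eta)):
        raise ValueError("cumulative_prob requires finite inputs")
    return float(_sigmoid(np.asarray(alpha_k - eta)))


def category_probs(alpha: np.ndarray, eta: float) -> np.ndarray:
    """Category probabilities P(Y = k | x), k = 1..K, as first differences
    of the cumulative logistic probabilities at the thresholds."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1:
        raise ValueError("alpha must be a non-empty 1-D threshold vector")
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("alpha thresholds must be strictly increasing")
    if not (np.all(np.isfinite(alpha)) and np.isfinite(eta)):
        raise ValueError("category_probs requires finite inputs")
    cum = np.concatenate(([0.0], _sigmoid(alpha - eta), [1.0]))
    return np.diff(cum)


def linear_predictor(state: ParameterState, data: OrdinalDataset, model: Model) -> np.ndarray:
    """eta_i = sum_j beta_j x_ij (Models I-III) or sum_j gamma_j beta_j x_ij (IV)."""
    model = Model(model)
    if model is Model.IV:
        return data.X @ (state.gamma * state.beta)
    return data.X @ state.beta


def log_likelihood(
    state: ParameterState, data: OrdinalDataset, model: Model | str
) -> float:
    """Log-likelihood of the ordinal data under the cumulative-logit model.

    Models I-III share the predictor ``beta'x``; Model IV multiplies each
    coefficient by its inclusion indicator, so features with gamma_j = 0 are
    dropped from the likelihood entirely (their beta_j remains a free
    parameter under its prior).
    """
    model = Model(model)
    state.validate_for(model)
    if state.alpha.size != data.K - 1:
        raise ValueError("alpha length must be K - 1")
    if state.beta.size != data.p:
        raise ValueError("beta length must equal number of features")
    eta = linear_predictor(state, data, model)
    upper = np.concatenate((state.alpha, [np.inf]))[data.y - 1]
    lower = np.concatenate(([-np.inf], state.alpha))[data.y - 1]
    with np.errstate(over="ignore"):
        pu = np.where(np.isinf(upper), 1.0, _sigmoid(upper - eta))
        pl = np.where(np.isinf(lower), 0.0, _sigmoid(lower - eta))
    pr = pu - pl
    if np.any(pr <= 0):
        return -np.inf
    return float(np.sum(np.log(pr)))
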