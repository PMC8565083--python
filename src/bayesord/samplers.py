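"""MCMC engines for the four penalized Bayesian ordinal regression models.

:func:`fit` runs slice-sampling-within-Gibbs chains (the hot loop is the
JIT-compiled kernel in :mod:`bayesord._gibbs`): univariate slice updates for
the thresholds alpha_k (restricted to their ordering interval) and the
coefficients beta_j, conjugate Gibbs draws for lambda (Gamma), gamma
(Bernoulli) and pi (Beta).  Slice widths adapt during the tuning phase and
freeze afterwards, so the post-warm-up kernel is a fixed transition that
leaves the joint posterior invariant.

The individual conditional updates are also exposed as plain numpy
functions (:func:`update_lambda`, :func:`update_gamma_conditional`,
:func:`update_pi`, :func:`update_alpha_beta`) so each full conditional can
be inspected and tested on its own.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from . import _gibbs
from .model_core import (
    Model,
    OrdinalDataset,
    ParameterState,
    PiMode,
    PriorSpec,
    log_likelihood,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "fit",
    "update_lambda",
    "update_gamma_conditional",
    "update_pi",
    "update_alpha_beta",
    "sample_prior",
    "kernel_sweep",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol.

    Defaults reproduce the reference protocol: three chains with 5000
    burn-in and 5000 tuning sweeps each, thinning to every third sweep, and
    9999 saved draws in total across chains (split evenly, 3333 per chain).
    """

    n_chains: int = 3
    n_burnin: int = 5000
    n_adapt: int = 5000
    thin: int = 3
    n_saved_total: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_burnin < 0 or self.n_adapt < 0:
            raise ValueError("n_burnin and n_adapt must be >= 0")
        if self.n_saved_total < self.n_chains:
            raise ValueError("n_saved_total must be >= n_chains")

    @property
    def n_saved_per_chain(self) -> int:
        return self.n_saved_total // self.n_chains


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws.

    Arrays are shaped [chain, iteration, dim]; ``gamma`` is None for
    Model I, ``pi`` is None unless the Beta hyperprior was used, ``lam`` is
    None for Model II.  Draws are post-warm-up and already thinned.
    """

    model: Model
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None
    pi: np.ndarray | None
    lam: np.ndarray | None
    config: MCMCConfig
    prior: PriorSpec
    feature_ids: tuple[str, ...]

    @property
    def n_pooled(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Chains stacked into one sample, shape (N, dim) or (N,)."""
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} draws are not stored for model {self.model.value}")
        return arr.reshape(-1, *arr.shape[2:])

    def pooled_effect(self, j: int) -> np.ndarray:
        """Pooled draws of the effective coefficient of feature j:
        beta_j for Models I-III, gamma_j * beta_j for Model IV."""
        beta = self.pooled("beta")[:, j]
        if self.model is Model.IV:
            return self.pooled("gamma")[:, j] * beta
        return beta

    def save(self, directory: str | Path) -> None:
        """Write draws as per-parameter .npy arrays plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {"alpha": self.alpha, "beta": self.beta}
        for name in ("gamma", "pi", "lam"):
            if getattr(self, name) is not None:
                arrays[name] = getattr(self, name)
        for name, arr in arrays.items():
            np.save(directory / f"{name}.npy", arr)
        prior = dataclasses.asdict(self.prior)
        prior["model"] = self.prior.model.value
        prior["pi_mode"] = self.prior.pi_mode.value
        manifest = {
            "model": self.model.value,
            "config": dataclasses.asdict(self.config),
            "prior": prior,
            "feature_ids": list(self.feature_ids),
            "shapes": {name: list(arr.shape) for name, arr in arrays.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        arrays = {
            name: np.load(directory / f"{name}.npy")
            for name in manifest["shapes"]
        }
        return cls(
            model=Model(manifest["model"]),
            alpha=arrays["alpha"],
            beta=arrays["beta"],
            gamma=arrays.get("gamma"),
            pi=arrays.get("pi"),
            lam=arrays.get("lam"),
            config=MCMCConfig(**manifest["config"]),
            prior=PriorSpec(**manifest["prior"]),
            feature_ids=tuple(manifest["feature_ids"]),
        )


# ---------------------------------------------------------------------------
# conjugate full conditionals (spec-level operations)
# ---------------------------------------------------------------------------


def update_lambda(
    beta: np.ndarray,
    gamma: np.ndarray | None,
    model: Model | str,
    a: float,
    b: float,
    lambda0: float = 20.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw lambda from its conjugate Gamma full conditional.

    With a DE(0, 1/lambda) prior on m coefficients and lambda ~ Gamma(a, b),
    the conditional is Gamma(a + m, b + S) with S the summed |beta| of those
    coefficients.  Models I/IV place the DE(0, 1/lambda) prior on every
    beta_j (m = p); Model III only on the slab components (gamma_j = 1) —
    spike coefficients sit under the fixed rate lambda0 and contribute
    nothing.  Model II has no lambda.
    """
    model = Model(model)
    if model is Model.II:
        raise ValueError("Model II has no lambda parameter")
    beta = np.asarray(beta, dtype=float)
    if model is Model.III:
        if gamma is None:
            raise ValueError("Model III lambda update requires gamma")
        gamma = np.asarray(gamma)
        m = int(gamma.sum())
        S = float(np.abs(beta[gamma == 1]).sum())
    else:
        m = beta.size
        S = float(np.abs(beta).sum())
    rng = np.random.default_rng() if rng is None else rng
    return float(rng.gamma(shape=a + m, scale=1.0 / (b + S)))


def update_gamma_conditional(
    beta_j: float,
    pi_j: float,
    prior: PriorSpec,
    model: Model | str | None = None,
    likelihood_ratio: float | None = None,
    lam: float | None = None,
) -> float:
    """P(gamma_j = 1 | everything else).

    Models II/III: the indicator appears only in the prior mixture (beta_j
    stays in the likelihood either way), so the probability is
    pi_j f1(beta_j) / [pi_j f1(beta_j) + (1-pi_j) f0(beta_j)] with f0/f1
    the spike/slab densities — for Model III the slab rate is the current
    draw of lambda, passed via ``lam``.  Model IV drops x_j from the
    likelihood when gamma_j = 0 while beta_j's DE prior is the same under
    both indicator values, so the densities cancel and the slab term is
    weighted by the likelihood ratio L(gamma_j=1 | rest)/L(gamma_j=0 | rest).
    """
    model = Model(model if model is not None else prior.model)
    if model is Model.I:
        raise ValueError("Model I has no inclusion indicators")
    if not 0.0 < pi_j < 1.0:
        raise ValueError("pi_j must lie in (0, 1)")
    if model is Model.II:
        f0 = stats.norm.pdf(beta_j, scale=math.sqrt(prior.sigma2_0))
        f1 = stats.norm.pdf(beta_j, scale=math.sqrt(prior.sigma2_1))
        R = 1.0
    elif model is Model.III:
        if lam is None:
            raise ValueError("Model III requires the current lambda draw")
        f0 = stats.laplace.pdf(beta_j, scale=1.0 / prior.lambda0)
        f1 = stats.laplace.pdf(beta_j, scale=1.0 / lam)
        R = 1.0
    else:
        if likelihood_ratio is None:
            raise ValueError("Model IV requires the likelihood ratio")
        f0 = f1 = 1.0
        R = float(likelihood_ratio)
    num = pi_j * f1 * R
    return num / (num + (1.0 - pi_j) * f0)


def update_pi(
    gamma_j: int,
    c: float,
    d: float,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw pi_j from Beta(c + gamma_j, d + 1 - gamma_j).

    Beta-Bernoulli conjugacy with a single trial, because pi_j is
    feature-specific.  Only valid under the Beta hyperprior; a fixed pi is a
    constant and is never updated.
    """
    if gamma_j not in (0, 1):
        raise ValueError("gamma_j must be 0 or 1")
    rng = np.random.default_rng() if rng is None else rng
    return float(rng.beta(c + gamma_j, d + 1 - gamma_j))


def slice_sample(logf, x0, w, rng, lo=-np.inf, hi=np.inf, max_steps=1000):
    """Univariate slice sampling with stepping-out and shrinkage."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample requires a finite density at the current point")
    logy = f0 + np.log(rng.random())
    u = rng.random()
    L = max(x0 - w * u, lo)
    R = min(L + w, hi)
    steps = max_steps
    while L > lo and logf(L) > logy and steps > 0:
        L = max(L - w, lo)
        steps -= 1
    steps = max_steps
    while R < hi and logf(R) > logy and steps > 0:
        R = min(R + w, hi)
        steps -= 1
    for _ in range(max_steps):
        x1 = L + rng.random() * (R - L)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


def update_alpha_beta(
    state: ParameterState,
    data: OrdinalDataset,
    prior: PriorSpec,
    rng: np.random.Generator | None = None,
    width: float = 1.0,
) -> ParameterState:
    """One sweep of univariate slice updates for every alpha_k and beta_j.

    Each alpha_k is updated on the interval (alpha_{k-1}, alpha_{k+1}), so
    a draw violating the ordering is impossible by construction.  Each
    beta_j is updated under its conditional prior; a model-IV coefficient
    with gamma_j = 0 has a flat likelihood, and the slice target degenerates
    to the conditional prior.

    This is the reference numpy implementation of the kernel; :func:`fit`
    runs the compiled equivalent.
    """
    rng = np.random.default_rng() if rng is None else rng
    model = prior.model
    state.validate_for(model)
    alpha = state.alpha.copy()
    beta = state.beta.copy()
    gamma = None if state.gamma is None else state.gamma.copy()
    lam = state.lam
    K1 = alpha.size

    def make_state(al, be):
        return ParameterState(alpha=al, beta=be, gamma=gamma, pi=state.pi, lam=lam)

    for k in range(K1):
        lo = alpha[k - 1] if k > 0 else -np.inf
        hi = alpha[k + 1] if k < K1 - 1 else np.inf

        def logf_a(v, k=k):
            al = alpha.copy()
            al[k] = v
            ll = log_likelihood(make_state(al, beta), data, model)
            return ll - 0.5 * v * v / prior.sigma2_alpha

        alpha[k] = slice_sample(logf_a, alpha[k], width, rng, lo=lo, hi=hi)

    for j in range(beta.size):
        g = 1 if gamma is None else int(gamma[j])

        def log_prior_b(v):
            if model in (Model.I, Model.IV):
                return -lam * abs(v)
            if model is Model.II:
                s2 = prior.sigma2_1 if g == 1 else prior.sigma2_0
                return -0.5 * v * v / s2
            rate = lam if g == 1 else prior.lambda0
            return -rate * abs(v)

        include = not (model is Model.IV and g == 0)

        def logf_b(v, j=j):
            be = beta.copy()
            be[j] = v
            lp = log_prior_b(v)
            if include:
                lp += log_likelihood(make_state(alpha, be), data, model)
            return lp

        beta[j] = slice_sample(logf_b, beta[j], width, rng)

    return ParameterState(alpha=alpha, beta=beta, gamma=gamma, pi=state.pi, lam=lam)


# ---------------------------------------------------------------------------
# prior sampling and full-kernel access (joint-distribution validation)
# ---------------------------------------------------------------------------


def sample_prior(
    prior: PriorSpec, K: int, p: int, rng: np.random.Generator
) -> ParameterState:
    """Draw one parameter state from the joint prior of the given model."""
    while True:
        alpha = rng.normal(0.0, math.sqrt(prior.sigma2_alpha), size=K - 1)
        alpha.sort()
        if K == 2 or np.all(np.diff(alpha) > 0):
            break
    lam = None
    if prior.has_lambda:
        lam = float(rng.gamma(prior.a, 1.0 / prior.b))
    gamma = None
    pi: float | np.ndarray | None = None
    if prior.has_gamma:
        if prior.pi_mode is PiMode.BETA:
            pi = rng.beta(prior.c, prior.d, size=p)
        else:
            pi = np.full(p, prior.t)
        gamma = (rng.random(p) < pi).astype(np.int64)
    model = prior.model
    if model in (Model.I, Model.IV):
        beta = rng.laplace(0.0, 1.0 / lam, size=p)
    elif model is Model.II:
        sd = np.where(gamma == 1, math.sqrt(prior.sigma2_1), math.sqrt(prior.sigma2_0))
        beta = rng.normal(0.0, sd)
    else:  # III
        rate = np.where(gamma == 1, lam, prior.lambda0)
        beta = rng.laplace(0.0, 1.0 / rate)
    return ParameterState(alpha=alpha, beta=beta, gamma=gamma, pi=pi, lam=lam)


_MODEL_CODE = {Model.I: 1, Model.II: 2, Model.III: 3, Model.IV: 4}


def _state_arrays(state: ParameterState, prior: PriorSpec, p: int):
    gamma = state.gamma if state.gamma is not None else np.zeros(p, dtype=np.int64)
    if prior.has_gamma and prior.pi_mode is PiMode.BETA:
        pi = np.asarray(state.pi, dtype=float).copy()
    else:
        pi = np.full(p, prior.t if prior.has_gamma else 0.5)
    lam = state.lam if state.lam is not None else 1.0
    return gamma.astype(np.int64).copy(), pi, float(lam)


def kernel_sweep(
    state: ParameterState,
    data: OrdinalDataset,
    prior: PriorSpec,
    widths: tuple[np.ndarray, np.ndarray] | None = None,
) -> ParameterState:
    """Apply one full sweep of the compiled Gibbs kernel to ``state``.

    Uses the kernel's own RNG stream; seed it first with
    ``bayesord._gibbs.seed_rng(seed)``.  Slice widths default to 1 and are
    not adapted, so repeated calls form a time-homogeneous Markov chain with
    the joint posterior as its stationary distribution.
    """
    model = prior.model
    state.validate_for(model)
    code = _MODEL_CODE[model]
    p = data.p
    alpha = state.alpha.astype(float).copy()
    beta = state.beta.astype(float).copy()
    gamma, pi, lam = _state_arrays(state, prior, p)
    lam_arr = np.array([lam])
    coef = gamma * beta if model is Model.IV else beta
    eta = data.X @ coef
    if widths is None:
        w_alpha = np.full(data.K - 1, 1.0)
        w_beta = np.full(p, 1.0)
    else:
        w_alpha, w_beta = widths
    yk = (data.y - 1).astype(np.int64)
    _gibbs.gibbs_sweep(
        data.X, yk, data.K, code, alpha, beta, gamma, pi, lam_arr, eta,
        prior.a, prior.b, prior.sigma2_alpha, prior.sigma2_0, prior.sigma2_1,
        prior.lambda0,
        prior.has_gamma and prior.pi_mode is PiMode.BETA,
        prior.c, prior.d, w_alpha, w_beta, False,
    )
    return ParameterState(
        alpha=alpha,
        beta=beta,
        gamma=gamma if prior.has_gamma else None,
        pi=pi if (prior.has_gamma and prior.pi_mode is PiMode.BETA) else state.pi,
        lam=float(lam_arr[0]) if prior.has_lambda else None,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _initial_alpha(data: OrdinalDataset) -> np.ndarray:
    """Empirical logit of the cumulative category frequencies."""
    counts = np.bincount(data.y, minlength=data.K + 1)[1:]
    cum = np.cumsum(counts)[:-1] / data.n
    cum = np.clip(cum, 1.0 / (2 * data.n), 1.0 - 1.0 / (2 * data.n))
    alpha = np.log(cum / (1.0 - cum))
    # enforce strict ordering in degenerate corners
    for k in range(1, alpha.size):
        if alpha[k] <= alpha[k - 1]:
            alpha[k] = alpha[k - 1] + 1e-6
    return alpha


def fit(
    data: OrdinalDataset,
    prior: PriorSpec,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the selected model variant.

    Chains differ only by seed-derived initial states: the empirical
    threshold initialization is jittered per chain for overdispersion,
    beta starts at zero, gamma is drawn from its prior, lambda at its prior
    mean a/b.  Identical (data, prior, config) give bit-identical output.
    """
    config = MCMCConfig() if config is None else config
    model = prior.model
    if getattr(data, "_levels_missing", False):
        raise ValueError("fit refuses data in which some category 1..K never occurs")
    if data.p > 0 and not data.is_standardized(tol=1e-6):
        warnings.warn(
            "features are not standardized; the default prior scales assume "
            "mean-0 / SD-1 columns",
            stacklevel=2,
        )
    code = _MODEL_CODE[model]
    yk = (data.y - 1).astype(np.int64)
    pi_is_beta = prior.has_gamma and prior.pi_mode is PiMode.BETA
    n_save = config.n_saved_per_chain
    alpha_emp = _initial_alpha(data)

    chain_seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * config.n_chains
    ) % (2**31 - 1)

    alphas, betas, gammas, pis, lams = [], [], [], [], []
    for chain in range(config.n_chains):
        init_rng = np.random.default_rng(int(chain_seeds[2 * chain]))
        alpha0 = alpha_emp + 0.5 * init_rng.standard_normal(alpha_emp.size)
        alpha0.sort()
        for k in range(1, alpha0.size):
            if alpha0[k] <= alpha0[k - 1]:
                alpha0[k] = alpha0[k - 1] + 1e-6
        beta0 = np.zeros(data.p)
        if prior.has_gamma:
            pbar = prior.pi_bar
            gamma0 = (init_rng.random(data.p) < pbar).astype(np.int64)
            pi0 = (
                init_rng.beta(prior.c, prior.d, size=data.p)
                if pi_is_beta
                else np.full(data.p, prior.t)
            )
        else:
            gamma0 = np.zeros(data.p, dtype=np.int64)
            pi0 = np.full(data.p, 0.5)
        lam_init = prior.a / prior.b

        out = _gibbs.run_chain(
            data.X, yk, data.K, code,
            alpha0, beta0, gamma0, pi0, lam_init,
            prior.a, prior.b, prior.sigma2_alpha, prior.sigma2_0,
            prior.sigma2_1, prior.lambda0,
            pi_is_beta, prior.c, prior.d,
            config.n_burnin, config.n_adapt, config.thin, n_save,
            int(chain_seeds[2 * chain + 1]),
        )
        alpha_d, beta_d, gamma_d, pi_d, lam_d = out
        alphas.append(alpha_d)
        betas.append(beta_d)
        gammas.append(gamma_d)
        pis.append(pi_d)
        lams.append(lam_d)

    alpha_all = np.stack(alphas)
    if np.any(np.diff(alpha_all, axis=2) <= 0):
        raise RuntimeError("internal invariant violated: non-increasing alpha draw")
    return PosteriorSamples(
        model=model,
        alpha=alpha_all,
        beta=np.stack(betas),
        gamma=np.stack(gammas).astype(np.int8) if prior.has_gamma else None,
        pi=np.stack(pis) if pi_is_beta else None,
        lam=np.stack(lams) if prior.has_lambda else None,
        config=config,
        prior=prior,
        feature_ids=data.feature_ids,
    )
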