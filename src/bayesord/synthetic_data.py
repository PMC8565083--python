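"""Synthetic p >> n ordinal datasets with known sparse truth.

Data are generated through the same latent-variable mechanism the model
assumes: features X with exchangeable correlation ``rho`` are standardized,
a sparse coefficient vector beta carries ``support_size`` entries of
magnitude ``effect`` with alternating signs (real expression signatures run
in both directions), the latent variable is Z_i = beta'x_i + logistic(0, 1)
noise, and Y_i = k when alpha_{k-1} < Z_i <= alpha_k.

The generator guarantees every category appears in y, redrawing the logistic
noise a bounded number of times if necessary.  What it does not emulate:
probe-level measurement noise, batch effects, or the heavy-tailed empirical
covariance of real expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import OrdinalDataset
from .preprocess import standardize

__all__ = ["SimulationTruth", "SelectionScore", "simulate", "score_selection"]

_MAX_NOISE_RETRIES = 100


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth underlying one simulated dataset."""

    beta_true: np.ndarray
    support: tuple[int, ...]
    alpha_true: np.ndarray
    seed: int

    def support_ids(self, feature_ids) -> set[str]:
        return {feature_ids[j] for j in self.support}


@dataclass(frozen=True)
class SelectionScore:
    """Sensitivity and false discovery rate of a selected feature set."""

    sensitivity: float
    fdr: float
    n_selected: int


def simulate(
    n: int,
    p: int,
    K: int = 3,
    support_size: int = 5,
    effect: float = 1.5,
    alpha: tuple[float, ...] = (-1.0, 1.0),
    rho: float = 0.0,
    seed: int = 0,
) -> tuple[OrdinalDataset, SimulationTruth]:
    """Draw one ordinal dataset from the latent-logistic mechanism.

    Parameters
    ----------
    n, p, K : problem dimensions.
    support_size : number of truly non-zero coefficients (the first
        ``support_size`` features; exchangeable correlation makes the
        placement immaterial).
    effect : magnitude of the non-zero coefficients, signs alternating
        +, -, +, ...
    alpha : K-1 strictly increasing latent thresholds.
    rho : exchangeable feature correlation in [0, 1).
    seed : RNG seed; identical seeds give identical datasets.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size != K - 1 or np.any(np.diff(alpha) <= 0):
        raise ValueError("alpha must be K-1 strictly increasing thresholds")
    if not 0 <= support_size <= p:
        raise ValueError("support_size must lie in [0, p]")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    shared = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, p))
    X = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio
    X = standardize(X)

    beta = np.zeros(p)
    signs = np.where(np.arange(support_size) % 2 == 0, 1.0, -1.0)
    beta[:support_size] = signs * effect
    support = tuple(range(support_size))

    eta = X @ beta
    y = None
    for _ in range(_MAX_NOISE_RETRIES):
        z = eta + rng.logistic(size=n)
        cand = np.digitize(z, alpha, right=True) + 1  # alpha_{k-1} < z <= alpha_k -> k
        if np.unique(cand).size == K:
            y = cand
            break
    if y is None:
        raise RuntimeError(
            f"could not cover all {K} categories in {_MAX_NOISE_RETRIES} noise draws; "
            "thresholds are too extreme for this n"
        )
    data = OrdinalDataset(
        X=X, y=y, K=K, feature_ids=tuple(f"feature_{j + 1}" for j in range(p))
    )
    truth = SimulationTruth(beta_true=beta, support=support, alpha_true=alpha, seed=seed)
    return data, truth


def score_selection(selected, truth: SimulationTruth, feature_ids=None) -> SelectionScore:
    """Score a selected feature set against the simulation truth.

    ``selected`` is a set of 0-based feature indices, or of feature-id
    strings when ``feature_ids`` is supplied.  FDR uses the
    max(|selected|, 1) denominator so an empty selection scores FDR 0.
    """
    support = set(truth.support)
    if not support:
        raise ValueError("sensitivity is undefined for an empty true support")
    if feature_ids is not None:
        index = {fid: j for j, fid in enumerate(feature_ids)}
        try:
            selected = {index[s] for s in selected}
        except KeyError as exc:
            raise ValueError(f"selected feature not in feature_ids: {exc}") from exc
    else:
        selected = set(int(s) for s in selected)
    tp = len(selected & support)
    fp = len(selected - support)
    return SelectionScore(
        sensitivity=tp / len(support),
        fdr=fp / max(len(selected), 1),
        n_selected=len(selected),
    )
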