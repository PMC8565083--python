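"""Multi-chain convergence diagnostics.

Implements the classical Gelman-Rubin potential scale reduction factor
(PSRF, R-hat): with m chains of length n, W the mean within-chain sample
variance and B the between-chain variance of the chain means (times n),

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

This is the non-split, non-rank-normalized estimator matching the original
diagnostic; a split variant is available behind a flag.  Values near 1
indicate the chains are sampling the same distribution; values slightly
below 1 are possible estimator noise and are reported as computed.

Binary inclusion-indicator chains make R-hat ill-behaved, so gamma draws are
excluded from the report by default and summarized by per-chain means
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConvergenceReport", "psrf", "convergence_report"]


def psrf(chain_draws: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor of one scalar parameter.

    Parameters
    ----------
    chain_draws : (m, n) array
        m >= 2 chains of n >= 10 draws each.
    split : bool
        If True, halve each chain first (split R-hat).
    """
    draws = np.asarray(chain_draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("chain_draws must be a (chain, iteration) array")
    m, n = draws.shape
    if m < 2:
        raise ValueError("psrf requires at least 2 chains")
    if n < 2:
        raise ValueError("psrf requires at least 2 iterations per chain")
    if split:
        half = n // 2
        draws = np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)
        m, n = draws.shape
    within = draws.var(axis=1, ddof=1)
    W = within.mean()
    means = draws.mean(axis=1)
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


@dataclass(frozen=True)
class ConvergenceReport:
    """PSRF per monitored scalar parameter plus the flagged subset."""

    psrf: dict[str, float]
    n_chains: int
    n_iter: int
    cutoff: float
    flagged: tuple[str, ...]
    gamma_chain_means: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "psrf": self.psrf,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "cutoff": self.cutoff,
            "flagged": list(self.flagged),
            "gamma_chain_means": self.gamma_chain_means,
        }


def convergence_report(
    samples,
    cutoff: float = 1.1,
    monitor: list[str] | None = None,
    split: bool = False,
) -> ConvergenceReport:
    """R-hat for every threshold alpha_k, the shrinkage rate lambda, and the
    coefficients beta_j (restricted to ``monitor`` feature ids if given).

    ``samples`` is a :class:`bayesord.samplers.PosteriorSamples`.
    """
    values: dict[str, float] = {}
    K1 = samples.alpha.shape[2]
    for k in range(K1):
        values[f"alpha_{k + 1}"] = psrf(samples.alpha[:, :, k], split=split)
    if samples.lam is not None:
        values["lambda"] = psrf(samples.lam, split=split)
    ids = list(samples.feature_ids)
    wanted = set(monitor) if monitor is not None else None
    for j, fid in enumerate(ids):
        if wanted is not None and fid not in wanted:
            continue
        values[f"beta[{fid}]"] = psrf(samples.beta[:, :, j], split=split)
    flagged = tuple(name for name, r in values.items() if r > cutoff)
    gamma_means: dict[str, list[float]] = {}
    if samples.gamma is not None:
        for j, fid in enumerate(ids):
            if wanted is not None and fid not in wanted:
                continue
            gamma_means[f"gamma[{fid}]"] = (
                samples.gamma[:, :, j].mean(axis=1).tolist()
            )
    return ConvergenceReport(
        psrf=values,
        n_chains=samples.alpha.shape[0],
        n_iter=samples.alpha.shape[1],
        cutoff=cutoff,
        flagged=flagged,
        gamma_chain_means=gamma_means,
    )
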