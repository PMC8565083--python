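"""Feature filtering and standardization applied before model fitting.

Two steps: keep only the most variable features, as judged by a quantile of
the per-feature standard deviations, then center and scale each surviving
column.  Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["FilterReport", "filter_by_sd_quantile", "standardize"]


@dataclass(frozen=True)
class FilterReport:
    """Record of an SD-quantile filter pass."""

    p_in: int
    p_out: int
    sd_threshold: float
    q: float
    kept_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kept_ids"] = list(self.kept_ids)
        return d


def _column_sds(X: np.ndarray) -> np.ndarray:
    return X.std(axis=0, ddof=1)


def filter_by_sd_quantile(
    X: np.ndarray, q: float, feature_ids: list[str] | None = None
) -> tuple[np.ndarray, FilterReport]:
    """Keep columns whose sample SD is at or above the q-quantile of all
    column SDs.

    The threshold is the linear-interpolation quantile of the SD vector.
    Columns strictly above the threshold are kept, and ties at the threshold
    are kept too, so a maximal-variance feature is never silently dropped
    (with identical SDs everywhere, every column survives any q).  Column
    order is preserved.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    p_in = X.shape[1]
    if feature_ids is None:
        feature_ids = [f"feature_{j + 1}" for j in range(p_in)]
    sds = _column_sds(X)
    threshold = float(np.quantile(sds, q))
    keep = sds >= threshold if q > 0 else np.ones(p_in, dtype=bool)
    kept_ids = tuple(fid for fid, k in zip(feature_ids, keep) if k)
    report = FilterReport(
        p_in=p_in,
        p_out=int(keep.sum()),
        sd_threshold=threshold,
        q=q,
        kept_ids=kept_ids,
    )
    return X[:, keep], report


def standardize(X: np.ndarray, feature_ids: list[str] | None = None) -> np.ndarray:
    """Center each column to mean 0 and scale to sample SD 1.

    Idempotent to numerical precision.  A constant column cannot be scaled
    and raises, naming the offending feature.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError("standardize needs at least 2 rows")
    sds = _column_sds(X)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        name = feature_ids[j] if feature_ids is not None else f"column {j}"
        raise ValueError(f"constant feature cannot be standardized: {name}")
    return (X - X.mean(axis=0)) / sds
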