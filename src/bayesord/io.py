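"""Delimited-text readers/writers and configuration parsing.

Feature matrices travel as CSV/TSV with a header row of feature IDs and a
first column of sample IDs; responses as a two-column file (sample ID,
ordinal label).  The label-to-category mapping is explicit: the caller
supplies the ordered level list (e.g. favorable < intermediate < adverse)
either in code or in the YAML/JSON config, because the response ordering is
domain knowledge the data file cannot carry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import OrdinalDataset, PriorSpec

__all__ = [
    "read_feature_matrix",
    "read_response",
    "load_dataset",
    "write_feature_matrix",
    "write_response",
    "prior_from_config",
]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Samples x features table; index = sample IDs, columns = feature IDs."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no feature columns found in {path}")
    return df.astype(float)


def read_response(path: str | Path, levels: list[str]) -> pd.Series:
    """Two-column (sample ID, label) file mapped to integer categories 1..K
    following the supplied level ordering."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] != 1:
        raise ValueError("response file must have exactly two columns")
    labels = df.iloc[:, 0].astype(str)
    mapping = {str(lev): k + 1 for k, lev in enumerate(levels)}
    unknown = set(labels) - set(mapping)
    if unknown:
        raise ValueError(f"response labels not in level ordering: {sorted(unknown)}")
    return labels.map(mapping).astype(int)


def load_dataset(
    x_path: str | Path, y_path: str | Path, levels: list[str]
) -> OrdinalDataset:
    """Join feature matrix and response on sample ID and build the dataset."""
    X = read_feature_matrix(x_path)
    y = read_response(y_path, levels)
    common = X.index.intersection(y.index)
    if len(common) == 0:
        raise ValueError("feature matrix and response share no sample IDs")
    X = X.loc[common]
    y = y.loc[common]
    return OrdinalDataset(
        X=X.to_numpy(),
        y=y.to_numpy(),
        K=len(levels),
        feature_ids=tuple(map(str, X.columns)),
    )


def write_feature_matrix(X: np.ndarray, feature_ids, path: str | Path) -> None:
    df = pd.DataFrame(
        X,
        index=[f"sample_{i + 1}" for i in range(X.shape[0])],
        columns=list(feature_ids),
    )
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def write_response(y: np.ndarray, levels: list[str], path: str | Path) -> None:
    labels = [levels[int(v) - 1] for v in y]
    df = pd.DataFrame(
        {"label": labels},
        index=[f"sample_{i + 1}" for i in range(len(y))],
    )
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def prior_from_config(path: str | Path) -> tuple[PriorSpec, list[str]]:
    """Read a YAML/JSON config holding the PriorSpec fields plus the ordered
    response ``levels`` list.  Returns (prior, levels)."""
    raw = yaml.safe_load(Path(path).read_text())
    levels = [str(v) for v in raw.pop("levels", [])]
    prior = PriorSpec(**raw)
    return prior, levels
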