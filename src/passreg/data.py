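"""Domain types, delimited-file I/O, and feature preprocessing operators.

A labeled table carries a binary outcome ``Y``, a scalar surrogate ``S`` and a
feature matrix ``X``; an unlabeled table carries only ``(S, X)``.  Files are
comma- or tab-delimited with a header row; the Y/S columns are located by
name and every remaining column is a feature, in file order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSet",
    "UnlabeledSet",
    "ModelCoefficients",
    "read_dataset",
    "write_dataset",
    "log1p_counts",
    "orthogonalize_features",
    "pooled_surrogate_data",
]


def _check_matrix(X, name="X"):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return X


@dataclass
class LabeledSet:
    """Subject-level (Y, S, X) table with Y binary."""

    Y: np.ndarray
    S: np.ndarray
    X: np.ndarray
    feature_names: List[str]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.X = _check_matrix(self.X)
        if not np.all(np.isin(self.Y, (0.0, 1.0))):
            raise ValueError("Y entries must be 0 or 1")
        n = self.X.shape[0]
        if self.Y.shape != (n,) or self.S.shape != (n,):
            raise ValueError("Y, S, X row counts disagree")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains missing or non-finite values")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one feature")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "LabeledSet":
        return LabeledSet(self.Y[idx], self.S[idx], self.X[idx], self.feature_names)


@dataclass
class UnlabeledSet:
    """Subject-level (S, X) table without outcome labels."""

    S: np.ndarray
    X: np.ndarray
    feature_names: List[str]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.X = _check_matrix(self.X)
        if self.S.shape != (self.X.shape[0],):
            raise ValueError("S and X row counts disagree")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains missing or non-finite values")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelCoefficients:
    """Intercept, surrogate coefficient and feature coefficients of a
    linear predictor zeta + gamma*S + X'beta."""

    zeta: float
    gamma: float
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise ValueError("beta must be a vector")

    def linear_predictor(self, S, X):
        S = np.asarray(S, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.beta.shape[0]:
            raise ValueError("feature dimension mismatch")
        return self.zeta + self.gamma * S + X @ self.beta

    def predict_proba(self, S, X):
        eta = self.linear_predictor(S, X)
        return 1.0 / (1.0 + np.exp(-eta))


def read_dataset(
    path: Union[str, Path],
    s_column: str,
    y_column: Optional[str] = None,
    sep: Optional[str] = None,
) -> Union[LabeledSet, UnlabeledSet]:
    """Read a delimited table into a LabeledSet (if ``y_column`` given) or an
    UnlabeledSet.  Delimiter is sniffed from the extension unless given."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if s_column not in df.columns:
        raise KeyError(f"surrogate column {s_column!r} not found in {path.name}")
    if df.isna().any().any():
        raise ValueError(f"{path.name} contains missing values")
    if y_column is not None:
        if y_column not in df.columns:
            raise KeyError(f"outcome column {y_column!r} not found in {path.name}")
        y = df[y_column].to_numpy(dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError(f"outcome column {y_column!r} is not binary 0/1")
        feats = [c for c in df.columns if c not in (y_column, s_column)]
        return LabeledSet(
            y, df[s_column].to_numpy(dtype=float),
            df[feats].to_numpy(dtype=float), feats,
        )
    feats = [c for c in df.columns if c != s_column]
    return UnlabeledSet(df[s_column].to_numpy(dtype=float), df[feats].to_numpy(dtype=float), feats)


def write_dataset(data: Union[LabeledSet, UnlabeledSet], path: Union[str, Path]) -> None:
    """Write a dataset as CSV/TSV with full float precision (round-trip safe)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = {}
    if isinstance(data, LabeledSet):
        cols["Y"] = data.Y
    cols["S"] = data.S
    for j, name in enumerate(data.feature_names):
        cols[name] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")


def log1p_counts(X) -> np.ndarray:
    """Elementwise log(1 + x) for nonnegative count-like data."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("log1p_counts requires nonnegative entries")
    return np.log1p(X)


def orthogonalize_features(X, u) -> np.ndarray:
    """Residualize every column of X on (intercept, u) by least squares.

    Returned columns have zero mean and zero sample correlation with ``u``.
    """
    X = _check_matrix(X)
    u = np.asarray(u, dtype=float)
    if u.shape != (X.shape[0],):
        raise ValueError("u must have one entry per row of X")
    uc = u - u.mean()
    ss = uc @ uc
    if ss == 0:
        raise ValueError("u is constant; cannot orthogonalize")
    Xc = X - X.mean(axis=0)
    coef = (uc @ Xc) / ss
    return Xc - np.outer(uc, coef)


def pooled_surrogate_data(labeled: LabeledSet, unlabeled: UnlabeledSet):
    """Stack (S, X) over the labeled and unlabeled sets (labeled rows first)."""
    if labeled.feature_names != unlabeled.feature_names:
        raise ValueError("labeled and unlabeled feature names disagree")
    S = np.concatenate([labeled.S, unlabeled.S])
    X = np.vstack([labeled.X, unlabeled.X])
    return S, X
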