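"""The tabular data container consumed by every fitter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """A design matrix with a response vector and variable names.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric design matrix, one row per sample.  Must be free of
        missing values.
    y : ndarray of shape (n,)
        Response vector; continuous for Gaussian models, 0/1 coded for
        binomial models.
    names : sequence of str, optional
        Unique variable labels; defaults to ``x1 .. xp``.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least two samples")
        if p < 1:
            raise ValueError("need at least one variable")
        if len(self.y) != n:
            raise ValueError(f"response length {len(self.y)} != {n} rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains missing or non-finite values")
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(p)]
        else:
            self.names = [str(s) for s in self.names]
        if len(self.names) != p:
            raise ValueError(f"{len(self.names)} names for {p} columns")
        if len(set(self.names)) != p:
            raise ValueError("variable names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str) -> "Dataset":
        """Split a dataframe into covariates and the named outcome column."""
        if outcome not in df.columns:
            raise KeyError(f"outcome column {outcome!r} not found")
        covars = df.drop(columns=[outcome])
        return cls(
            X=covars.to_numpy(dtype=float),
            y=df[outcome].to_numpy(dtype=float),
            names=list(covars.columns),
        )

    def to_dataframe(self, outcome: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df[outcome] = self.y
        return df

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row-subset view (copies), keeping names."""
        return Dataset(X=self.X[rows], y=self.y[rows], names=list(self.names))
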