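"""Shared data containers for analysis samples.

The package works on plain tabular data: a confounder matrix ``W``, a
binary exposure vector ``X`` and a continuous outcome ``Y``.  CSV files
use the column convention ``y, x, w1..wp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when an analysis sample violates the input contract."""


@dataclass
class ObservedData:
    """One analysis sample: confounders ``W`` (n x p), binary exposure
    ``X`` and continuous outcome ``Y`` (length n each).

    No missing values are permitted anywhere; the exposure must be coded
    0/1 with both levels present for estimation.
    """

    W: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    column_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.X = np.asarray(self.X, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.W.shape[0]
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise DataValidationError(
                f"length mismatch: W has {n} rows, X {self.X.shape[0]}, Y {self.Y.shape[0]}"
            )
        if not np.all(np.isfinite(self.W)) or not np.all(np.isfinite(self.Y)):
            raise DataValidationError("missing or non-finite values in W or Y")
        if not np.all(np.isin(self.X, (0.0, 1.0))):
            bad = np.unique(self.X[~np.isin(self.X, (0.0, 1.0))])
            raise DataValidationError(
                f"exposure must be coded 0/1; found values {bad[:5].tolist()}"
            )
        if not self.column_names:
            self.column_names = tuple(f"w{j + 1}" for j in range(self.W.shape[1]))

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    def subset(self, idx: np.ndarray) -> "ObservedData":
        return ObservedData(self.W[idx], self.X[idx], self.Y[idx], self.column_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.W, columns=list(self.column_names))
        df.insert(0, "x", self.X.astype(int))
        df.insert(0, "y", self.Y)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedData":
        """Build a sample from a ``y, x, w*`` data frame, enforcing the
        no-missing and binary-exposure contracts."""
        cols = [c.lower() for c in df.columns]
        frame = df.copy()
        frame.columns = cols
        if "y" not in cols or "x" not in cols:
            raise DataValidationError("CSV must contain 'y' and 'x' columns")
        if frame.isna().any().any():
            bad = [c for c in frame.columns if frame[c].isna().any()]
            raise DataValidationError(
                f"missing values present in columns {bad}; missing-data handling "
                "is out of scope — supply complete records"
            )
        wcols = [c for c in cols if c not in ("y", "x")]
        if not wcols:
            raise DataValidationError("no confounder columns found")
        x = frame["x"].to_numpy(dtype=float)
        if not np.all(np.isin(x, (0.0, 1.0))):
            raise DataValidationError(
                "exposure column 'x' must be coded 0/1; "
                f"found values {sorted(set(np.unique(x)) - {0.0, 1.0})[:5]}"
            )
        return cls(
            frame[wcols].to_numpy(dtype=float),
            x,
            frame["y"].to_numpy(dtype=float),
            tuple(wcols),
        )
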