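"""Count-data container shared by all models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CountDataset"]


@dataclass(frozen=True)
class CountDataset:
    """A cross-section of event counts with covariates.

    Attributes
    ----------
    y : ndarray of int
        Non-negative event counts, one per observation unit.
    X : ndarray, shape (N, p)
        Covariate matrix including the intercept column when the model has
        a free or fixed intercept.
    offset : ndarray or None
        Exposure term added to the linear predictor with coefficient fixed
        at 1 (e.g. log segment length), same length as y.
    names : tuple of str
        Covariate labels, one per column of X.
    """

    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray | None = None
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 1:
            raise ValueError("y must be 1-D")
        if not np.all(np.isfinite(y.astype(float))) or np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("y must be non-negative integers")
        y = y.astype(np.int64)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        offset = self.offset
        if offset is not None:
            offset = np.asarray(offset, dtype=float)
            if offset.shape != y.shape:
                raise ValueError("offset must match y in length")
            if not np.all(np.isfinite(offset)):
                raise ValueError("offset must be finite")
        names = tuple(self.names) if self.names else tuple(f"x{j}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("names must have one entry per column of X")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "names", names)

    @property
    def N(self) -> int:
        return self.y.size

    def linpred_offset(self) -> np.ndarray:
        """Offset vector, zeros when absent."""
        return self.offset if self.offset is not None else np.zeros(self.N)
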