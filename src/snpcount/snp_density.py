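"""The semi-nonparametric (SNP) heterogeneity density.

The density is a squared degree-K polynomial times the standard normal pdf,

    f(eps) = (sum_m a_m eps^m)^2 * phi(eps) / C(a),

normalized by C(a) = sum_m sum_n a_m a_n I(m+n), where I(n) is the n-th
moment of the standard normal.  With a_0 fixed at 1 (identification: (a) and
(-a) give the same density) the family nests the standard normal at K=0 and
approximates a broad class of continuous densities as K grows, including
skewed and multimodal shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .quadrature import QuadratureRule, hermite_rule

__all__ = [
    "SNPCoefficients",
    "normal_moment",
    "norm_constant",
    "snp_pdf",
    "snp_moment",
    "density_curve",
    "mean_exp",
]

_NORM_CONST = 1.0 / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=None)
def normal_moment(n: int) -> float:
    """n-th raw moment I(n) of the standard normal, by the recursion
    I(0)=1, I(1)=0, I(n)=(n-1)*I(n-2).

    Exact: odd moments are 0 and even moments are the double factorial
    (n-1)!!, returned as floats with integer values.
    """
    if not isinstance(n, (int, np.integer)) or n < 0:
        raise ValueError(f"moment order must be a non-negative integer, got {n!r}")
    if n == 0:
        return 1.0
    if n == 1:
        return 0.0
    return (n - 1) * normal_moment(n - 2)


@dataclass(frozen=True)
class SNPCoefficients:
    """Polynomial coefficients a_0..a_K with a_0 = 1 (identification)."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if a.ndim != 1 or a.size < 1:
            raise ValueError("coefficient vector must be 1-D and non-empty")
        if a[0] != 1.0:
            raise ValueError(f"a_0 must be fixed at 1 for identification, got {a[0]}")
        if not np.all(np.isfinite(a)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "a", a)

    @property
    def K(self) -> int:
        """Polynomial length (degree)."""
        return self.a.size - 1

    @classmethod
    def from_free(cls, free: Sequence[float]) -> "SNPCoefficients":
        """Build from the free coefficients a_1..a_K (a_0 prepended as 1)."""
        return cls(np.concatenate([[1.0], np.asarray(free, dtype=float)]))


def norm_constant(coef: SNPCoefficients) -> float:
    """Normalization C(a) = sum_m sum_n a_m a_n I(m+n).

    Strictly positive whenever a_0 = 1: C(a) is the second moment of the
    polynomial under phi, E[(sum a_m eps^m)^2] > 0 for a nonzero polynomial.
    """
    a = coef.a
    K = coef.K
    moments = np.array([normal_moment(m + n) for m in range(K + 1) for n in range(K + 1)])
    return float(a @ moments.reshape(K + 1, K + 1) @ a)


def snp_pdf(eps, coef: SNPCoefficients):
    """Density (sum_m a_m eps^m)^2 phi(eps) / C(a); vectorized over eps."""
    eps = np.asarray(eps, dtype=float)
    poly = np.polynomial.polynomial.polyval(eps, coef.a)
    phi = _NORM_CONST * np.exp(-0.5 * eps**2)
    out = poly**2 * phi / norm_constant(coef)
    return out if out.ndim else float(out)


def snp_moment(coef: SNPCoefficients, r: int) -> float:
    """E[eps^r] = sum_m sum_n a_m a_n I(m+n+r) / C(a), exact via the
    normal-moment recursion."""
    if not isinstance(r, (int, np.integer)) or r < 0:
        raise ValueError(f"moment order must be a non-negative integer, got {r!r}")
    a = coef.a
    K = coef.K
    num = sum(
        a[m] * a[n] * normal_moment(m + n + r) for m in range(K + 1) for n in range(K + 1)
    )
    return float(num / norm_constant(coef))


def mean_exp(coef: SNPCoefficients, rule: QuadratureRule | None = None) -> float:
    """E[exp(eps)] under the SNP density, by Gauss-Hermite quadrature.

    Approximate (the default 30-point rule is accurate to ~1e-8 for the K
    values used in practice); relevant when the intercept is freed, since
    the intercept and E[exp(eps)] are confounded in the Poisson mean.
    """
    if rule is None:
        rule = hermite_rule(30)
    return float(rule.weights @ (np.exp(rule.nodes) * snp_pdf(rule.nodes, coef)))


def density_curve(coef: SNPCoefficients, grid) -> np.ndarray:
    """Tabulate the density on a grid: structured (epsilon, density) array
    for CSV export / plotting."""
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid values must be finite")
    out = np.empty(grid.size, dtype=[("epsilon", float), ("density", float)])
    out["epsilon"] = grid
    out["density"] = snp_pdf(grid, coef)
    return out
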