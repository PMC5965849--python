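"""Gauss-Hermite quadrature in the modified-weight convention.

The marginal likelihood of a Poisson model with continuous heterogeneity
``eps`` is an integral of the form ``int g(eps) d eps`` where ``g`` already
contains a Gaussian factor (the standard-normal kernel of the heterogeneity
density).  Gauss-Hermite quadrature evaluates integrals against
``exp(-eps^2)``; folding that kernel back into the weights,

    w_tilde_j = w_j * exp(s_j**2),

turns the rule into a plain weighted sum ``sum_j w_tilde_j * g(s_j)`` that
can be applied to any integrand decaying at least like ``exp(-eps^2/2)``.
The modified weights are O(1) at every node (raw weights underflow beyond
|s| ~ 6), which is why they are the stored representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import roots_hermite

__all__ = ["QuadratureRule", "hermite_rule", "integrate"]


@dataclass(frozen=True)
class QuadratureRule:
    """An order-J Gauss-Hermite rule with modified weights.

    Attributes
    ----------
    nodes : ndarray
        Roots of the physicists' Hermite polynomial H_J, ascending.
    weights : ndarray
        Modified weights ``w_j * exp(nodes_j**2)``, all positive.
    order : int
        Number of supporting points J.
    """

    nodes: np.ndarray
    weights: np.ndarray
    order: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def hermite_rule(order: int) -> QuadratureRule:
    """Build the order-J Gauss-Hermite rule with modified weights.

    Nodes are the roots of the physicists' Hermite polynomial ``H_J`` and are
    *not* rescaled by sqrt(2): integrands are evaluated on the natural scale
    of the heterogeneity, whose density carries its own standard-normal
    factor.

    Parameters
    ----------
    order : int
        Number of supporting points, >= 1.  30 points give likelihood terms
        accurate to well below 1e-6 for the models in this package.

    Returns
    -------
    QuadratureRule
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ValueError(f"quadrature order must be a positive integer, got {order!r}")
    nodes, raw_weights = roots_hermite(order)
    return QuadratureRule(nodes=nodes, weights=raw_weights * np.exp(nodes**2), order=int(order))


def integrate(integrand: Callable[[np.ndarray], np.ndarray], rule: QuadratureRule) -> float:
    """Approximate ``int integrand(eps) d eps`` by the modified-weight sum.

    Exact for ``p(eps) * exp(-eps^2)`` with ``p`` a polynomial of degree
    <= 2*order - 1; accurate for integrands decaying at least like
    ``exp(-eps^2/2)``.

    Raises
    ------
    FloatingPointError
        If the integrand is non-finite at some node (index reported).
    """
    values = np.asarray(integrand(rule.nodes), dtype=float)
    if values.shape != rule.nodes.shape:
        values = np.broadcast_to(values, rule.nodes.shape)
    bad = ~np.isfinite(values)
    if bad.any():
        j = int(np.argmax(bad))
        raise FloatingPointError(
            f"integrand non-finite at quadrature node index {j} (s={rule.nodes[j]:.6g})"
        )
    return float(rule.weights @ values)
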