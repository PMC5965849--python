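"""Poisson regression with semi-nonparametric heterogeneity.

The marginal likelihood has no closed form: each observation's probability
is the integral of a Poisson pmf against the SNP density, evaluated by
Gauss-Hermite quadrature with modified weights,

    Pr(y_i) ~= sum_j w_tilde_j * Poisson(y_i | exp(x_i b + off_i + s_j))
                                * f_SNP(s_j; a),

and the sample log-likelihood is maximized over the free regression
coefficients and a_1..a_K (a_0 = 1).  Because the SNP family can absorb a
location shift, the intercept and E[eps] are not separately identified; the
default practice is to fix the intercept at the NB estimate and let the
polynomial place the heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.api import GLM, families
from statsmodels.tools.numdiff import approx_hess

from .data import CountDataset
from .quadrature import QuadratureRule, hermite_rule
from .snp_density import SNPCoefficients, mean_exp, norm_constant, snp_moment, snp_pdf

__all__ = ["SNPFit", "snp_loglik", "fit_snp", "heterogeneity_summary"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _per_obs_logprob(beta, coef: SNPCoefficients, data: CountDataset,
                     rule: QuadratureRule, eff_offset=None) -> np.ndarray:
    """Vector of ln Pr(y_i) under the quadrature approximation."""
    beta = np.asarray(beta, dtype=float)
    if beta.size != data.X.shape[1]:
        raise ValueError(f"beta has {beta.size} entries for {data.X.shape[1]} columns")
    if eff_offset is None:
        eff_offset = data.linpred_offset()
    lp = data.X @ beta + eff_offset
    s = rule.nodes
    y = data.y.astype(float)

    # log of w_tilde_j * f_SNP(s_j): polynomial may vanish at a node, which
    # contributes probability zero -> -inf is the correct log term.
    poly = np.polynomial.polynomial.polyval(s, coef.a)
    with np.errstate(divide="ignore"):
        log_density = (
            2.0 * np.log(np.abs(poly))
            - 0.5 * s**2 - _LOG_SQRT_2PI
            - np.log(norm_constant(coef))
        )
    log_wf = np.log(rule.weights) + log_density  # (J,)

    # Poisson log-kernel on the (N, J) grid, overflow -> -inf term.
    with np.errstate(over="ignore"):
        mu = np.exp(lp)[:, None] * np.exp(s)[None, :]
    terms = y[:, None] * (lp[:, None] + s[None, :]) - mu - gammaln(y + 1.0)[:, None]
    return logsumexp(terms + log_wf[None, :], axis=1)


def snp_loglik(beta, coef: SNPCoefficients, data: CountDataset,
               rule: QuadratureRule) -> float:
    """Sample log-likelihood sum_i ln Pr(y_i), log-sum-exp over nodes.

    Raises
    ------
    FloatingPointError
        If some observation's probability underflows to zero (its index is
        reported); typically a sign that beta is wildly off scale.
    """
    ll = _per_obs_logprob(beta, coef, data, rule)
    if not np.all(np.isfinite(ll)):
        i = int(np.argmax(~np.isfinite(ll)))
        raise FloatingPointError(f"zero marginal probability at observation {i}")
    return float(np.sum(ll))


@dataclass(frozen=True)
class SNPFit:
    """MLE result for the Poisson-SNP regression.

    ``beta`` covers every column of X; a fixed intercept appears at its
    fixed value with NaN standard error.  ``k`` counts free parameters only
    (free betas + K polynomial coefficients; a_0 and a fixed intercept are
    excluded).
    """

    beta: np.ndarray
    coef: SNPCoefficients
    se_beta: np.ndarray
    se_a: np.ndarray        # aligned with coef.a; NaN at a_0
    loglik: float
    K: int
    fixed_intercept: float | None
    k: int
    converged: bool
    names: tuple[str, ...]
    rule_order: int
    message: str = ""


def _intercept_column(data: CountDataset) -> int:
    for j in range(data.X.shape[1]):
        if np.all(data.X[:, j] == 1.0):
            return j
    raise ValueError("no constant column found; cannot fix the intercept")


def fit_snp(
    data: CountDataset,
    K: int,
    fixed_intercept: float | None = None,
    rule: QuadratureRule | None = None,
    start_a=None,
    start_beta=None,
    n_starts: int = 6,
    seed: int = 0,
) -> SNPFit:
    """Constrained MLE of the Poisson-SNP model.

    Maximizes the quadrature log-likelihood over the free coefficients and
    a_1..a_K.  The likelihood can be multimodal in ``a``, so optimization is
    multi-started: a_1..a_K = 0 (the lognormal-heterogeneity point), the
    user-supplied warm start if any, and seeded random perturbations; the
    best converged optimum wins.

    Parameters
    ----------
    K : int
        Polynomial length, >= 0 (K=0 is the Poisson-lognormal degenerate
        case with no free density parameters).
    fixed_intercept : float, optional
        Hold the constant column's coefficient at this value (usually the
        NB intercept estimate) and fold it into the offset.
    rule : QuadratureRule, optional
        Defaults to the 30-point rule; order >= 2K+2 is recommended.
    start_a : sequence, optional
        Warm start for a_1..a_K (shorter vectors are zero-padded).
    start_beta : sequence, optional
        Warm start for the free coefficients (free columns of X, in order);
        added as an extra start alongside the Poisson-GLM center.
    """
    if not isinstance(K, (int, np.integer)) or K < 0:
        raise ValueError(f"K must be a non-negative integer, got {K!r}")
    if rule is None:
        rule = hermite_rule(30)
    if K > 0 and norm_constant(SNPCoefficients.from_free(np.ones(K))) > 1e12:
        raise ValueError(f"K={K} is numerically unstable; use a smaller polynomial length")

    eff_offset = data.linpred_offset().copy()
    free_mask = np.ones(data.X.shape[1], dtype=bool)
    if fixed_intercept is not None:
        j0 = _intercept_column(data)
        free_mask[j0] = False
        eff_offset = eff_offset + fixed_intercept * data.X[:, j0]
    Xf = data.X[:, free_mask]
    n_beta = Xf.shape[1]
    sub = CountDataset(y=data.y, X=Xf, offset=eff_offset,
                       names=tuple(np.array(data.names)[free_mask]))

    # Poisson-GLM slopes are a robust center for every start.
    beta_start = np.asarray(
        GLM(data.y.astype(float), Xf, family=families.Poisson(), offset=eff_offset)
        .fit().params, dtype=float,
    )

    def negll(theta):
        coef = SNPCoefficients.from_free(theta[n_beta:])
        try:
            return -snp_loglik(theta[:n_beta], coef, sub, rule)
        except FloatingPointError:
            return np.inf

    rng = np.random.default_rng(seed)
    starts = [(beta_start, np.zeros(K))]
    warm = None
    if start_a is not None:
        warm = np.zeros(K)
        warm[: min(K, len(start_a))] = np.asarray(start_a, dtype=float)[:K]
        starts.append((beta_start, warm))
    if start_beta is not None:
        starts.append((np.asarray(start_beta, dtype=float),
                       warm if warm is not None else np.zeros(K)))
    while len(starts) < max(n_starts, 1):
        starts.append((beta_start, 0.1 * rng.standard_normal(K)))

    best = None
    for b0, a0 in starts:
        theta0 = np.concatenate([b0, a0])
        res = minimize(negll, theta0, method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    res = minimize(negll, best.x, method="BFGS",  # polish the winner
                   options={"gtol": 1e-7, "maxiter": 1000})
    if res.fun > best.fun:
        res = best

    # BFGS with finite-difference gradients often stops on "precision loss"
    # at the optimum; treat a stalled likelihood as converged.
    ll_change = abs(best.fun - res.fun)
    converged = bool(res.success or best.success or ll_change < 1e-8)
    message = str(res.message)
    if not (res.success or best.success) and ll_change < 1e-8:
        message = f"log-likelihood change {ll_change:.2e} < 1e-8 at final polish"

    theta = res.x
    coef = SNPCoefficients.from_free(theta[n_beta:])
    beta = np.full(data.X.shape[1], np.nan)
    beta[free_mask] = theta[:n_beta]
    if fixed_intercept is not None:
        beta[~free_mask] = fixed_intercept

    se_beta = np.full(data.X.shape[1], np.nan)
    se_a = np.full(K + 1, np.nan)
    try:
        H = approx_hess(theta, negll)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se_beta[free_mask] = np.sqrt(d[:n_beta])
            se_a[1:] = np.sqrt(d[n_beta:])
    except np.linalg.LinAlgError:
        pass

    return SNPFit(
        beta=beta,
        coef=coef,
        se_beta=se_beta,
        se_a=se_a,
        loglik=-float(res.fun),
        K=K,
        fixed_intercept=fixed_intercept,
        k=n_beta + K,
        converged=converged,
        names=data.names,
        rule_order=rule.order,
        message=message,
    )


def heterogeneity_summary(fit: SNPFit, span: float = 8.0, step: float = 1e-3) -> dict:
    """Describe the fitted heterogeneity density.

    Locates every local maximum of the SNP density on [-span, span] by grid
    scan plus bounded refinement, assigns each mode the probability mass of
    its basin (between the adjacent local minima), and reports E[eps]
    (exact, via normal moments) and E[exp(eps)] (30-point quadrature).

    Returns a dict with keys ``modes`` (list of {location, density, mass}),
    ``mean``, ``mean_exp``, ``curve`` (structured epsilon/density array).
    """
    coef = fit.coef
    grid = np.arange(-span, span + step / 2, step)
    dens = snp_pdf(grid, coef)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1

    modes = []
    for i in idx:
        res = minimize_scalar(
            lambda e: -snp_pdf(e, coef),
            bounds=(grid[i - 1], grid[i + 1]), method="bounded",
            options={"xatol": 1e-10},
        )
        modes.append((float(res.x), float(-res.fun)))
    modes.sort()

    # basin boundaries: density minima between consecutive modes
    bounds = [-np.inf]
    for (left, _), (right, _) in zip(modes[:-1], modes[1:]):
        seg = (grid >= left) & (grid <= right)
        bounds.append(float(grid[seg][np.argmin(dens[seg])]))
    bounds.append(np.inf)

    rule = hermite_rule(60)
    masses = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        inside = (rule.nodes > lo) & (rule.nodes <= hi)
        masses.append(float(rule.weights[inside] @ snp_pdf(rule.nodes[inside], coef)))

    return {
        "modes": [
            {"location": loc, "density": den, "mass": mass}
            for (loc, den), mass in zip(modes, masses)
        ],
        "mean": snp_moment(coef, 1),
        "mean_exp": mean_exp(coef),
        "curve": np.rec.fromarrays([grid, dens], names=["epsilon", "density"]),
    }
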