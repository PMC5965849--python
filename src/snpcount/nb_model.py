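"""Negative Binomial (Poisson-gamma) regression.

The NB model is a Poisson regression whose multiplicative heterogeneity
t = exp(eps) follows a Gamma(1/alpha^2, alpha^2) distribution with unit
mean; equivalently eps follows a log-gamma density.  Mixing the Poisson over
t gives a closed-form pmf (NB2: Var(y) = mu + alpha^2 mu^2), which is the
benchmark against which the flexible semi-nonparametric heterogeneity model
is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from statsmodels.api import GLM, families
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .data import CountDataset

__all__ = ["CountDataset", "NBFit", "nb_pmf", "nb_logpmf", "loggamma_pdf", "fit_nb"]


def nb_logpmf(y, lin_pred, alpha2: float):
    """Log of the closed-form NB pmf at count y given linear predictor.

    Uses r = alpha^2 e^lp / (alpha^2 e^lp + 1):
    ln Pr = lnGamma(1/a2+y) - lnGamma(1+y) - lnGamma(1/a2)
            + y ln r + (1/a2) ln(1-r),
    with ln r and ln(1-r) evaluated through log1p-style softplus terms so
    large |lp| cannot overflow.
    """
    if alpha2 <= 0:
        raise ValueError(f"alpha2 must be positive, got {alpha2}")
    y = np.asarray(y, dtype=float)
    lin_pred = np.asarray(lin_pred, dtype=float)
    inv = 1.0 / alpha2
    z = np.log(alpha2) + lin_pred          # ln(alpha2 * e^lp)
    log_r = z - np.logaddexp(0.0, z)       # ln r
    log_1mr = -np.logaddexp(0.0, z)        # ln(1 - r)
    return (
        gammaln(inv + y) - gammaln(1.0 + y) - gammaln(inv)
        + y * log_r + inv * log_1mr
    )


def nb_pmf(y, lin_pred, alpha2: float):
    """Closed-form NB pmf (probability scale)."""
    return np.exp(nb_logpmf(y, lin_pred, alpha2))


def loggamma_pdf(eps, alpha2: float):
    """Density of eps = ln t when t ~ Gamma(1/alpha^2, alpha^2), E[t] = 1.

    f(eps) = exp{(1/a2)[eps - ln a2] - e^(eps - ln a2)} / Gamma(1/a2);
    asymmetric (left-skewed) for every alpha2 > 0.
    """
    if alpha2 <= 0:
        raise ValueError(f"alpha2 must be positive, got {alpha2}")
    eps = np.asarray(eps, dtype=float)
    u = eps - np.log(alpha2)
    out = np.exp(u / alpha2 - np.exp(u) - gammaln(1.0 / alpha2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NBFit:
    """MLE result for the NB regression.

    ``beta`` covers every column of X (fixed coefficients included at their
    fixed value, with NaN standard error); ``k`` counts free parameters only
    (free betas + the dispersion).
    """

    beta: np.ndarray
    alpha2: float
    se: np.ndarray          # per-beta SEs, NaN for fixed coefficients
    se_alpha2: float
    loglik: float
    k: int
    converged: bool
    names: tuple[str, ...]
    message: str = ""

    @property
    def intercept(self) -> float:
        return float(self.beta[0])


def _split_fixed(data: CountDataset, fixed: dict[str, float] | None):
    """Move fixed-coefficient columns into the effective offset."""
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(data.names)
    if unknown:
        raise ValueError(f"fixed coefficients name unknown covariates: {sorted(unknown)}")
    free_mask = np.array([name not in fixed for name in data.names])
    offset = data.linpred_offset().copy()
    for j, name in enumerate(data.names):
        if name in fixed:
            offset += fixed[name] * data.X[:, j]
    return free_mask, offset, fixed


def _moment_alpha2(y, mu) -> float:
    """Method-of-moments dispersion from Pearson-type residuals."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return float(np.clip(num / den, 1e-4, 50.0))


def fit_nb(data: CountDataset, fixed: dict[str, float] | None = None) -> NBFit:
    """Maximum-likelihood NB fit with dispersion on the log scale.

    Starts from a Poisson GLM for the coefficients and a method-of-moments
    dispersion, then maximizes the exact NB log-likelihood by BFGS over
    (beta_free, ln alpha^2).  Standard errors come from the inverse observed
    information (numerical Hessian); the dispersion SE is delta-method
    transformed back to the alpha^2 scale.

    Parameters
    ----------
    fixed : dict, optional
        Covariate name -> coefficient value to hold fixed (the columns are
        folded into the offset; no SE is reported for them).
    """
    if np.all(data.y == 0):
        raise ValueError("response is all zeros; dispersion is not identifiable")
    free_mask, eff_offset, fixed = _split_fixed(data, fixed)
    Xf = data.X[:, free_mask]
    n_free = Xf.shape[1]
    if data.N <= n_free + 1:
        raise ValueError("need more observations than parameters")
    y = data.y.astype(float)

    pois = GLM(y, Xf, family=families.Poisson(), offset=eff_offset).fit()
    beta0 = np.asarray(pois.params, dtype=float)
    mu0 = np.exp(Xf @ beta0 + eff_offset)
    theta0 = np.concatenate([beta0, [np.log(_moment_alpha2(y, mu0))]])

    def negll(theta):
        lp = Xf @ theta[:n_free] + eff_offset
        a2 = np.exp(theta[-1])
        return -float(np.sum(nb_logpmf(y, lp, a2)))

    res = minimize(negll, theta0, method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:  # one polish from the current point
        res = minimize(negll, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000})

    # Newton polish: removes the BFGS stopping noise so equivalent datasets
    # (e.g. row permutations) land on the identical optimum.
    theta = res.x
    for _ in range(2):
        g = approx_fprime(theta, negll, centered=True)
        try:
            step = np.linalg.solve(approx_hess(theta, negll), g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or negll(theta - step) > negll(theta):
            break
        theta = theta - step
    alpha2 = float(np.exp(theta[-1]))
    beta = np.full(data.X.shape[1], np.nan)
    beta[free_mask] = theta[:n_free]
    for j, name in enumerate(data.names):
        if name in fixed:
            beta[j] = fixed[name]

    se = np.full(data.X.shape[1], np.nan)
    se_alpha2 = np.nan
    try:
        H = approx_hess(theta, negll)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se[free_mask] = np.sqrt(d[:n_free])
            se_alpha2 = float(np.sqrt(d[-1]) * alpha2)  # delta method for exp
    except np.linalg.LinAlgError:
        pass

    return NBFit(
        beta=beta,
        alpha2=alpha2,
        se=se,
        se_alpha2=se_alpha2,
        loglik=-float(negll(theta)),
        k=n_free + 1,
        converged=bool(res.success),
        names=data.names,
        message=str(res.message),
    )
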