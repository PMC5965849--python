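"""Goodness-of-fit measures, likelihood-ratio tests, and forward selection
of the polynomial length K."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data import CountDataset
from .nb_model import NBFit
from .quadrature import QuadratureRule
from .snp_model import SNPFit, fit_snp

__all__ = ["GOFReport", "LRTResult", "SelectionPath", "gof", "lrt", "select_K"]


@dataclass(frozen=True)
class GOFReport:
    """Deviance = -2 LL; AIC = 2(k - LL); BIC = ln(n) k - 2 LL."""

    loglik: float
    deviance: float
    aic: float
    bic: float
    n: int
    k: int


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested fits against chi-square(df)."""

    statistic: float
    df: int
    critical_value: float
    p_value: float
    significant: bool


def gof(fit: NBFit | SNPFit, n: int) -> GOFReport:
    """Goodness-of-fit report for a fitted model on n observations.

    ``k`` is the fit's free-parameter count: a fixed intercept, the fixed
    a_0, and offset terms carry no penalty.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ll = float(fit.loglik)
    if not np.isfinite(ll):
        raise ValueError("log-likelihood must be finite")
    k = int(fit.k)
    return GOFReport(
        loglik=ll,
        deviance=-2.0 * ll,
        aic=2.0 * (k - ll),
        bic=np.log(n) * k - 2.0 * ll,
        n=int(n),
        k=k,
    )


def lrt(fit_null, fit_alt, df: int, level: float = 0.05) -> LRTResult:
    """Likelihood-ratio test: 2*(LL_alt - LL_null) ~ chi-square(df).

    The fits must be nested (alternative extends the null); a tiny negative
    statistic from optimizer noise is clamped to zero, a substantively
    negative one is an error.
    """
    if not isinstance(df, (int, np.integer)) or df <= 0:
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    stat = 2.0 * (float(fit_alt.loglik) - float(fit_null.loglik))
    if stat < -1e-6:
        raise ValueError(
            f"alternative log-likelihood below the null ({stat/2:.6g}); fits are not nested "
            "or the alternative did not converge"
        )
    stat = max(stat, 0.0)
    crit = float(chi2.ppf(1.0 - level, df))
    return LRTResult(
        statistic=stat,
        df=int(df),
        critical_value=crit,
        p_value=float(chi2.sf(stat, df)),
        significant=stat > crit,
    )


@dataclass(frozen=True)
class SelectionPath:
    """Forward-selection trace: fits for K = 1..K_stop and the chosen K.

    ``steps`` holds the df=1 incremental tests between consecutive K;
    ``overall`` is the chosen-K-vs-K=1 test on df = K_chosen - 1 (the
    summary comparison conventionally reported), or None when K_chosen = 1.
    """

    fits: tuple[SNPFit, ...]
    chosen_K: int
    steps: tuple[LRTResult, ...]
    overall: LRTResult | None

    @property
    def chosen(self) -> SNPFit:
        return self.fits[self.chosen_K - 1]


def select_K(
    data: CountDataset,
    K_max: int,
    level: float = 0.05,
    fixed_intercept: float | None = None,
    rule: QuadratureRule | None = None,
    seed: int = 0,
) -> SelectionPath:
    """Grow the polynomial forward until the LRT stops improving.

    Fits K = 1, 2, ... with each fit warm-started from the previous optimum
    (which also enforces the nested-likelihood monotonicity), testing each
    added coefficient at df = 1; stops at the first non-significant
    increment or at K_max.  The chosen model is the last significant K.
    """
    if K_max < 1:
        raise ValueError(f"K_max must be >= 1, got {K_max}")
    fits: list[SNPFit] = []
    steps: list[LRTResult] = []
    chosen = 1
    prev = None
    for K in range(1, K_max + 1):
        try:
            fit = fit_snp(
                data, K, fixed_intercept=fixed_intercept, rule=rule,
                start_a=None if prev is None else prev.coef.a[1:],
                seed=seed + K,
            )
        except Exception as err:
            raise RuntimeError(f"SNP fit failed at K={K}") from err
        # warm-started nesting guarantees LL(K) >= LL(K-1) up to tolerance
        if prev is not None and fit.loglik < prev.loglik - 1e-4:
            fit = prev  # keep the better nested optimum; treat step as flat
        fits.append(fit)
        if prev is not None:
            step = lrt(prev, fit, df=1, level=level)
            steps.append(step)
            if not step.significant:
                break
            chosen = K
        prev = fit

    overall = None
    if chosen > 1:
        overall = lrt(fits[0], fits[chosen - 1], df=chosen - 1, level=level)
    return SelectionPath(
        fits=tuple(fits), chosen_K=chosen, steps=tuple(steps), overall=overall
    )
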