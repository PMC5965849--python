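"""Poisson-SNP model: quadrature likelihood vs adaptive oracles, MLE,
identification, heterogeneity diagnostics."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm, poisson

from snpcount import (
    CountDataset,
    SNPCoefficients,
    SimulationSpec,
    fit_nb,
    fit_snp,
    gen_dataset,
    heterogeneity_summary,
    snp_loglik,
    snp_pdf,
)
from snpcount.snp_model import SNPFit, _per_obs_logprob

# fitted degree-3 coefficients from the empirical crash-frequency model
A_EMPIRICAL3 = np.array([1.0, -0.3242, -0.1714, 0.0408])


def _oracle_prob(y, lp, coef):
    val, _ = quad(
        lambda e: poisson.pmf(y, np.exp(lp + e)) * snp_pdf(e, coef),
        -12, 12, epsabs=1e-13, limit=200,
    )
    return val


def test_poisson_lognormal_case_matches_adaptive_oracle(rule30):
    coef = SNPCoefficients(np.array([1.0]))
    X = np.ones((6, 1))
    for y, lp in [(0, 0.0), (1, 0.5), (3, 1.0), (5, 1.5), (0, -1.0), (4, 2.0)]:
        data = CountDataset(y=np.full(6, y), X=X, offset=np.full(6, lp))
        # beta = [0] on a ones column, lp carried by the offset
        got = _per_obs_logprob(np.zeros(1), coef, data, rule30)[0]
        assert abs(np.exp(got) - _oracle_prob(y, lp, coef)) < 1e-6


def test_zero_count_zero_predictor_closed_check(rule30):
    """ln Pr(0) = ln E[exp(-exp(eps))] under standard normal heterogeneity."""
    data = CountDataset(y=np.array([0]), X=np.ones((1, 1)))
    got = snp_loglik(np.zeros(1), SNPCoefficients(np.array([1.0])), data, rule30)
    oracle, _ = quad(lambda e: np.exp(-np.exp(e)) * norm.pdf(e), -12, 12, epsabs=1e-14)
    assert abs(got - np.log(oracle)) < 1e-10


def test_loglik_matches_oracle_for_higher_K(rule30, rng):
    # modest counts and fitted-scale coefficients (magnitude decaying with
    # the order, as every fitted vector in practice does): the regime where
    # the 30-point rule is numerically exact
    for _ in range(5):
        K = int(rng.integers(1, 6))
        coef = SNPCoefficients.from_free(rng.normal(0, 0.3 / (1 + np.arange(K))))
        y = int(rng.integers(0, 7))
        lp = float(rng.normal(0, 1))
        data = CountDataset(y=np.array([y]), X=np.array([[1.0]]), offset=np.array([lp]))
        got = snp_loglik(np.zeros(1), coef, data, rule30)
        assert abs(np.exp(got) - _oracle_prob(y, lp, coef)) < 1e-5


def test_offset_intercept_translation_invariance(rule30, loggamma_data):
    data, _ = loggamma_data
    coef = SNPCoefficients(A_EMPIRICAL3)
    beta = np.array([1.0, -0.3, 0.4])
    c = 0.7
    shifted = CountDataset(
        y=data.y, X=data.X, offset=np.full(data.N, c), names=data.names
    )
    ll = snp_loglik(beta, coef, data, rule30)
    ll_shifted = snp_loglik(beta - np.array([c, 0, 0]), coef, shifted, rule30)
    assert abs(ll - ll_shifted) < 1e-10


def test_30_vs_60_point_likelihood_agreement(rule30, rule60, loggamma_data):
    """Order-doubling stability on the modest-count terms of the benchmark
    sample (the rule's error grows with y; see the quadrature tests)."""
    data, _ = loggamma_data
    coef = SNPCoefficients(A_EMPIRICAL3)
    beta = np.array([1.0, -0.3, 0.4])
    l30 = _per_obs_logprob(beta, coef, data, rule30)
    l60 = _per_obs_logprob(beta, coef, data, rule60)
    modest = data.y <= 5
    assert modest.sum() > 500
    assert np.max(np.abs(np.exp(l30[modest]) - np.exp(l60[modest]))) < 1e-6


def test_fit_recovers_normal_heterogeneity_slopes():
    """Normal-heterogeneity design, K=2: slopes within 3 SEs; fitted density
    close to N(0, 0.8^2) in sup norm."""
    data, _ = gen_dataset(SimulationSpec.normal(sigma=0.8, n=500, seed=2))
    fit = fit_snp(data, K=2, seed=0)
    assert fit.converged
    slopes = fit.beta[1:]
    np.testing.assert_array_less(np.abs(slopes - [-0.3, 0.4]), 3 * fit.se_beta[1:])
    # recenter: the free intercept absorbs the location of eps
    grid = np.linspace(-3, 3, 301)
    shift = grid[np.argmax(snp_pdf(grid, fit.coef))]
    sup = np.max(np.abs(snp_pdf(grid + shift, fit.coef) - norm.pdf(grid, 0, 0.8)))
    assert sup < 0.05


def test_nested_fits_monotone_in_K():
    data, _ = gen_dataset(SimulationSpec.normal(sigma=0.8, n=300, seed=4))
    f1 = fit_snp(data, K=1, seed=0)
    f2 = fit_snp(data, K=2, start_a=f1.coef.a[1:], seed=0)
    assert f2.loglik >= f1.loglik - 1e-4
    # and restarting K=1 from the K=2 optimum cannot beat K=2
    f1b = fit_snp(data, K=1, start_a=f2.coef.a[1:2], seed=0)
    assert f2.loglik >= f1b.loglik - 1e-4


def test_fixed_vs_free_intercept_identification(loggamma_data, loggamma_nb_fit):
    data, _ = loggamma_data
    fixed = fit_snp(data, K=2, fixed_intercept=loggamma_nb_fit.intercept, seed=0)
    # the free model nests the fixed one; warm-start from its optimum
    free = fit_snp(data, K=2, start_a=fixed.coef.a[1:], start_beta=fixed.beta, seed=0)
    assert fixed.fixed_intercept == pytest.approx(loggamma_nb_fit.intercept)
    assert np.isnan(fixed.se_beta[0])
    assert free.loglik >= fixed.loglik - 1e-4
    assert free.k == fixed.k + 1


def test_fit_rejects_bad_K(loggamma_data):
    with pytest.raises(ValueError):
        fit_snp(loggamma_data[0], K=-1)


def _summary_fit(a):
    coef = SNPCoefficients(np.asarray(a))
    return SNPFit(
        beta=np.zeros(1), coef=coef, se_beta=np.full(1, np.nan),
        se_a=np.full(coef.K + 1, np.nan), loglik=0.0, K=coef.K,
        fixed_intercept=None, k=coef.K, converged=True, names=("intercept",),
        rule_order=30,
    )


def test_summary_standard_normal_single_mode():
    summary = heterogeneity_summary(_summary_fit([1.0]))
    assert len(summary["modes"]) == 1
    assert abs(summary["modes"][0]["location"]) < 1e-6
    assert summary["modes"][0]["mass"] == pytest.approx(1.0, abs=1e-8)


def test_summary_empirical_coefficients_trimodal():
    """The fitted empirical heterogeneity shows three visible modes, the
    dominant one at negative epsilon carrying almost all the mass.

    (The squared cubic admits a fourth stationary maximum in the far right
    tail at density ~1e-7 — far below visibility; the summary reports every
    true local maximum, so visibility is a density filter here.)
    """
    summary = heterogeneity_summary(_summary_fit(A_EMPIRICAL3))
    visible = [m for m in summary["modes"] if m["density"] > 1e-4]
    assert len(visible) == 3
    major = max(summary["modes"], key=lambda m: m["mass"])
    assert major["location"] < 0
    assert major["mass"] > 0.9
    assert abs(sum(m["mass"] for m in summary["modes"]) - 1.0) < 1e-6


def test_summary_modes_match_grid_argmax_oracle(rng):
    for _ in range(5):
        coef = SNPCoefficients.from_free(rng.normal(0, 0.5, size=4))
        summary = heterogeneity_summary(_summary_fit(coef.a))
        grid = np.arange(-8.0, 8.0, 1e-4)
        dens = snp_pdf(grid, coef)
        best = grid[np.argmax(dens)]
        top = max(summary["modes"], key=lambda m: m["density"])
        assert abs(top["location"] - best) < 1e-3
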