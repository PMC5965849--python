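# Methods

## Model

`snpcount` estimates mixed-Poisson regressions
`y_i | eps_i ~ Poisson(exp(x_i' beta + offset_i + eps_i))` under two
heterogeneity laws:

* **NB / log-gamma.** `t = exp(eps) ~ Gamma(1/alpha^2, alpha^2)`, so
  `E[t] = 1`, `SD[t] = alpha`, and the marginal pmf is the closed-form NB2
  with `Var(y) = mu + alpha^2 mu^2`. The implied density of `eps` itself is
  the (left-skewed, unimodal) log-gamma.
* **SNP.** `f(eps) = P(eps)^2 phi(eps) / C(a)` with
  `P(eps) = sum_{m<=K} a_m eps^m`, `a_0 = 1`. The normalizer
  `C(a) = sum_{m,n} a_m a_n I(m+n)` uses the standard-normal moment
  recursion `I(n) = (n-1) I(n-2)`, which is exact in integer arithmetic;
  all SNP moments are computed the same way rather than by quadrature.

Squaring the polynomial keeps the density non-negative with no shape
constraints on `a`; the cost is a sign ambiguity (`a` and `-a` give the same
density), resolved by pinning `a_0 = +1`. At K = 0 the family is the
standard normal (a Poisson-lognormal model); growing K adds skewness and
up to K extra modes.

## Quadrature

The SNP marginal probability is an integral of a Poisson kernel against
`f(eps)`. It is evaluated with an order-J Gauss–Hermite rule in the
*modified-weight* convention: nodes are the roots of the physicists'
Hermite polynomial `H_J` (computed by the Golub–Welsch eigenvalue routine
in `scipy.special.roots_hermite`, never hard-coded) and the stored weights
are `w_j exp(s_j^2)`, so the likelihood is the plain weighted sum
`sum_j w~_j Poisson(y | exp(xb + s_j)) f(s_j)`. Raw Gauss–Hermite weights
underflow beyond `|s| ~ 6`; the modified weights are O(1) at every node.
Nodes are deliberately **not** rescaled by sqrt(2): the integrand carries
its own `phi` factor, and the default order of 30 resolves it directly.

Accuracy is count-dependent. The Poisson kernel in `eps` peaks near
`ln y - xb` with width `~1/sqrt(y)`, so for modest counts (y ≤ 5–10) the
30-point rule agrees with adaptive integration to better than 1e-6 per
observation, while at y ~ 50 the per-term error reaches ~4e-4 (the peak is
narrower than the node spacing). The 30-point sum is nevertheless the
estimator this package defines — higher orders are available via the
`quadrature order` setting, and the test suite pins the oracle-equivalence
checks to the modest-count regime where the rule is numerically exact.
Similarly, the modified-weight rule is not exact for `phi`-weighted
polynomials; SNP moments therefore come from the exact `I(n)` table, with a
60-point rule sufficing to cross-check them to ~1e-12.

## Estimation

* **NB.** Started from a Poisson GLM for `beta` and a Pearson-residual
  method-of-moments dispersion; maximized by BFGS over
  `(beta, ln alpha^2)` — the log parameterization keeps `alpha^2 > 0`
  without box constraints — and finished with up to two Newton steps using
  numerical derivatives, which removes optimizer stopping noise so that
  equivalent datasets (e.g. row permutations) produce bit-comparable
  optima. Standard errors come from the inverse observed information
  (numerical Hessian); the dispersion SE is delta-method transformed back
  to the `alpha^2` scale.
* **SNP.** The likelihood can be multimodal in `a`, so optimization is
  multi-started: `a = 0` (the lognormal point), an optional warm start, and
  seeded perturbations of scale 0.1 (six starts by default); slopes always
  start at the Poisson GLM estimates. BFGS with gradient tolerance 1e-6,
  then a polish pass at 1e-7; a fit is reported converged when the
  optimizer succeeds or the final polish moves the log-likelihood by less
  than 1e-8. `k` counts free parameters only — a fixed intercept and `a_0`
  carry no AIC/BIC penalty.
* **Identification.** A flexible `f(eps)` absorbs location, so the
  intercept and `E[eps]` are jointly unidentified. Default practice for
  NB-vs-SNP comparisons: fix the SNP intercept at the NB estimate. When
  the design has no intercept (the normal/bimodal/trimodal benchmark
  experiments), the SNP density itself carries location and scale — this
  matters: bolting a fixed intercept onto the no-intercept normal design
  absorbs most of what the quadratic coefficient would explain and stalls
  the selection path at K = 1. The `free-intercept` option reports
  `E[eps]` and `E[exp(eps)]` (the latter by 30-point quadrature,
  documented as approximate) so users can re-center.

## Order selection

`select_K` grows K forward from 1, warm-starting each fit from the previous
optimum (which also enforces nested-likelihood monotonicity), and stops at
the first increment whose df = 1 likelihood-ratio test is non-significant
(default level 0.05). Because reported comparisons conventionally contrast
the chosen K against K = 1 on df = K − 1, that summary statistic is emitted
alongside the stepwise path. On data with no heterogeneity the path hugs
the plain-Poisson likelihood from below; note the family approaches its
degenerate zero-heterogeneity limit only slowly in K, so with moderate
means the increments can remain significant for many steps — the flat-path,
stop-early behavior is characteristic of rare-event (low-mean) data.

## Synthetic designs

`simulate` reproduces four benchmark conditions, all with
`x1, x2 ~ iid U(0, 5)` and `y ~ Poisson(exp(x beta + eps))`:

| design | eps | defaults |
|---|---|---|
| loggamma | `ln t`, `t ~ Gamma(1/alpha^2, alpha^2)` | `alpha^2 = 0.8`, `beta = (1, -0.3, 0.4)`, n = 1000 |
| normal | `N(mu, sigma^2)` | `mu = 0`, `sigma = 0.8`, no intercept, n = 1000 |
| bimodal | `3·1(u1>0.4) + 1.5 u2 + 0.5 eta - 2.5` | no intercept, n = 500 |
| trimodal | `3·1(u1>0.8) - 3·1(u2>0.7) + 2 u3 + 0.5 eta - 1.0` | no intercept, n = 500 |

(`u ~ U(0,1)`, `eta ~ N(0,1)`.) One root seed is split into covariate /
heterogeneity / count streams, so the same seed yields comparable designs
across heterogeneity kinds, and generation is bit-reproducible. The
generator emulates the benchmark conditions only: covariates are
independent and uniform, exposure is constant, and there is no spatial or
temporal structure, so passing tests demonstrate correct estimation under
the stated designs — not robustness to correlated covariates, varying
exposure, or misspecified mean functions found in real crash data.

Where simulations are replicated for distributional checks, the suite uses
reduced problem sizes chosen to keep Monte-Carlo error informative (60
replicates at n = 300 for NB bias, 100 replicates at n = 1000 for
dispersion coverage, single samples at the design's native n elsewhere).

## KDE

`kde_density` implements the fixed-bandwidth Gaussian estimator
`f(e) = (1/n) sum_j phi((e - eps_j)/h)/h` on an explicit grid (default −6.0
to 6.0 by 0.1), with h = 0.3 suiting the bimodal design at n ~ 500 and
h = 0.4 giving smoother trimodal curves. No automatic bandwidth selection
is offered — the estimator is a visualization aid where h is part of the
display choice.

## Numerical notes and limitations

* NB pmf and SNP likelihood are computed in log space (log-gamma function
  for factorials, softplus forms for the NB success probability,
  log-sum-exp over quadrature nodes); a polynomial root at a node
  contributes a legitimate `-inf` log term.
* `heterogeneity_summary` locates *all* stationary maxima of the fitted
  density by grid scan (step 1e-3 on [−8, 8]) plus bounded refinement and
  reports each mode's basin mass; a squared degree-K polynomial can have
  up to K + 1 maxima, some at invisibly small densities (e.g. ~1e-7 in the
  far tail of a cubic fit), so consumers should filter by density or mass.
* Very large K makes `C(a)` ill-conditioned; `fit_snp` refuses K whose
  normalizer blows past 1e12 and suggests a smaller polynomial.
* SPSS ingestion (`convert`) requires the optional `pyreadstat` backend;
  the canonical interchange format is headered CSV, re-read with
  `float_precision="round_trip"` so export/reload round-trips are
  bit-exact.
* Standard errors are observed-information estimates; no sandwich or
  bootstrap corrections are provided.
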