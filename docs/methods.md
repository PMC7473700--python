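# Methods

## Model

`sfapanel` estimates a log production frontier for hospital-year panel
data with a composed error:

    y_it = x_it' β + v_it − u_i,        v_it ~ N(0, σv²) iid,
    u_i ~ N(μ, σu²) truncated at zero,  u_i ⟂ v_it,

where `y_it` is the log of annual output and `x_it` collects the chosen
regressor expansion of the four inputs (active beds, doctors, nurses,
non-medical staff). `u_i ≥ 0` is the unit's *time-invariant* technical
inefficiency; `v_it` is ordinary noise. Three functional forms are
supported:

* **Cobb–Douglas** — response `ln(inpatients + outpatients)`, the four
  ln-inputs; input elasticities constant by construction (4 slopes).
* **Translog** — adds the six pairwise interactions `ln x_j · ln x_h`
  and four own-squared terms with an explicit ½ factor, so the reported
  `β_jj` follow the `β_jj · 0.5 (ln x_j)²` convention (14 slopes).
* **Multi-output distance** — response `ln(outpatients)`, translog term
  set plus `ln Y*`, its four interactions with the ln-inputs and
  `0.5 (ln Y*)²`, where `Y* = outpatients / inpatients` is the output
  mix (20 slopes). This form is implemented exactly as specified even
  though `Y*` contains the response, so it carries simultaneity by
  construction; it is retained for comparability, not recommended as a
  structural model.

## Likelihood and its evaluation

Because `u_i` is shared across a unit's years, observations are
dependent within units; the marginal likelihood integrates `u_i` out
per unit and is available in closed form (the classic time-invariant
panel frontier result). With precisions `a = 1/σu²`, `b = 1/σv²`,
`A_i = T_i b + a` and residual sums `S1_i = Σ_t e_it`, `S2_i = Σ_t e_it²`,
the posterior of `u_i` given the unit's residuals is `N(μ*_i, 1/A_i)`
truncated at zero, with `μ*_i = (aμ − b S1_i)/A_i`. Numerical choices:

* all normal CDFs are evaluated via `log_ndtr` (log space);
* the quadratic form in the unit log-likelihood is algebraically
  rearranged so no large-term cancellation occurs as γ → 0 or γ → 1;
* at `σu² = 0` the likelihood degenerates to the pooled Gaussian
  (exactly, with `u ≡ max(μ, 0)`).

The closed form is verified in the tests against peak-aware adaptive
quadrature of the defining integral to 1e−6 per unit over a grid of
γ ∈ {0.05, 0.5, 0.95}, μ ∈ {−0.1, 0, 0.1}, T ∈ {1, 3, 6}.

The analytic gradient in (β, σu², σv², μ) is implemented and checked
against central differences; the optimizer receives it through the
chain rule in unconstrained coordinates (β, ln σ², logit γ, μ) with
γ = σu²/σ², σ² = σu² + σv².

## Optimization

Starting values are corrected-OLS style: OLS slopes, σ² from the OLS
residual variance, γ = 0.5, μ = 0. The driver runs L-BFGS-B from the
deterministic start plus four jittered restarts (fixed jitter seed) and
keeps the best finite optimum; composed-error likelihoods can be
multi-modal near the γ boundary. Internally the regressor block is
QR-orthonormalized (`X = QR`, optimize over `α = Rβ`): translog and
distance designs are severely collinear, and the reparameterization —
which leaves `Xβ = Qα` and hence the likelihood unchanged — turns a
crawling ill-conditioned search into a well-conditioned one. Estimates
and the covariance are mapped back through `R⁻¹`.

Standard errors come from the inverse observed information (central
finite-difference Hessian at the optimum in the unconstrained
coordinates), with the delta method for σu², σv², σ² and γ. A Wald
chi-square for joint slope significance and the log-likelihood complete
the conventional fit report. γ pinned at its transformed bound is
recorded as a warning; non-convergence is returned explicitly
(`converged=False`), and efficiency scoring refuses such fits. Data with
exactly zero OLS residual variance are treated as the noise-free limit:
the frontier is an exact linear solve.

## Efficiency scores

The Battese–Coelli point score is the posterior mean
`TE_i = E[exp(−u_i) | e_i1 … e_iT_i]`, computed from the truncated-
normal posterior in log space and verified against quadrature to 1e−6.
Scores are strictly in (0, 1]; values above 1 by less than 1e−12 are
clipped to 1, anything larger raises an internal-consistency error.
Because the model is time-invariant there is one score per unit; it is
broadcast to the unit's years for reporting and period summaries (mean,
sample sd, t-interval on the mean of unit-year scores; the CI
construction is a package convention). Year-varying efficiency can only
arise from refitting on year windows, which the pipeline supports as a
recipe but does not present as a separate estimator.

## Model comparison

Nested forms (Cobb–Douglas ⊂ translog, df = 10: six interactions plus
four half-squares) are compared with the likelihood-ratio statistic
`2(lnL_full − lnL_restricted)` against χ²(10). The mixed chi-square
boundary correction matters only when γ itself is tested, which is not
the comparison made here. A paired t-test (matched by unit-year)
compares efficiency series between specifications.

## Elasticities and returns to scale

The elasticity of output with respect to input j at a point given in
ln-levels is `e_j = β_j + Σ_{h≠j} β_jh ln x_h + β_jj ln x_j` (the
half-square convention makes `β_jj` enter once); for the distance form
the `Y*` interaction adds `β_{jY*} ln Y*`. The default evaluation point
is the sample mean of ln-levels (geometric mean of levels) — the point
at which translog first-order coefficients are interpretable — and is
always reported. The scale elasticity is the sum over inputs; returns
to scale classify against 1 with tolerance 1e−9 on exact arithmetic.
Elasticities are checked against central finite differences of the
fitted ln-output (step 1e−5, tolerance 1e−6).

## Fiscal space

Savings from closing an efficiency gap are
`Rev = (eff_target − eff_baseline) × G` with G the fiscal-year hospital
services budget (MUR million). Report cells round half-up to the
nearest million (percent-of-GGHE cells to one decimal); unrounded
values are retained. GGHE levels are user-supplied configuration. A
target below baseline is a flagged "disinvestment scenario", not an
error. Currency conversion is out of scope.

## Synthetic data

The generator reproduces the study design the pipeline targets: five
regional hospitals observed 2001–2006 plus one combined pseudo-unit
("ALL") over 2007–2017 — 41 records. Defaults are the study conditions:

* input levels drawn log-uniformly within the published descriptive
  min/max ranges (log-uniform guarantees positivity without truncation
  artifacts). All units share one (combined) input scale, mirroring how
  the emulated study evidently pooled its 41 observations; this scale
  mix is flagged in the ground-truth metadata. The published
  descriptive table is treated as approximate calibration only (it
  contains internal inconsistencies, e.g. an average-length-of-stay sd
  larger than its maximum);
* Cobb–Douglas slope truth at the published point estimates
  (0.232, 0.618, 0.165, 0.228); the intercept (5.13) is calibrated so
  mean ln-inputs map to the published mean total output net of mean
  inefficiency;
* σu² = 0.018, σv² = 0.004, μ = 0.045 (the published Cobb–Douglas
  variance row);
* total output split into outpatients/inpatients by the published
  output mix (outpatient share 0.886), deterministically by default,
  with optional logit-normal jitter;
* counts rounded to integers ≥ 1 by default; `integerize=False`
  supports exact noise-free checks.

`benchmark_config(n_units, n_years, seed)` keeps the error-scale truth
but widens the input ranges to roughly a decade per input and drops the
combined unit. This is the configuration for estimator benchmarking:
with the narrow study ranges the translog second-order columns are
numerically unidentifiable, so recovery and calibration experiments
need the wider spread. Problem sizes used by the packaged checks: 200
units × 6 years for parameter recovery (20 seeds), 80 units × 6 years
for the 500-replicate null calibration of the LR test.

What the generator does **not** emulate: case-mix/severity, quality of
care, length-of-stay heterogeneity, input trends over time, or
correlation between inputs. Passing tests therefore demonstrate that
the estimator stack recovers the truth of this data-generating process,
not that the published coefficient table would be reproduced from the
(undeposited) real panel.

## Known limitations

* The multi-output distance form inherits the printed specification's
  endogenous `Y*` regressors; its estimates are descriptive.
* (σu², μ) are weakly identified along a ridge when γ is small or the
  panel is short; standard errors are correspondingly large, and the
  reported observed-information SEs should be read with that in mind.
* The time-varying inefficiency (decay) model, heteroscedastic
  inefficiency, Bayesian estimation, cost frontiers, DEA, and
  information-criteria model selection are out of scope.
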