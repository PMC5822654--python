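# Methods

## The model

The analysis targets cross-sectional cohorts of primary-school children
(ages 8–9) with accelerometer-measured activity and sociometric friend
nominations. For each sex stratum we form the directed nomination graph
within schools and its weight matrix `W`: entry (i, j) = 1 iff child i
nominated child j, rows divided by their sums so every non-zero row sums to
one. `W y` is then each child's friends'-average outcome. The network
autocorrelation (spatial lag) model is

    y = ρ W y + X β + ε,   ε ~ N(0, σ² I),

with `y` mean daily MVPA or sedentary minutes (centred within stratum in
the pipeline; the intercept is retained) and `X` an intercept plus IMD
deprivation score, BMI z-score and the 0–12 activity participation score.
ρ measures outcome dependence transmitted along friendship ties. The model
assumes a correctly observed network (nominations capped at four,
within-school, in-study only), homogeneous ρ within stratum, and Gaussian
errors; it does not model tie formation.

## Estimation

The Gaussian log-likelihood is maximised by concentrating β and σ²:

    l_p(ρ) = −(n/2)·log σ̂²(ρ) + Σᵢ log|1 − ρλᵢ| + const,

with σ̂²(ρ) = RSS(ρ)/n from regressing (I − ρW)y on X, and λᵢ the
eigenvalues of W. W is directed, so eigenvalues are complex and the
Jacobian term uses complex moduli; because ties never cross schools, W is
block-diagonal and the eigenvalues are computed once per school block and
concatenated (exact, and much cheaper than the full matrix). ρ̂ is found by
bounded Brent search (tolerance 1e−8) over the feasible interval — the
reciprocals of the extreme real eigenvalues intersected with (−0.999,
0.999) — and a boundary solution is reported as non-converged rather than
returned silently. The asymptotic covariance of (ρ, β, σ²) is the negative
inverse of a central-difference Hessian of the full log-likelihood at the
optimum (relative step 1e−4).

The baseline comparator is OLS with school-cluster-robust (sandwich)
standard errors, small-sample factor G/(G−1)·(n−1)/(n−k), fitted through
statsmodels. AIC = 2k − 2·loglik counts intercept, slopes, σ² and (lag
model only) ρ, so with ρ fixed at 0 the lag model reproduces the OLS fit
exactly and its AIC is exactly 2 higher.

## Moran diagnostics

Moran's I over `W` is computed for raw outcomes and model residuals.
Children whose weight row is all zero are excluded from n, S₀, the mean and
the denominator. Inference defaults to a one-sided permutation test, p =
(1 + #{I_perm ≥ I_obs})/(n_perm + 1) with 999 permutations — the analytic
normal approximation under randomisation is available as an option, and
neither is claimed to reproduce any particular reported p-value, since the
original computation is not specified. The Moran scatter (centred value vs
lag) has least-squares slope equal to I for full-row row-standardised W.

## Impacts

With M = (I − ρ̂W)⁻¹, covariate k's direct impact is β̂ₖ·mean(diag M), the
total is β̂ₖ·mean of M's row sums, and the indirect ("spillover") impact is
their difference — the standard averaged summary of effects that propagate
through the network; for row-stochastic full-row W, total = β̂ₖ/(1 − ρ̂)
exactly. CIs are percentile intervals from 200 draws of (ρ, β) from the
multivariate normal at the estimates with the fit's covariance; draws with
infeasible ρ are discarded and counted (an error beyond 50%). Zero-weight
rows contribute their M row (unit diagonal) to the averages as-is.

## Multiple imputation

Missing covariates, items and outcomes are imputed by chained equations
("regression switching"): per completed dataset, missing cells are
initialised from observed marginals, then each variable in a fixed order
(covariates, items, outcomes) is imputed from a Bayesian normal-linear
regression on all other modelled variables plus school indicators —
posterior draws of σ² (scaled inverse-χ²) and β propagate parameter
uncertainty, with residual noise added. Ordinal items are rounded and
bounded to 0–3; predictive-mean matching is available as an option. The
activity participation score is imputed passively (recomputed as the item
sum in every dataset, never imputed directly). Imputation runs separately
per sex; defaults are m = 20 datasets and 20 cycles. Downstream fits are
pooled by Rubin's rules — q̄ = mean, T = W̄ + (1 + 1/m)B, Rubin
small-sample df — applied to the full (ρ, β) vector; ρ is pooled like a
coefficient, a choice we document rather than a reproduction of any
specific reported rule. Pooled impacts use the pooled estimates with the
pooled total covariance. Nominations are never imputed, so the network is
fixed across imputations.

## Accelerometry rules

Counts arrive in 10-s epochs. Non-wear is any maximal span running from a
zero epoch to a zero epoch, containing no nonzero run longer than 2
consecutive minutes, and spanning ≥60 minutes in total; the whole span,
interruptions included, is excluded. The consecutive-interruption reading
(rather than cumulative) follows the common Troiano-style convention; the
original processing software's exact rule is not public, so the thresholds
and convention are configurable. Cut points default to the child
calibration values (sedentary ≤100 cpm, moderate ≥2296 cpm), rescaled to
10-s epochs by /6 with ceilings floored and floors ceiled, class intervals
closed at both thresholds. A valid day has ≥500 worn minutes; children
with <3 valid days get missing summaries destined for imputation. Minutes
conserve exactly: sedentary + light + MVPA = wear.

## Synthetic data generator

The generator emulates the study shape: 47 schools of 18–34 children, 55%
girls, BMI z ~ N(0.3, 1), IMD ~ Gamma(mean 15, SD 10 — a right-skewed
shape typical of deprivation indices; only the means are reported in the motivating cohort), four
activity items uniform on {0,…,3}. Each child nominates 2–4 schoolmates
(the reported median is 3 of a maximum 4), each tie same-sex with
probability 0.90. Outcomes come from the lag model's reduced form
y = (I − ρW)⁻¹(Xβ + u + ε) — a dense solve, never a truncated series —
with school random intercepts u (SD 5 min/day by default, making cluster
adjustment consequential) and MVPA defaults ρ = 0.20, β = (−14.76, −0.004,
−2.64, 2.45), σ = 15.5 min/day; σ was back-derived from the reported
model AIC at the study's n, and the sedentary counterparts (ρ = 0.14,
σ = 37) likewise. Missingness is MAR: per-variable target rates (0.5% for
BMI z up to 18% for sedentary time) tilted by a logistic score in sex and
the school's leave-one-out mean outcome, normalised so realised rates match
targets; an MCAR mode drops the tilt. The epoch generator draws each worn
epoch's intensity band from a configurable mix and a count within that
band, planting exact-zero non-wear blocks verbatim; within-child day-to-day
variance has no reported value, so the mix is a free design parameter.

One behaviour of the default study is worth flagging: because the
generator's school random intercepts create within-school outcome
similarity that the lag model (which has no school intercept) cannot
attribute elsewhere, the fitted network dependence on the default study
sits above the generating ρ. That is a faithful rendering of what
unmodelled school-level clustering does to network autocorrelation
estimates, not an estimator defect — the estimator-correctness experiments
below therefore switch the school intercepts off.

What the generator does *not* emulate: activity-homophilous tie formation
(ties are random apart from sex homophily), out-of-school friendships,
MNAR missingness, seasonal or weekday/weekend outcome structure, and raw
tri-axial accelerations. Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those features of
real cohorts.

## Estimator experiments and problem sizes

`friendnet.experiments` generates from the lag model **without** school
random intercepts: the fitted model has no school intercept term, and on a
within-school network a shared school intercept is indistinguishable from
network dependence, so including one would confound an
estimator-correctness check. These experiments also set the IMD slope to
−0.4 (the reported near-zero value makes relative recovery error
ill-defined). At the study scale (n = 600, 24 schools, ρ = 0.20):

* mean ρ̂ recovers ρ within ±0.03 (a mild downward bias of ρ̂ in network
  autocorrelation models is documented in the methodological literature and
  visible here, ~0.01);
* mean β̂ recovers every coefficient within 5%;
* 95% Wald CIs for ρ cover the truth at nominal rate (93–97% band);
* percentile total-impact CIs (200 draws) cover in 90–99 of 100 replicates;
* the Moran permutation test holds its 5% size at ρ = 0 and has ≥95% power
  at ρ = 0.5;
* MCAR missingness at the study's rates moves pooled ρ̂ recovery by less
  than 0.03 relative to complete-data fits (m = 10, 10 cycles in the
  experiment for speed; analysis defaults are 20/20).

Simulation sizes in the test suite (replicate counts, m, permutation
counts) are chosen so the full suite characterises the estimators at the
study's own scale while remaining a routine desk run.

## Numerical choices and edge cases

* Row standardisation divides only non-zero rows; zero rows stay zero and
  are flagged/excluded as described per method.
* Isolate pruning iterates removal of degree-zero nodes to a fixpoint
  (removal of an isolate cannot orphan a neighbour, so one pass suffices;
  the loop is kept as a safety property).
* Ties are directed; mutual nominations give two entries. A symmetrised W
  is available by flag, since the original construction is not stated.
* Boundary conventions: 500-min validity and both cut-point thresholds are
  inclusive; the 2-min interruption cap is inclusive.
* Degenerate inputs raise: zero-variance outcome in Moran's I, rank
  deficiency (naming the collinear columns), ρ outside the feasible
  interval (naming the interval), 100%-missing variables, empty networks.
* All randomness flows through explicit seeds; every generation and
  analysis function is a pure function of (inputs, config, seed).

## Known limitations

Cross-sectional: ρ conflates friend influence and activity-based friend
selection. The ML covariance is model-based; the school-cluster adjustment
for the lag model is an interpretation (model-based vcov, optional school
bootstrap) since no exact formula for the original adjustment is available. The imputation model
ignores the network term, which slightly attenuates pooled ρ̂ at high
missingness. Name-matching of free-text nominations is out of scope —
nominations must arrive resolved to ids.
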