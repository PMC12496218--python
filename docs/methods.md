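# Methods

`wtpmxl` implements a complete analysis pipeline for stated-preference
discrete choice experiments on landscape rewilding: data simulation with a
known generative process, estimation of a mixed logit in willingness-to-pay
(WTP) space by maximum simulated likelihood (MSL), and the derived outputs
a study of politically structured preferences needs — per-party WTP tables,
status-quo metrics, and a variance decomposition of preference
heterogeneity.

## Model

Respondent *n* chooses among three alternatives per card: two rewilding
*programs* and the zero-cost *status quo* (SQ).  Utility is

    U_itn = V_itn + e_itn,
    V_itn = alpha_n * ( beta_n0 SQ_itn + beta_n1' logL_itn
                        + beta_n2 LC_itn + beta_n3 LH_itn - Cost_itn ),

with Gumbel errors, so each task is a multinomial logit given the
respondent's coefficients.  `logL` collects the four landscape gradients
(forest, river, agriculture, connectivity), coded 1–4 and entered as
`log(code)` so the SQ level contributes zero and marginal utility declines
with level; large carnivores are coded 0/1/1/2 (the two single-species
levels are pooled) and large herbivores 0/1/2/3, both linear in the code;
cost is EUR/year.  Because the cost coefficient is factored out as
`alpha_n`, every `beta` is in EUR: the parenthesized form of V is the only
one under which the attribute coefficients are WTPs, and the package
commits to it.

Heterogeneity is hierarchical:

    beta_n  = mu + Lambda X_n + zeta_n          (normal WTP coefficients)
    alpha_n = exp(pi + gamma' X_n + eta_n)      (log-normal money utility)
    (zeta_n, eta_n) ~ N(0, Omega)

`X_n` holds respondent covariates — log distance, age, gender, city size,
income, education, and baseline-omitted dummies for party and region — so
`Lambda` shifts mean WTPs per covariate unit and `mu` is the mean for the
baseline profile (in particular, the largest party at covariate zero).
`Omega` is the joint (K+1)-dimensional covariance of the WTP block and the
money term: the likelihood integrates the two jointly, so their correlation
is estimable; a switch (`independent_money`) zeroes that covariance, and a
`diagonal` structure makes all components independent.

## Estimation

The likelihood per respondent is an integral over `(zeta, eta)` with no
closed form.  It is simulated as the average over `R` draws of the product
over that respondent's 12 tasks of logit choice probabilities, computed in
log space with log-sum-exp at every stage (within tasks, across draws) so
no underflow occurs even when a draw explains the panel badly.

* **Draws.** Scrambled Sobol points (Owen-type scrambling as implemented in
  `scipy.stats.qmc`, seeded), transformed to standard normal deviates by the
  inverse CDF.  Respondent *n* consumes rows `[nR, (n+1)R)` of one long
  sequence, generated once per estimation run and held fixed across all
  objective evaluations.  Default `R = 2000`; validation studies in this
  repository use 100–500 to keep runtimes sensible, which is noted wherever
  it applies.
* **Parameterization.** `Omega = C C'` with `C` lower-triangular and raw
  (unconstrained) entries; positive semidefiniteness holds by construction
  and a column sign flip leaves `Omega` unchanged, so no diagonal
  constraint is needed.
* **Gradient.** The gradient of the simulated log likelihood is computed
  analytically for all blocks including the Cholesky factor (the chain rule
  through `zeta = C u` reduces to weighted outer products of per-draw score
  terms with the draws).  It matches central finite differences to ~1e-9
  relative, and makes survey-scale fits feasible on one core.
* **Optimizer.** L-BFGS-B on a rescaled parameter vector (EUR-dimension
  parameters divided by a 25 EUR characteristic scale so all coordinates
  have comparable curvature), gradient tolerance 1e-5, at most 1000
  iterations.  Starting values come from a two-stage multinomial logit: a
  pooled preference-space MNL (cost coefficient parameterized as `exp(c)`,
  since the WTP-space model requires positive money utility; degenerate
  data drift to the zero boundary instead of leaving the parameter space)
  pins down `(mu, pi)`, then a WTP-space pass with `Omega = 0` adds
  `(Lambda, gamma)`.  The Cholesky factor starts at a small positive
  diagonal, `0.25 (|mu_0| + 5)` per WTP dimension and `0.3` for the money
  term.
* **Inference.** The observed-information variance is obtained by central
  finite differences of the analytic gradient; the respondent-clustered
  sandwich variance combines it with per-respondent score outer products.
  Wald tests on coefficient blocks use the sandwich variance by default;
  confidence intervals are normal-based at 95%.

Degenerate cases collapse exactly: with `Omega = 0` and no covariates the
simulated likelihood equals the analytic MNL likelihood for any draw set
(all draws map to the same coefficients), which the test suite asserts to
machine precision.  With one random coefficient the simulated likelihood at
2000 draws agrees with 64-node Gauss–Hermite quadrature to better than
1e-4 relative.

## Synthetic data generator

The generator draws covariates (standardized continuous variables, ordinal
city size and education, party and region labels at configured shares),
respondent coefficients from the hierarchy above, random choice cards
(attribute levels uniform per program alternative, SQ fixed at its
lowest-level zero-cost profile, cost drawn from {10, 25, 50, 100, 200}
EUR/year), and finally choices from the implied logit probabilities.  All
randomness flows from one declared seed.

Default parameter values were chosen once to echo the magnitudes such
surveys report: mean WTPs of tens of EUR with connectivity and large
animals highest; party and region loadings dominating the explained
heterogeneity; residual standard deviations comparable to the means; a
log-normal money utility around exp(-3.5) with sd 0.5 on the log scale; and
a positive SQ inertia constant (+95 EUR) that puts the overall status-quo
share in the 13–19% range at the default design.  A uniformly random
design is used instead of a D-efficient one: at fixture scale, random level
balance identifies all parameters, and it keeps the generator free of an
optimization step the analysis does not need.

What the generator does *not* emulate: blocked or efficiency-optimized
designs, attribute non-attendance, protest responses and response-time
behavior (cleaning flags are accepted as inputs instead), and any
divergence between the estimator's model and respondents' actual decision
process.  Passing recovery tests therefore demonstrate internal consistency
of estimator and generator at survey scale — not robustness to
misspecification on real data.

## Validation studies

* **Parameter recovery.** 20 independent studies of 1000 respondents × 12
  tasks, estimated with 500 draws under a diagonal-Omega specification with
  one non-baseline party: means, the money-utility location, party shifts
  and all random-component variances are compared to truth via relative
  bias of the cross-seed mean and its Monte Carlo standard error.  The
  diagonal truth keeps every variance identified at this scale and the
  parameter count (24) small enough that the 20 refits run in minutes.
  Note that individual variance parameters are estimated with cross-seed
  coefficients of variation near 40%, so a 20-seed bias estimate for a
  variance carries a Monte Carlo standard error of roughly 8 percentage
  points; deviations of that order are expected noise.
* **Wald size.** 500 simulated studies under a zero covariate loading,
  each fitted as a WTP-space MNL (exact likelihood, fast), applying the
  same per-attribute group test the decomposition table uses; the 5%-level
  empirical rejection rate is compared with the binomial band around 0.05.
  The per-attribute (1 df) version of the test is well calibrated at 250
  respondents; the joint all-attribute Wald on WTP-space loadings
  over-rejects mildly in small samples, as ratio-type parameterizations
  tend to.

## Decomposition conventions

For attribute *j*, the observed variance is the sample variance (ddof = 1)
of the fitted linear predictor `Lambda_j X` across respondents, the
unobserved part is `Omega_jj`, and the explained share is their ratio.  A
covariate group's raw contribution is the variance of its own fitted
combination — for categorical blocks (voting, regions) this keeps the
covariance among the block's dummies inside the block.  Because marginal
per-covariate variances do not sum to the variance of the total predictor
when covariates correlate, *relative* contributions are normalized by the
sum of group contributions, which makes every row sum to exactly 100%;
the unnormalized shares of total variance are also emitted for
transparency.  The money coefficient is decomposed on its natural log
scale (`gamma`, `Omega_eta,eta`) and labeled as such, never converted to
EUR; the table's mean row averages the six program attributes, excluding
the SQ constant and the cost row.

For log-coded attributes the headline WTP is reported at the lowest level,
where it equals the coefficient itself; the discrete value of the first
improvement (`beta log 2`) is emitted alongside under a separate label,
since both readings are in circulation and the output should not force the
choice silently.

## Known limitations

* The MSL objective carries simulation bias of order 1/R; at the reduced
  draw counts used in tests it is visible only within Monte Carlo noise.
* Maximum-likelihood estimates of weakly identified random-component
  variances are left-skewed in finite samples: when an attribute's
  heterogeneity contributes little utility variance relative to the Gumbel
  noise, individual replicates can place the likelihood maximum at a
  near-zero variance (verified to be the global optimum, not an optimizer
  artifact, by restarting from the truth).  Cross-seed averages of such
  variance estimates therefore converge slowly, and recovery summaries for
  them should be read against their Monte Carlo standard errors.
* Analytic standard errors assume a correctly specified model;
  cost non-attendance or lexicographic behavior on real data would violate
  it.
* The Wald test on joint multi-attribute WTP-space blocks over-rejects
  somewhat below ~1000 respondents (see above); the per-attribute group
  tests the tables report are calibrated.
* Party map coordinates are accepted as plain metadata; the package takes
  no position on their provenance or scaling.
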