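# Methods

## Data-generating processes

Each simulated dataset has two covariates chosen to mimic an adult
inpatient cohort: a continuous age-like variable
`x1 ~ Normal(57.3, 306.25)` (years; SD 17.5) and a binary sex-like
indicator `x2 ~ Bernoulli(0.43)`. The count outcome is generated with
log-mean `mu_i = exp(b0 + b1*x1 + b2*x2)` under one of four processes:

* **poisson** — `y_i ~ Poisson(mu_i)`.
* **nb** — gamma–Poisson heterogeneity: `tau_i ~ Gamma(theta, theta)`
  with `theta = 1/alpha` (so `E tau = 1`, `V tau = alpha`), then
  `y_i ~ Poisson(mu_i * tau_i)`. This exercises the mixture derivation
  of the NB2 distribution rather than sampling NB2 directly; the two
  are distributionally identical, which the test suite checks against
  the `scipy.stats.nbinom` pmf.
* **zip / zinb** — a Bernoulli(`phi`) structural-zero mask is drawn
  first and recorded in the dataset, then the Poisson/NB count is drawn
  and masked. `phi` is constant across observations: the generator has
  no zero-part covariates by design, because the study grid varies the
  *marginal* proportion of structural zeros.

Default true coefficients are `beta = (2.1, -0.001, 0.03)`. The slopes
are age and sex effects of the magnitude seen in NB regressions of
hospital length of stay (per-year effect of -0.1% on the mean,
+3% for the reference-vs-other sex contrast), and the intercept puts
the mean count near 8 days at the covariate means. Every generator
takes the coefficient vector as an argument; nothing downstream depends
on the default.

The factorial study grid crosses sample size n ∈ {50, 200, 600, 1000}
with, where the family has them, dispersion alpha ∈ {0.01, 1, 5, 10}
and structural-zero proportion phi ∈ {0.1, 0.3, 0.5, 0.7}: 4 Poisson
cells, 16 NB, 16 ZIP and 64 ZINB cells. The full design uses 1000
replications per cell; the packaged tests and the acceptance script run
200 replications per cell, which keeps every Monte-Carlo comparison
they make (minimum convergence percentages, mean-AIC orderings) stable
while fitting in minutes on one CPU.

Seed discipline: replication `r` of cell `s` uses a seed derived by
`SeedSequence([base_seed, crc32(scenario_id), r])`, reduced mod 2^31
and recorded in the dataset, so any single replication can be
regenerated in isolation and parallel execution cannot change results.
Linear predictors are validated against the `exp` overflow limit (700)
before exponentiation.

## The LOS emulator

`generate_los_emulator` produces a synthetic hospital-admissions-style
table (`los, age, sex, insurance, admission_type`). LOS is drawn from
an NB2 regression whose dispersion `alpha = (43.10 - 8) / 8^2 = 0.548`
solves `V = mu(1 + alpha*mu)` at the target marginal moments (mean 8.0
days, variance 43.1), with the intercept calibrated at generation time
so the realized-covariate mean equals the target; counts are clipped at
40 days (tail mass ≈ 0.2%, negligible for the moments). Categorical
frequencies follow a typical asthma inpatient cohort (60% female;
insurance government 4.4% / medicaid 14.0% / medicare 44.4% / private
36.4% / self-pay 0.8%; admission elective 17.4% / emergency 80.7% /
urgent 1.9%). Age is drawn from a plain Normal(62.3, 16^2) — a
realistic adult inpatient age distribution; the emulator does not
reproduce the top-coding of ages above 89 found in de-identified
hospital extracts, nor any real covariate–outcome confounding
structure. Passing tests on emulator data therefore demonstrate model
behaviour under overdispersion without zero-inflation, not agreement
with any particular real cohort.

## Fitting and convergence coding

All four likelihoods are written in log-gamma / log-sum-exp arithmetic
(the zero branch of the mixtures via `logaddexp`), with analytic
gradients, and maximized with L-BFGS-B over `(beta, gamma, ln alpha)`;
`ftol = 1e-12`, `gtol = 1e-8`, at most 500 iterations, with up to two
deterministic jittered restarts if the line search stalls. Because the
age covariate's scale (~57) dwarfs its coefficient (~1e-3), design
columns are centred and scaled internally and estimates, gradients and
the covariance matrix are transformed back exactly.

Starting values: the count part from a Poisson pre-fit (itself started
at log mean response), the zero-part intercept from the link transform
of the observed excess-zero fraction `max(0.05, p0_obs - p0_poisson)`,
other zero-part coefficients at 0, `alpha` at 0.5.

Convergence is coded explicitly because it is itself a study metric:

* **converged** — optimizer success (or final gradient inf-norm below
  `1e-5 * max(1, |loglik|)`), finite estimates, and positive-definite
  observed information (smallest eigenvalue above `1e-9` of the
  largest) with finite standard errors.
* **converged with boundary** — the zero-part linear predictor drifts
  to the ±30 cap, or the information matrix is singular only in
  zero-part directions (separation / mixture weight collapsing to 0).
  A mixture weight of zero is a valid boundary MLE, so these count as
  converged; their covariance comes from an eigenvalue-floored inverse,
  which reports the flat directions as very large finite standard
  errors rather than failing.
* **non-converged** — all-zero outcome (count part unidentified, for
  every family); dispersion collapsing below `alpha = 1e-4` (the NB
  has degenerated to its Poisson limit and the MLE sits on the
  boundary — this is what makes NB/ZINB convergence rates drop on
  equidispersed data) or hitting the upper `ln alpha` box; optimizer
  failure with a large gradient; non-PD information elsewhere. Each
  failure carries a reason code, logged per replication.

The observed information is a central finite difference of the analytic
gradient (step `1e-5 * (1 + |x|)` per coordinate). Inference is Wald:
`se = sqrt(diag(cov))`, two-sided normal p-values; the dispersion's SE
is delta-method on the `ln alpha` scale. AIC/BIC count every estimated
parameter (`beta`, all `gamma`, and `alpha` where present); BIC uses
the number of observations.

## Metrics

* **Convergence rate**: percent of replications whose fit satisfied the
  criterion above.
* **MAE** `= mean |E(y_i|x_i) - E_hat(y_i|x_i)|`, where the reference
  is the *true* conditional mean of the generating process (`mu_i`, or
  `mu_i(1-phi)` for the zero-inflated processes). The formula compares
  two expectations, so the true mean — not the realized count — is the
  natural reference; a `mae_reference="observed"` switch provides the
  mean-absolute-residual alternative.
* AIC/BIC/MAE are averaged over **converged replications only**;
  summaries carry replication-level standard errors so Monte-Carlo
  uncertainty is explicit.
* **Pearson dispersion**: `sum((y - E)^2 / V) / (n - k)` with `E`, `V`
  the fitted family's conditional moments; values well above 1 signal
  overdispersion relative to the fitted model.

## Design choices on points the protocol leaves open

* Fitted ZIP/ZINB models in the simulation use an intercept-only zero
  part (the generating `phi` is constant); a configuration switch fits
  the same covariates in both parts, which is the convention used in
  the empirical stage.
* Wald (not likelihood-ratio) inference, matching standard
  count-regression software output.
* Zero-part link defaults to logit; probit and complementary log-log
  are available.
* Dummy coding in the empirical pipeline defaults to reference levels
  male / self-pay / urgent, overridable per column.
* p-values are unadjusted, two-sided, at significance level 0.05.

## Known limitations

* Convergence rates for NB/ZINB fitted to (near-)equidispersed data
  depend on the optimizer and on how boundary solutions are counted;
  other software coding the same fits differently will report different
  rates. The universal-convergence findings (every cell where the fitted
  dispersion has an interior optimum) are robust to this; the exact
  sub-100% percentages are not, and the package treats them as
  optimizer-specific diagnostics rather than reproducible quantities.
* The harness executes replications sequentially; the per-replication
  seed derivation makes concurrent execution safe in principle, but no
  parallel executor is shipped.
* Underdispersed processes, hurdle models, covariate-dependent
  zero-inflation in the generator, and robust/sandwich standard errors
  are out of scope.
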