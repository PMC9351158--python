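# countcompare

Tools for choosing among the four workhorse regression models for count
outcomes — Poisson, negative binomial (NB), zero-inflated Poisson (ZIP)
and zero-inflated negative binomial (ZINB) — with hospital length of
stay (LOS) as the motivating application. The package bundles:

* **synthetic data generators** for all four count processes (and a
  hospital-admissions-style LOS table emulator),
* **from-scratch maximum-likelihood fitters** with analytic gradients,
  Wald inference, AIC/BIC and the Pearson dispersion diagnostic,
* a **Monte-Carlo replication harness** that measures convergence
  rates and mean AIC/BIC/MAE over a factorial grid of sample sizes,
  dispersion levels and structural-zero proportions, and
* an **empirical-comparison pipeline** that fits all four models to any
  LOS-format table and reports them side by side.

It is aimed at biostatisticians and health-services researchers who
need to decide — and to demonstrate — which count model their data
support.

## Models

With counts $y_i$ and covariates $x_i$, all four families share the
log link $\mu_i = e^{x_i'\beta}$.

* **Poisson**: $P(Y_i=y_i) = e^{-\mu_i}\mu_i^{y_i}/y_i!$, with
  $E(Y_i) = V(Y_i) = \mu_i$ (equidispersion).
* **NB2**: a gamma–Poisson mixture ($\tau_i \sim \Gamma(\theta,\theta)$,
  $\theta = 1/\alpha$, then $Y_i \sim \text{Poisson}(\mu_i\tau_i)$),
  giving $V(Y_i) = \mu_i(1 + \alpha\mu_i)$; $\alpha \to 0$ recovers the
  Poisson.
* **ZIP / ZINB**: a two-process mixture in which a Bernoulli trial with
  probability $\varphi_i = F(z_i'\gamma)$ (logit link by default)
  produces a *structural* zero, and otherwise the count comes from the
  Poisson or NB2 component:

  $$P(Y_i = y_i) = \begin{cases}
      \varphi_i + (1-\varphi_i)\,g(0) & y_i = 0 \\
      (1-\varphi_i)\,g(y_i) & y_i > 0
  \end{cases}$$

  with $E(Y_i) = \mu_i(1-\varphi_i)$.

All likelihoods are maximized by quasi-Newton (L-BFGS-B) iteration over
$(\beta, \gamma, \ln\alpha)$ with analytic gradients; model fit is
compared by AIC $= -2\ell + 2k$ and BIC $= -2\ell + k\ln n$, parameter
accuracy by the mean absolute error between true and fitted conditional
means, and misspecification by the Pearson chi-square statistic divided
by its degrees of freedom.

## Worked example

Fit all four models to a synthetic overdispersed LOS table:

```python
from countcompare import generate_los_emulator, compare_models

df = generate_los_emulator(n=2167, seed=0)
report = compare_models(
    df, outcome="los",
    covariates=["age", "sex", "insurance", "admission_type"],
)
print({fam: round(a, 1) for fam, a in report.aic.items()})
print({fam: round(d, 3) for fam, d in report.dispersion.items()})
print(report.ranking("aic"))
```

prints

```
{'poisson': 18411.2, 'nb': 13396.9, 'zip': 17517.2, 'zinb': 13401.2}
{'poisson': 5.197, 'nb': 0.972, 'zip': 3.721, 'zinb': 0.993}
['nb', 'zinb', 'zip', 'poisson']
```

The outcome here has mean 8.08 but variance 42.39 and almost no zeros
(4.9%): classic overdispersion without zero-inflation. The Poisson fit
is badly overdispersed (Pearson statistic 5.2 ≫ 1), the NB fit absorbs
it (0.97 ≈ 1), and the NB wins both AIC and BIC; the ZINB comes second,
paying the information-criterion price of its unneeded zero part —
whose coefficients come back with enormous standard errors, the
signature of an estimated mixture weight collapsing to zero.
`report.render_text()` prints the full side-by-side coefficient table.

The simulation study runs from the command line:

```bash
countcompare simulate --output-dir out/ --replications 1000
countcompare tables --summaries out/summaries.csv --output-dir out/tables/
```

`simulate` is resumable (completed grid cells are skipped on rerun) and
bit-reproducible from the base seed.

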