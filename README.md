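# microzinb

Bayesian zero-inflated negative binomial (ZINB) regression for
microbiome count data.

ASV/OTU count tables are awkward for standard regression: most entries
are zeros (a mix of true absence and technical dropout) and the nonzero
counts are far more variable than a Poisson model allows.  `microzinb`
models a taxon's counts as

    P(y = 0)     = phi + (1 - phi) * (theta/(theta + mu))^theta
    P(y = k > 0) = (1 - phi) * NB(k; mu, theta)

with a log-linear mean `log(mu_i) = B_i beta`, NB size `theta`
(overdispersion `1/theta`), and extra-zero probability `phi` linked to
the data in one of three ways — most usefully the **tau link**
`logit(phi_i) = -tau * B_i beta`, which lets dropout shrink as abundance
grows with a single extra parameter.  Inference is MCMC under diffuse
priors (Gamma(0.001, 0.001) on `theta` and `tau`, Normal(0, precision
1e-6) on coefficients); effect sizes are posterior means with 95%
equal-tailed credible intervals.

It is written for microbiome statisticians and bioinformaticians who
want to (1) fit and compare the Poisson/NB/ZIP/ZINB/hurdle model family
on per-taxon counts, (2) benchmark estimator accuracy under controlled
zero inflation and overdispersion, (3) characterize how zero-inflated
and overdispersed a count table actually is, and (4) run a per-taxon
differential-abundance analysis with host covariates (age, BMI-for-age
z-score, ethnicity x geography interactions) on real or simulated
cohorts.

## Worked example

```python
import numpy as np
from microzinb import ModelSpec, ScenarioConfig, sample_posterior, simulate_scenario

scen = ScenarioConfig(n=300, effect_level=1.0, phi=0.3, inv_theta=1.0, seed=42)
sim = simulate_scenario(scen, zero_mech="tau")
fit = sample_posterior(ModelSpec(variant="ZINB_tau", seed=42),
                       sim["B"], sim["y"], param_names=sim["names"])
print(fit.summary.round(3))
```

prints (`examples/01_simulate_and_fit.py`):

```
     parameter   mean    sd   q2.5  q97.5  truth
beta:intercept  2.301 0.201  1.936  2.682  2.452
      beta:age  1.022 0.080  0.865  1.174  1.000
 beta:ethnic_K -0.888 0.156 -1.166 -0.540 -1.000
    beta:geo_W  1.392 0.253  0.871  1.907  1.000
    beta:geo_H -0.809 0.261 -1.321 -0.330 -1.000
    beta:geo_N  1.108 0.247  0.633  1.592  1.000
    beta:bmiaz -1.137 0.084 -1.298 -0.973 -1.000
           tau  0.533 0.097  0.374  0.770    NaN
         theta  0.780 0.099  0.595  1.009    NaN
failed=False  converged=True
```

Each `beta:` row is a covariate's effect on the log mean abundance; all
seven true coefficients fall inside their 95% credible intervals.  The
`tau` row quantifies how strongly dropout is tied to abundance, and
`1/theta ~ 1.3` recovers the simulated overdispersion of 1.  The
`failed` flag would replace every number with NA if the sampler had
degenerated (non-finite density or R-hat > 1.2 everywhere).

The other capabilities each have a narrative script under `examples/`:
count-table characterization (`02`), z-scores and GVIF collinearity
screening (`03`), the ARB accuracy benchmark (`04`), and the
differential-abundance pipeline with ethnogeographic interaction
reporting (`05`).  A thin CLI mirrors them:
`microzinb simulate|benchmark|characterize|gvif|zscore|fit|da --help`.
File formats are documented in `FORMATS.md`, the statistical details in
`docs/methods.md`.

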