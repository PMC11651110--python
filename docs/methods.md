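# Methods

## The model family

Counts of one taxon across samples are modelled as zero-inflated
negative binomial (ZINB):

    P(y = 0)     = phi + (1 - phi) * (theta / (theta + mu))**theta
    P(y = k > 0) = (1 - phi) * NB(k; mu, theta)

where `mu` is the NB mean, `theta` the NB size (overdispersion is
`1/theta`; NB variance is `mu + mu^2/theta`), and `phi` in [0, 1] the
weight of *extra* zeros — a mixture of biological absence and technical
dropout that the count component cannot explain.  Moments:
`E[Y] = (1-phi) mu`, `Var[Y] = (1-phi) mu (1 + mu/theta + phi mu)`.
Setting `phi = 0` recovers the NB, `theta -> inf` the zero-inflated
Poisson (ZIP), and both limits together the Poisson.

In the regression family the mean is log-linear, `log(mu_i) = B_i beta`,
and the extra-zero probability follows one of three links:

- **tau link** (`ZIP_tau`, `ZINB_tau`): `logit(phi_i) = -tau * B_i beta`,
  i.e. `phi_i = 1/(1 + mu_i**tau)`.  For `tau > 0` abundant taxa get few
  extra zeros — a single free parameter couples dropout to abundance.
- **covariate link** (`MZIP`, `MZINB`): `logit(phi_i) = -(G_i gamma)`
  with its own coefficient vector on a zero-model design `G` (default
  `G = B`).  The leading minus sign keeps the sign convention of the tau
  link.
- **free intercept** (`ZIP_inter`, `ZINB_inter`): `logit(phi_i) = theta0`,
  constant zero inflation.

`P` and `NB` omit the zero model; `HURDLE` is the frequentist two-part
alternative (logistic model for `P(y=0)` with `logit(phi) = -(G gamma)`,
zero-truncated NB for the positives, MLE with Wald intervals).  When the
truncated-NB dispersion MLE hits the `alpha -> 0` boundary or fails to
converge — which is the generic outcome on equidispersed positives —
the count part falls back to the boundary MLE, a zero-truncated Poisson,
and `theta` is reported as infinite.

### Priors

Diffuse by default and exposed on `ModelSpec`: `theta` and `tau` get
Gamma(a = 0.001, rate b = 0.001) (nearly scale-invariant on the positive
axis, and constraining `tau > 0`); every linear coefficient (`beta`,
`gamma`, `theta0`) gets Normal(0, precision 1e-6), i.e. variance 1e6.
The precision convention follows the BUGS/JAGS-style parameterization
these hyperparameters come from; a *variance* of 1e-6 would be absurdly
informative.

## Posterior sampling

The sampler is emcee's affine-invariant ensemble MCMC, run as
`chains = 2` fully independent ensembles.  Positive parameters are
sampled on the log scale with the Jacobian correction; `phi` only ever
appears through its logit, so boundary values cannot underflow.  Walkers
start from a Poisson-GLM fit of `beta` plus moment-based starts for
`theta`, `tau` and the zero model, with small jitter.

The iteration schedule is expressed in the adapt/burn-in/sample
vocabulary of Gibbs-style samplers (defaults 10 000 / 2 000 / 2 000) and
mapped to ensemble steps: each ensemble discards
`ceil((adapt + burnin)/nwalkers)` warmup steps and retains
`ceil(samples/nwalkers)` steps, with `nwalkers = max(2*ndim + 2, 16)`.
With the defaults this yields ~4 000 retained draws whose bulk ESS is
typically 50–120 — comparable information to a few thousand draws of a
well-mixed single-site sampler, at a few seconds per fit.

Diagnostics: split-R-hat is computed across the independent ensembles
(the level at which runs are truly independent; walkers within one
ensemble interact and would inflate R-hat spuriously), bulk ESS across
the per-walker chains (which carry the autocorrelation).  A fit is
flagged **failed** — summaries missing-coded, never an exception — when
draws are non-finite, mean acceptance collapses below 0.02, or R-hat
exceeds 1.2 on every parameter.  Structural problems (dimension
mismatch, all-zero counts, fewer than p+2 observations) raise before
sampling.  Identical `ModelSpec` + seed gives bit-identical summaries.

Point estimate is the posterior mean; intervals are equal-tailed
2.5/97.5 posterior quantiles.  A 60-replicate calibration study on
self-simulated tau-link data (n = 500, effect 1, 1/theta = 1) measured
per-coefficient 95%-interval coverage of ~94%, i.e. nominal within
Monte-Carlo error.

## Simulation design

`generate_covariates` emulates a school-age cohort: age uniform on
3.0–15.0 y, sex and ethnicity balanced binary, four locations uniform,
height and weight driven linearly by age with noise (deliberately
collinear, so the GVIF experiment is reproducible), BMI-for-age z-score
standard normal.  The scenario design matrix is
(intercept, standardized age, ethnic dummy, 3 geography dummies, bmiaz).

Effect levels 0.5 / 1 / 1.5 are the magnitudes of the non-intercept
coefficients, applied with a fixed alternating sign pattern
(+, -, +, -, +, -); the intercept is solved so median `mu` is 10, a
typical filtered-taxon scale.  (The levels are described as
"correlation coefficients" in the source vocabulary, but values above 1
cannot be correlations; magnitude-of-coefficient is the only consistent
reading.)  Overdispersion `1/theta` in {0, 1, 2} (0 = Poisson) and
marginal zero inflation `phi` in {0, 0.2, 0.5}.  For the tau mechanism,
`tau` is solved numerically so the *average* of `1/(1+mu_i**tau)` equals
the target `phi`, making the three mechanisms comparable at equal
marginal zero inflation; the covariate mechanism solves its intercept
the same way.  The base grid is 4 sample sizes x 3 effects x 3 phi x 3
dispersion = 108 cells; the overdispersion-tolerance extension is
{100, 200, 500, 1000, 2000} x `1/theta` in {2, 5, 10} at moderate effect
and zero inflation (15 cells).

What the generator does *not* emulate: compositionality and
between-taxon correlation, library-size variation, read-level noise, or
phylogenetic structure.  Passing tests therefore demonstrate correctness
of the estimators under the stated single-taxon sampling model, not
robustness to those real-data features.

## The ARB benchmark

Accuracy is absolute relative bias: per fit, the **median over nonzero
true coefficients** of `|estimate - truth|/|truth|`, with the intercept
excluded (its truth depends on the mean-scale normalization; the
exclusion is configurable in the sense that the caller chooses which
coefficients enter).  Cells aggregate as mean (sd) per model for tabular
summaries and median across replicates/cells for box-plot style
summaries.  Failed fits are recorded as NA, counted, and skipped by the
aggregates — a model that cannot estimate a cell is data.  With the
robust ensemble sampler and the hurdle boundary fallback, outright
failures at the extreme-overdispersion cells are much rarer than with
slice-sampling backends, where such cells are reported as wholly
unestimable; the failure-accounting machinery is exercised wherever
failures do occur (e.g. the hurdle model on replicates without zeros).

Two notes on the equivalence of models in the no-signal cell
(`phi = 0`, `1/theta = 0`): the comparison is made at effect level 0.5,
where every `mu_i > 1`.  At larger effects the design spreads `mu`
across 1, and the tau link then *forces* `phi_i -> 1` for `mu_i < 1`
regardless of tau — the zero-inflated variants become structurally
misspecified even though the data contain no extra zeros, and
equivalence genuinely breaks.  This boundary behaviour of the tau link
is a property of the model, not of the implementation.  Second, the
equivalence ratio is a median over few replicates and is noisy; the
test fixes its seed.

## Per-taxon moment characterization

For a single taxon the triple (phi, mu, theta) is estimated by matching
three sample statistics — mean `m`, variance `v`, zero fraction `p0` —
to their model values.  Eliminating `mu = m/(1-phi)` and
`1/theta = (v/m - 1)/mu - phi` leaves one equation in `phi`,

    f(phi) = phi + (1-phi) * P_NB(0; mu(phi), theta(phi)) - p0,

with `f(0) <= 0 <= f(p0)` whenever the NB alone under-explains the
observed zeros, so a bracketed root solve on [0, p0] (tolerance 1e-8)
is guaranteed to converge; negative implied dispersions are clamped to
the Poisson boundary.  `phi_hat` is clamped to [0, 1]; a taxon is
flagged zero-inflated when `phi_hat > 0.05` (a package choice — no
canonical cutoff exists — and configurable).  The NB-part dispersion
removes `floor(phi_hat * n)` zeros and re-matches NB moments; it is
typically slightly below the whole-sample dispersion.  Overdispersion is
called at `1/theta_hat > 10`.

## Preprocessing

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a fixed depth, default 5 000 reads; samples below the
depth are dropped and reported rather than kept unrarefied.  The
low-abundance filter removes taxa with cohort-wide totals strictly below
a threshold (15 for characterization, 30 before per-taxon regression).
Rank aggregation sums counts over taxa sharing a lineage label, pooling
unassigned taxa into "unclassified"; it conserves per-sample totals
exactly.

## Covariate engineering

Anthropometrics are standardized by the LMS method,
`z = ((x/M)**L - 1)/(L S)` (log branch at L = 0, `expm1` for small L),
with L/M/S interpolated linearly in age per sex.  The bundled reference
is synthetic (smooth plausible curves for 3–15 y); real WHO tables load
from CSV.  BMI-for-age z-scores classify as normal (-2 <= z <= 2),
overweight (2 < z <= 4), obese (z > 4) — cutoffs taken from the source
convention and exposed as parameters (WHO practice uses 2/3); z < -2 is
reported separately as underweight.

The regression design uses treatment coding with a configurable
reference (ethnic U, location H by default), centered age, and
ethnic x geography interaction columns only for level pairs observed in
the data.  Collinearity is screened with the generalized VIF
(Fox–Monette determinant formula on the correlation matrix of
non-intercept columns), compared across terms on the `GVIF**(1/(2 df))`
scale; a candidate design is acceptable when its worst scaled GVIF is
strictly below 3.

## Differential-abundance pipeline

Each retained taxon is fitted independently (default `ZINB_tau`) on the
design above.  A covariate is *discriminatory* when its 95% equal-tailed
credible interval excludes zero; age/BMI effects with |posterior mean|
above 0.35 are additionally highlighted.  No p-values are produced and
**no multiple-testing correction is applied** — flags are per-taxon
Bayesian interval statements and should be read as such.  Per-taxon
failures are flagged and logged, never fatal.  The ethnogeographic
report combines main-effect and interaction draws per (ethnic,
geography) pair relative to the reference pair and flags taxa with at
least one pair of non-overlapping intervals.  Whether age and BMI are
fitted jointly or separately was an open design point; the default is a
single joint model per taxon (both covariates plus the interaction),
since separate fits would silently confound the two.

## Problem sizes

The test suite and acceptance script run the method at reduced scale
chosen to exercise every claim in minutes: coverage at n = 500 with 20
replicates; benchmark cells at n in {100, 200} with 3–10 replicates;
the calibration cohort with 40 taxa at n = 200.  The full 108-cell grid
with the default schedule is a multi-hour computation and is available
through `scenario_grid()` / `run_benchmark` unchanged.

## Known limitations

- One taxon at a time: no compositional constraint, no joint modelling,
  no phylogenetic pooling.
- The tau link ties dropout monotonically to abundance; when
  `mu` spans 1 it cannot represent "no zero inflation anywhere" (see the
  benchmark note above).
- Ensemble MCMC ESS per draw is low compared with gradient-based
  samplers; schedules trade accuracy for time explicitly via
  `ModelSpec`.
- The hurdle model's Wald intervals are asymptotic; small cells can make
  its zero part separable (flagged as failed).
- The bundled LMS reference is synthetic; real z-scores require WHO
  tables supplied by the user.
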