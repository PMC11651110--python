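"""Bayesian regression family for zero-inflated microbiome counts.

Nine model variants share the log-linear mean model ``log(mu) = B beta``
and differ in the count distribution (Poisson vs negative binomial) and
in how the extra-zero probability ``phi`` is linked to the data:

====================  =======================  ==========================
variant               count component          zero-inflation link
====================  =======================  ==========================
P                     Poisson                  none
NB                    NB(mu, theta)            none
ZIP_tau / ZINB_tau    Poisson / NB             logit(phi) = -tau * B beta
MZIP / MZINB          Poisson / NB             logit(phi) = -(G gamma)
ZIP_inter/ZINB_inter  Poisson / NB             logit(phi) = theta0 (free)
HURDLE                zero-truncated NB        logistic two-part MLE
====================  =======================  ==========================

Bayesian variants are sampled with emcee (affine-invariant ensemble MCMC)
under diffuse priors: Gamma(0.001, 0.001) on theta and tau, Normal with
mean 0 and precision 1e-6 on every linear coefficient.  theta and tau are
sampled on the log scale (with the Jacobian correction); phi is handled
on the logit scale throughout so boundary values never underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .distributions import phi_from_tau, zinb_logpmf

__all__ = [
    "VARIANTS",
    "RegressionParams",
    "ModelSpec",
    "FitResult",
    "zinb_loglik",
    "log_prior",
    "sample_posterior",
    "fit_variant",
    "fit_hurdle_mle",
]

VARIANTS = (
    "P",
    "NB",
    "ZIP_tau",
    "MZIP",
    "ZIP_inter",
    "ZINB_tau",
    "MZINB",
    "ZINB_inter",
    "HURDLE",
)

_NB_FAMILY = {"NB", "ZINB_tau", "MZINB", "ZINB_inter"}
_LINKS = {
    "P": "none",
    "NB": "none",
    "ZIP_tau": "tau",
    "ZINB_tau": "tau",
    "MZIP": "cov",
    "MZINB": "cov",
    "ZIP_inter": "inter",
    "ZINB_inter": "inter",
}


@dataclass(frozen=True)
class RegressionParams:
    """Regression-level parameter bundle.

    Exactly one of ``tau`` (tau link), ``gamma`` (covariate link) or
    ``theta0`` (free-intercept link) is active for zero-inflated
    variants; ``theta`` is the NB size (None for Poisson-family).
    """

    beta: np.ndarray
    theta: float | None = None
    tau: float | None = None
    gamma: np.ndarray | None = None
    theta0: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        active = sum(x is not None for x in (self.tau, self.gamma, self.theta0))
        if active > 1:
            raise ValueError("at most one of tau/gamma/theta0 may be active")
        # nonpositive theta/tau are representable (a sampler may propose them);
        # log_prior assigns them -inf and the likelihood rejects them


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, prior hyperparameters and MCMC schedule.

    ``adapt + burnin`` ensemble moves are discarded as warmup and
    ``samples`` posterior draws are retained, split across the walkers
    of ``chains`` independent ensembles.
    """

    variant: str = "ZINB_tau"
    prior_a: float = 0.001
    prior_b: float = 0.001
    beta_precision: float = 1e-6
    adapt: int = 10_000
    burnin: int = 2_000
    samples: int = 2_000
    chains: int = 2
    seed: int = 0
    zero_design: np.ndarray | None = None  # G; defaults to B when None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid names: {', '.join(VARIANTS)}"
            )
        if min(self.adapt, self.burnin, self.samples) <= 0:
            raise ValueError("adapt, burnin and samples must be positive")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


@dataclass
class FitResult:
    """Posterior (or MLE) summary for one model fit.

    ``summary`` has one row per parameter with columns
    (parameter, mean, sd, q2.5, q97.5, ess, rhat).  When ``failed`` is
    True every numeric field is NaN (missing-coded) and no flag derived
    from the fit should be trusted.
    """

    variant: str
    summary: pd.DataFrame
    failed: bool
    converged: bool
    draws: pd.DataFrame | None = None  # posterior draws on the natural scale
    message: str = ""

    @property
    def beta(self) -> pd.Series:
        mask = self.summary["parameter"].str.startswith("beta:")
        s = self.summary.loc[mask].set_index("parameter")["mean"]
        s.index = [p.split(":", 1)[1] for p in s.index]
        return s

    @property
    def inv_theta(self) -> float:
        row = self.summary.loc[self.summary["parameter"] == "theta", "mean"]
        if row.empty or np.isnan(row.iloc[0]):
            return float("nan")
        return 1.0 / float(row.iloc[0])  # 0.0 at the Poisson boundary (theta = inf)


def _logsigmoid(x):
    return -np.logaddexp(0.0, -x)


def zinb_loglik(params: RegressionParams, B: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood of the tau-link ZINB regression model.

    Computed as the sum over observations of the ZINB log pmf with
    ``mu_i = exp(B_i beta)``, shared ``theta`` and
    ``phi_i = 1/(1 + mu_i**tau)``.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y)
    if y.size == 0:
        return 0.0
    if B.ndim != 2 or B.shape[0] != y.shape[0]:
        raise ValueError(f"design matrix rows ({B.shape[0]}) != len(y) ({y.shape[0]})")
    if params.tau is None or params.theta is None:
        raise ValueError("tau-link ZINB requires both tau and theta")
    if params.theta <= 0:
        raise ValueError("theta must be > 0")
    if B.shape[1] != params.beta.shape[0]:
        raise ValueError("beta length does not match design matrix columns")
    mu = np.exp(B @ params.beta)
    phi = phi_from_tau(mu, params.tau)
    return float(np.sum(zinb_logpmf(y, mu=mu, theta=params.theta, phi=phi)))


def log_prior(params: RegressionParams, spec: ModelSpec) -> float:
    """Joint log prior density of the active parameters.

    Gamma(prior_a, rate=prior_b) on theta and tau (returns -inf, never
    raises, when either is non-positive); Normal(0, precision
    beta_precision) on beta, gamma and theta0.  Terms for inactive
    parameters are omitted.
    """
    a, b = spec.prior_a, spec.prior_b
    sd = 1.0 / math.sqrt(spec.beta_precision)
    total = float(np.sum(stats.norm.logpdf(params.beta, 0.0, sd)))
    for x in (params.theta, params.tau):
        if x is not None:
            if x <= 0:
                return -math.inf
            total += float(stats.gamma.logpdf(x, a, scale=1.0 / b))
    if params.gamma is not None:
        total += float(np.sum(stats.norm.logpdf(params.gamma, 0.0, sd)))
    if params.theta0 is not None:
        total += float(stats.norm.logpdf(params.theta0, 0.0, sd))
    return total


class _PosteriorDensity:
    """Vectorized log posterior over ensemble coordinates.

    Layout of one coordinate vector: beta (p), then the link parameter
    (log tau | gamma (q) | theta0), then log theta for NB-family.
    """

    def __init__(self, variant: str, B: np.ndarray, y: np.ndarray, spec: ModelSpec):
        self.B = B
        self.y = np.asarray(y, dtype=float)
        self.is0 = self.y == 0
        self.link = _LINKS[variant]
        self.has_theta = variant in _NB_FAMILY
        self.spec = spec
        p = B.shape[1]
        names = [f"beta:{j}" for j in range(p)]
        self.sl_beta = slice(0, p)
        pos = p
        self.G = None
        if self.link == "tau":
            self.sl_link = pos
            names.append("tau")
            pos += 1
        elif self.link == "cov":
            self.G = B if spec.zero_design is None else np.asarray(spec.zero_design, float)
            if self.G.shape[0] != B.shape[0]:
                raise ValueError("zero_design rows must match design matrix rows")
            q = self.G.shape[1]
            self.sl_link = slice(pos, pos + q)
            names += [f"gamma:{j}" for j in range(q)]
            pos += q
        elif self.link == "inter":
            self.sl_link = pos
            names.append("theta0")
            pos += 1
        if self.has_theta:
            self.i_theta = pos
            names.append("theta")
            pos += 1
        self.ndim = pos
        self.names = names
        # indices sampled on the log scale (natural-scale params are exp of these)
        self.log_scale = [i for i, n in enumerate(names) if n in ("tau", "theta")]

    def log_prob(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        W = coords.shape[0]
        beta = coords[:, self.sl_beta]
        eta = beta @ self.B.T  # (W, n)
        bad = ~np.all(np.isfinite(coords), axis=1)
        bad |= np.abs(coords).max(axis=1) > 40.0
        bad |= np.abs(eta).max(axis=1) > 40.0
        eta = np.clip(eta, -40.0, 40.0)
        mu = np.exp(eta)
        y = self.y

        spec = self.spec
        a, b = spec.prior_a, spec.prior_b
        lp = -0.5 * spec.beta_precision * np.sum(beta**2, axis=1)

        if self.has_theta:
            ltheta = np.clip(coords[:, self.i_theta], -40.0, 40.0)
            theta = np.exp(ltheta)[:, None]
            nb0 = theta * (np.log(theta) - np.log(theta + mu))
            lpos = (
                special.gammaln(theta + y)
                - special.gammaln(theta)
                - special.gammaln(y + 1.0)
                + nb0
                + y * (eta - np.log(theta + mu))
            )
            lp += a * ltheta - b * theta[:, 0]  # gamma prior + log-scale Jacobian
        else:
            nb0 = -mu
            lpos = y * eta - mu - special.gammaln(y + 1.0)

        if self.link == "none":
            ll = np.where(self.is0, nb0, lpos)
        else:
            if self.link == "tau":
                ltau = np.clip(coords[:, self.sl_link], -40.0, 40.0)
                tau = np.exp(ltau)
                logit_phi = -tau[:, None] * eta
                lp += a * ltau - b * tau  # gamma prior + log-scale Jacobian
            elif self.link == "cov":
                gam = coords[:, self.sl_link]
                logit_phi = -(gam @ self.G.T)
                lp += -0.5 * spec.beta_precision * np.sum(gam**2, axis=1)
            else:  # inter
                t0 = coords[:, self.sl_link]
                logit_phi = np.broadcast_to(t0[:, None], mu.shape)
                lp += -0.5 * spec.beta_precision * t0**2
            logit_phi = np.clip(logit_phi, -500.0, 500.0)
            l0 = np.logaddexp(_logsigmoid(logit_phi), _logsigmoid(-logit_phi) + nb0)
            ll = np.where(self.is0, l0, _logsigmoid(-logit_phi) + lpos)

        out = lp + ll.sum(axis=1)
        out[bad | ~np.isfinite(out)] = -np.inf
        return out


def _initial_point(density: _PosteriorDensity, y: np.ndarray) -> np.ndarray:
    """Crude moment-based starting point for the walkers."""
    B, spec = density.B, density.spec
    beta0 = None
    try:  # Poisson GLM start: fast and close to the mode for every variant
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(np.asarray(y, float), B, family=sm.families.Poisson()).fit()
        if np.all(np.isfinite(glm.params)):
            beta0 = np.asarray(glm.params)
    except Exception:
        beta0 = None
    if beta0 is None:
        z = np.log(np.asarray(y, float) + 0.5)
        beta0, *_ = np.linalg.lstsq(B, z, rcond=None)
    x0 = np.zeros(density.ndim)
    x0[density.sl_beta] = np.clip(beta0, -8, 8)
    pos = y[y > 0]
    m, v = float(np.mean(pos)), float(np.var(pos) + 1e-8)
    inv_theta = max((v - m) / max(m**2, 1e-8), 1e-2)
    p0 = float(np.mean(y == 0))
    p0 = min(max(p0, 1e-3), 1 - 1e-3)
    if density.link == "tau":
        x0[density.sl_link] = 0.0  # tau = 1
    elif density.link == "cov":
        g = np.zeros(density.G.shape[1])
        g[0] = -special.logit(p0)
        x0[density.sl_link] = g
    elif density.link == "inter":
        x0[density.sl_link] = special.logit(p0)
    if density.has_theta:
        x0[density.i_theta] = -math.log(inv_theta)
    return x0


def _validate_fit_inputs(B, y, variant):
    B = np.asarray(B, dtype=float)
    y = np.asarray(y)
    if B.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if B.shape[0] != y.shape[0]:
        raise ValueError(f"design matrix rows ({B.shape[0]}) != len(y) ({y.shape[0]})")
    yf = np.asarray(y, dtype=float)
    if np.any(yf < 0) or np.any(yf != np.floor(yf)):
        raise ValueError("y must contain non-negative integers")
    if B.shape[0] < B.shape[1] + 2:
        raise ValueError("need at least p + 2 observations")
    if not np.any(yf > 0):
        raise ValueError("y is all zeros: the count component is unidentifiable")
    return B, yf


def _failed_summary(names) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": list(names),
            "mean": np.nan,
            "sd": np.nan,
            "q2.5": np.nan,
            "q97.5": np.nan,
            "ess": np.nan,
            "rhat": np.nan,
        }
    )


def sample_posterior(
    spec: ModelSpec,
    B: np.ndarray,
    y: np.ndarray,
    param_names: list[str] | None = None,
    keep_draws: bool = False,
) -> FitResult:
    """Sample the posterior of a Bayesian variant with ensemble MCMC.

    Runs ``spec.chains`` independent emcee ensembles; warmup
    (``adapt + burnin`` draws worth of steps) is discarded and
    ``samples`` draws are retained per ensemble.  Diagnostic failure
    (non-finite density, near-zero acceptance, or split-R-hat above 1.2
    on every parameter) is reported via ``failed=True`` with NaN
    summaries — never as an exception.  Structural problems (dimension
    mismatch, all-zero counts) do raise, before any sampling.
    """
    import emcee

    if spec.variant == "HURDLE":
        return fit_hurdle_mle(B, y, zero_design=spec.zero_design, param_names=param_names)
    B, y = _validate_fit_inputs(B, y, spec.variant)
    density = _PosteriorDensity(spec.variant, B, y, spec)
    names = list(density.names)
    if param_names is not None:
        for j, nm in enumerate(param_names):
            names[j] = f"beta:{nm}"
        if density.link == "cov":
            q = density.G.shape[1]
            base = density.B.shape[1]
            for j in range(min(q, len(param_names))):
                names[base + j] = f"gamma:{param_names[j]}"

    ndim = density.ndim
    nwalkers = max(2 * ndim + 2, 16)
    nwalkers += nwalkers % 2
    warm_steps = max(int(math.ceil((spec.adapt + spec.burnin) / nwalkers)), 50)
    draw_steps = max(int(math.ceil(spec.samples / nwalkers)), 20)
    x0 = _initial_point(density, y)

    chains = []
    acc = []
    try:
        for c in range(spec.chains):
            child = np.random.SeedSequence([int(spec.seed) % (2**31), c])
            rs = np.random.RandomState(child.generate_state(1)[0] % (2**32 - 1))
            p0 = x0[None, :] + 0.05 * rs.randn(nwalkers, ndim)
            sampler = emcee.EnsembleSampler(nwalkers, ndim, density.log_prob, vectorize=True)
            state = emcee.State(p0, random_state=rs.get_state())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state = sampler.run_mcmc(state, warm_steps)
                sampler.reset()
                sampler.run_mcmc(state, draw_steps)
            chains.append(sampler.get_chain())  # (steps, walkers, ndim)
            acc.append(float(np.mean(sampler.acceptance_fraction)))
    except Exception as exc:  # sampler degeneracy is data, not an exception
        return FitResult(spec.variant, _failed_summary(names), True, False, None, str(exc))

    # walker-level chains for ESS; ensemble-level (time-major pooled) chains for R-hat
    arr = np.concatenate([np.moveaxis(ch, 0, 1) for ch in chains], axis=0)
    pooled = np.stack([ch.reshape(-1, ndim) for ch in chains], axis=0)
    for i in density.log_scale:
        arr[:, :, i] = np.exp(arr[:, :, i])
        pooled[:, :, i] = np.exp(pooled[:, :, i])

    finite = bool(np.all(np.isfinite(arr)))
    rhat, ess = _diagnostics(arr, pooled)
    all_bad_rhat = bool(np.all(rhat > 1.2))
    failed = (not finite) or (np.mean(acc) < 0.02) or all_bad_rhat
    converged = finite and bool(np.all(rhat <= 1.2))

    if failed:
        msg = "non-finite draws" if not finite else (
            "acceptance collapsed" if np.mean(acc) < 0.02 else "R-hat > 1.2 on all parameters"
        )
        return FitResult(spec.variant, _failed_summary(names), True, False, None, msg)

    flat = arr.reshape(-1, ndim)
    summary = pd.DataFrame(
        {
            "parameter": names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": np.percentile(flat, 2.5, axis=0),
            "q97.5": np.percentile(flat, 97.5, axis=0),
            "ess": ess,
            "rhat": rhat,
        }
    )
    draws = pd.DataFrame(flat, columns=names) if keep_draws else None
    return FitResult(spec.variant, summary, False, converged, draws)


def _diagnostics(arr: np.ndarray, pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convergence diagnostics per parameter.

    Split-R-hat is computed on the independent-ensemble chains
    (``pooled``: each ensemble's walkers interleaved time-major), which
    is the level at which runs are independent; bulk ESS is computed on
    the per-walker chains (``arr``), which carry the autocorrelation.
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(pooled))["x"].values
        ess = az.ess(az.convert_to_dataset(arr))["x"].values
    rhat = np.where(np.isfinite(rhat), rhat, np.inf)
    return rhat, ess


def fit_variant(
    variant: str,
    B: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    param_names: list[str] | None = None,
    keep_draws: bool = False,
) -> FitResult:
    """Fit one of the nine model variants and return its coefficient summary.

    All variants report coefficients on the log-mean scale, so estimates
    are comparable across models.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid names: {', '.join(VARIANTS)}")
    if variant == "HURDLE":
        zd = spec.zero_design if spec is not None else None
        return fit_hurdle_mle(B, y, zero_design=zd, param_names=param_names)
    spec = replace(spec, variant=variant) if spec is not None else ModelSpec(variant=variant)
    return sample_posterior(spec, B, y, param_names=param_names, keep_draws=keep_draws)


def fit_hurdle_mle(
    B: np.ndarray,
    y: np.ndarray,
    zero_design: np.ndarray | None = None,
    param_names: list[str] | None = None,
) -> FitResult:
    """Two-part hurdle model by maximum likelihood.

    A logistic regression models P(y = 0) with logit(phi) = -(G gamma)
    (sign convention shared with the covariate-link Bayesian variants),
    and a zero-truncated negative binomial models the positive counts.
    Standard errors come from the observed information; Wald 95%
    intervals fill the q2.5/q97.5 columns.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

    B = np.asarray(B, dtype=float)
    y = np.asarray(y)
    if B.ndim != 2 or B.shape[0] != y.shape[0]:
        raise ValueError("design matrix rows must match len(y)")
    G = B if zero_design is None else np.asarray(zero_design, dtype=float)
    nz = int(np.sum(y == 0))
    if nz == 0:
        raise ValueError("hurdle zero part is degenerate: y contains no zeros")
    if nz == len(y):
        raise ValueError("hurdle count part is degenerate: y contains no positive counts")

    p = B.shape[1]
    q = G.shape[1]
    bnames = [f"beta:{param_names[j] if param_names else j}" for j in range(p)]
    gnames = [f"gamma:{param_names[j] if param_names else j}" for j in range(q)]
    names = bnames + gnames + ["theta"]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit_fit = sm.Logit((y == 0).astype(float), G).fit(disp=0, maxiter=200)
            pos = y > 0
            glm = sm.GLM(np.asarray(y[pos], float), B[pos], family=sm.families.Poisson()).fit()
            start = np.concatenate([np.asarray(glm.params), [0.1]])
            trunc = TruncatedLFNegativeBinomialP(y[pos], B[pos], truncation=0)
            count_fit = trunc.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            count_ok = bool(count_fit.mle_retvals.get("converged", False)) and bool(
                np.all(np.isfinite(count_fit.bse))
            )
            if not count_ok or count_fit.params[p] <= 1e-6:
                # equidispersed boundary (alpha -> 0): the MLE is truncated Poisson
                from statsmodels.discrete.truncated_model import TruncatedLFPoisson

                pfit = TruncatedLFPoisson(y[pos], B[pos], truncation=0).fit(
                    start_params=np.asarray(glm.params), method="bfgs", maxiter=500, disp=0
                )
                count_fit = pfit
                count_ok = bool(pfit.mle_retvals.get("converged", False))
                alpha, alpha_se = 0.0, np.nan
            else:
                alpha = float(count_fit.params[p])  # NB2 dispersion, alpha = 1/theta
                alpha_se = float(count_fit.bse[p])
        ok = bool(logit_fit.mle_retvals.get("converged", True)) and count_ok
        beta_hat = np.asarray(count_fit.params[:p])
        beta_se = np.asarray(count_fit.bse[:p])
        gamma_hat = -np.asarray(logit_fit.params)  # logit(phi) = -(G gamma)
        gamma_se = np.asarray(logit_fit.bse)
        est = np.concatenate([beta_hat, gamma_hat, [1.0 / alpha if alpha > 0 else np.inf]])
        theta_se = alpha_se / alpha**2 if alpha > 0 else np.nan  # delta method
        se = np.concatenate([beta_se, gamma_se, [theta_se]])
        ok = ok and bool(np.all(np.isfinite(est[:-1])) and np.all(np.isfinite(se[:-1])))
    except Exception as exc:
        return FitResult("HURDLE", _failed_summary(names), True, False, None, str(exc))

    if not ok:
        return FitResult("HURDLE", _failed_summary(names), True, False, None, "MLE non-convergence")
    summary = pd.DataFrame(
        {
            "parameter": names,
            "mean": est,
            "sd": se,
            "q2.5": est - 1.959963984540054 * se,
            "q97.5": est + 1.959963984540054 * se,
            "ess": np.nan,
            "rhat": np.nan,
        }
    )
    return FitResult("HURDLE", summary, False, True, None)
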