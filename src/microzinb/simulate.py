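"""Synthetic covariates and ZINB count responses for benchmarking.

The generator emulates a school-age children cohort: age uniform on
3.0–15.0 years, two ethnic groups (U/K), four geographic locations
(S/W/H/N), height and weight grown jointly with age (so the classic
height x weight x age collinearity is present by construction), and a
BMI-for-age z-score that is standard normal.  Counts follow the ZINB
regression model: ``mu_i = exp(B_i beta)`` with Poisson (``1/theta = 0``)
or NB counts and extra zeros injected by one of three mechanisms at a
target marginal probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ScenarioConfig",
    "generate_covariates",
    "sim_design",
    "true_beta",
    "simulate_counts",
    "simulate_scenario",
    "scenario_grid",
    "solve_tau_for_phi",
]

#: benchmark factor levels: sample sizes, coefficient magnitudes,
#: zero-inflation probabilities, overdispersion 1/theta
GRID_N = (100, 200, 500, 1000)
GRID_EFFECT = (0.5, 1.0, 1.5)
GRID_PHI = (0.0, 0.2, 0.5)
GRID_INV_THETA = (0.0, 1.0, 2.0)
EXTENDED_N = (100, 200, 500, 1000, 2000)
EXTENDED_INV_THETA = (2.0, 5.0, 10.0)

ZERO_MECHANISMS = ("tau", "covariate", "intercept")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell: sample size, effect magnitude, zero inflation
    probability, overdispersion 1/theta, replicate index and seed."""

    n: int
    effect_level: float
    phi: float
    inv_theta: float
    replicate: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must be in [0, 1)")
        if self.inv_theta < 0:
            raise ValueError("inv_theta must be >= 0")


def generate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Generate an n-row cohort covariate table.

    Columns: sample_id, age (years, uniform 3.0–15.0), sex (M/F), ethnic
    (U/K, balanced), geography (S/W/H/N, uniform), height (m), weight
    (kg) — both driven linearly by age with noise, so height, weight and
    age are strongly collinear — and bmiaz ~ N(0, 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    age = rng.uniform(3.0, 15.0, n)
    sex = rng.choice(["M", "F"], n)
    ethnic = rng.choice(["U", "K"], n)
    geography = rng.choice(["S", "W", "H", "N"], n)
    height = np.clip(0.90 + 0.040 * (age - 3.0) + rng.normal(0, 0.03, n), 0.90, 1.50)
    weight = np.clip(
        17.0 + 0.75 * (age - 3.0) + 40.0 * (height - (0.90 + 0.040 * (age - 3.0)))
        + rng.normal(0, 0.6, n),
        17.0,
        27.0,
    )
    bmiaz = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ethnic": ethnic,
            "geography": geography,
            "height": height,
            "weight": weight,
            "bmiaz": bmiaz,
        }
    )


def sim_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix used by the simulation scenarios.

    Columns: intercept, standardized age, ethnic indicator (K vs U),
    geography treatment dummies (reference S), bmiaz.
    """
    age = cov["age"].to_numpy(float)
    age_z = (age - age.mean()) / age.std()
    cols = {
        "intercept": np.ones(len(cov)),
        "age": age_z,
        "ethnic_K": (cov["ethnic"] == "K").to_numpy(float),
        "geo_W": (cov["geography"] == "W").to_numpy(float),
        "geo_H": (cov["geography"] == "H").to_numpy(float),
        "geo_N": (cov["geography"] == "N").to_numpy(float),
        "bmiaz": cov["bmiaz"].to_numpy(float),
    }
    names = list(cols)
    return np.column_stack(list(cols.values())), names


# alternating sign pattern for the non-intercept coefficients
_SIGNS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])


def true_beta(effect_level: float, B: np.ndarray) -> np.ndarray:
    """Coefficient vector for one scenario.

    Non-intercept coefficients are +/- ``effect_level`` with a fixed
    alternating sign pattern; the intercept is solved so the median of
    ``mu_i`` is 10 (a typical filtered-taxon abundance scale).
    """
    slopes = effect_level * _SIGNS[: B.shape[1] - 1]
    eta = B[:, 1:] @ slopes
    return np.concatenate([[np.log(10.0) - np.median(eta)], slopes])


def solve_tau_for_phi(mu: np.ndarray, phi: float) -> float:
    """tau such that mean_i 1/(1 + mu_i**tau) equals the target phi."""
    logmu = np.log(mu)

    def g(tau):
        return float(np.mean(special.expit(-tau * logmu))) - phi

    lo, hi = -50.0, 80.0
    if g(lo) * g(hi) > 0:  # degenerate mu distribution; fall back to best effort
        res = optimize.minimize_scalar(lambda t: abs(g(t)), bounds=(lo, hi), method="bounded")
        return float(res.x)
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def _solve_gamma0(r: np.ndarray, phi: float) -> float:
    """gamma0 such that mean_i expit(-(gamma0 + r_i)) equals phi."""

    def g(g0):
        return float(np.mean(special.expit(-(g0 + r)))) - phi

    return float(optimize.brentq(g, -60.0, 60.0, xtol=1e-10))


def simulate_counts(
    cov: pd.DataFrame,
    beta: np.ndarray,
    scenario: ScenarioConfig,
    zero_mech: str = "tau",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a ZINB count response for a covariate table.

    ``mu_i = exp(B_i beta)`` over the simulation design; counts are
    Poisson when ``scenario.inv_theta == 0`` and NB with
    ``theta = 1/inv_theta`` otherwise.  Extra zeros are injected with
    marginal probability ``scenario.phi`` using one of three mechanisms:
    ``tau`` (zero probability tied to the mean, ``phi_i = 1/(1+mu_i**tau)``
    with tau solved so the average matches), ``covariate``
    (``logit(phi_i) = -(gamma0 + gamma x_i)`` with gamma0 solved), or
    ``intercept`` (constant ``phi_i = phi``).
    """
    if zero_mech not in ZERO_MECHANISMS:
        raise ValueError(f"zero_mech must be one of {ZERO_MECHANISMS}")
    B, _ = sim_design(cov)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != B.shape[1]:
        raise ValueError(f"beta has length {beta.shape[0]}, design has {B.shape[1]} columns")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    mu = np.exp(np.clip(B @ beta, -40, 40))

    if scenario.inv_theta == 0:
        y = rng.poisson(mu)
    else:
        theta = 1.0 / scenario.inv_theta
        y = rng.negative_binomial(theta, theta / (theta + mu))

    phi = scenario.phi
    if phi > 0:
        if zero_mech == "tau":
            tau = solve_tau_for_phi(mu, phi)
            phi_i = special.expit(-tau * np.log(mu))
        elif zero_mech == "covariate":
            x = np.column_stack(
                [
                    B[:, 1],  # standardized age
                    (cov["ethnic"] == "K").to_numpy(float),
                    cov["bmiaz"].to_numpy(float),
                ]
            )
            r = x @ np.array([0.25, -0.25, 0.25])
            g0 = _solve_gamma0(r, phi)
            phi_i = special.expit(-(g0 + r))
        else:
            phi_i = np.full(len(mu), phi)
        y = np.where(rng.random(len(mu)) < phi_i, 0, y)
    return np.asarray(y, dtype=np.int64)


def simulate_scenario(
    scenario: ScenarioConfig, zero_mech: str = "tau"
) -> dict:
    """Generate one full scenario: covariates, design, truth and counts.

    Returns a dict with keys ``cov``, ``B``, ``names``, ``beta`` (true
    coefficients) and ``y``.  All randomness derives from
    ``scenario.seed`` and ``scenario.replicate``.
    """
    ss = np.random.SeedSequence([int(scenario.seed) % (2**31), scenario.replicate])
    s_cov, s_y = ss.spawn(2)
    cov = generate_covariates(scenario.n, s_cov)
    B, names = sim_design(cov)
    beta = true_beta(scenario.effect_level, B)
    y = simulate_counts(cov, beta, scenario, zero_mech, rng=np.random.default_rng(s_y))
    return {"cov": cov, "B": B, "names": names, "beta": beta, "y": y}


def scenario_grid(extended: bool = False, seed: int = 0) -> list[ScenarioConfig]:
    """The benchmark scenario grid.

    Base grid: n in {100, 200, 500, 1000} x effect {0.5, 1, 1.5} x
    phi {0, 0.2, 0.5} x 1/theta {0, 1, 2} (108 cells).  Extended
    overdispersion-tolerance grid: n in {100, ..., 2000} x 1/theta
    {2, 5, 10} (15 cells) at moderate effect (1) and zero inflation
    (0.2).  Per-cell seeds are derived deterministically from ``seed``.
    """
    cells: list[tuple[int, float, float, float]] = []
    if extended:
        for n in EXTENDED_N:
            for it in EXTENDED_INV_THETA:
                cells.append((n, 1.0, 0.2, it))
    else:
        for n in GRID_N:
            for eff in GRID_EFFECT:
                for phi in GRID_PHI:
                    for it in GRID_INV_THETA:
                        cells.append((n, eff, phi, it))
    seeds = np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    return [
        ScenarioConfig(n=n, effect_level=e, phi=p, inv_theta=it, seed=int(s))
        for (n, e, p, it), s in zip(cells, seeds)
    ]
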