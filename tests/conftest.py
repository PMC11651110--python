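import numpy as np
import pytest

from microzinb import ModelSpec, phi_from_tau
from microzinb.simulate import generate_covariates, sim_design, true_beta


@pytest.fixture
def fast_spec():
    """Reduced MCMC schedule for structural (non-accuracy) tests."""
    return ModelSpec(adapt=2000, burnin=500, samples=1000, seed=0)


def make_tau_link_data(n: int, seed: int, effect: float = 1.0, theta: float = 1.0, tau: float = 1.0):
    """Self-consistent tau-link ZINB data: the fitted model is the generator."""
    ss = np.random.SeedSequence([seed, 0])
    s1, s2 = ss.spawn(2)
    cov = generate_covariates(n, s1)
    B, names = sim_design(cov)
    beta = true_beta(effect, B)
    mu = np.exp(B @ beta)
    phi = phi_from_tau(mu, tau)
    rng = np.random.default_rng(s2)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    y = np.where(rng.random(n) < phi, 0, y)
    return {"B": B, "names": names, "beta": beta, "y": y, "mu": mu, "phi": phi}
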