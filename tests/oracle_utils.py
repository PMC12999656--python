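"""Independent oracles used by the invasion-analysis tests.

Both deliberately avoid the package's cached fitness path: the rare-mutant
oracle iterates the two-type competition recursion itself (log-space mutant
so underflow cannot bite), and the score-function oracle rebuilds the
averaging window from the public simulation modules and differentiates
scipy's beta log-density numerically.
"""

import math

import numpy as np
from scipy.stats import beta as scipy_beta

from thermoevo import (
    carrying_capacity,
    generate_temperature,
    growth_rate,
    simulate_resident,
)
from thermoevo.competition_tpc import log_beta_density


def rare_mutant_fitness(resident, mutant, regime, demo, cfg, N0=0.5, M0=1e-8):
    """Average log-growth of a vanishingly rare mutant in the coupled
    two-type competition recursion (mutant tracked in log space)."""
    series = generate_temperature(
        type(regime)(
            tau0=regime.tau0, m=regime.m, omega=regime.omega,
            sigma_eps=regime.sigma_eps, seed=cfg.noise_seed,
        ),
        cfg.horizon_L,
    )
    taus = series.values
    r = growth_rate(taus, demo.growth)
    k = carrying_capacity(taus, demo.capacity)
    a_mn = np.exp(log_beta_density(taus, resident) - log_beta_density(taus, mutant))
    a_nm = 1.0 / a_mn
    n, ln_m = N0, math.log(M0)
    growths = []
    for t in range(cfg.horizon_L):
        m = math.exp(ln_m)
        g_m = r[t] * (1.0 - (a_mn[t] * n + m) / k[t])
        if t >= cfg.burn_in:
            growths.append(g_m)
        if t < cfg.horizon_L - 1:
            g_n = r[t] * (1.0 - (n + a_nm[t] * m) / k[t])
            n = n * math.exp(g_n)
            ln_m += g_m
    return float(np.mean(growths))


def score_function_gradient(resident, regime, demo, cfg, h=1e-5):
    """Selection gradients as the attractor average of
    w_t * d log beta(tau_t; mu, s) / d(mu or s), with the log-density
    derivative taken numerically through scipy's implementation."""
    series = generate_temperature(
        type(regime)(
            tau0=regime.tau0, m=regime.m, omega=regime.omega,
            sigma_eps=regime.sigma_eps, seed=cfg.noise_seed,
        ),
        cfg.horizon_L,
    )
    traj = simulate_resident(0.5, series, demo)
    sl = slice(cfg.burn_in, cfg.horizon_L)
    taus = series.values[sl]
    r = growth_rate(taus, demo.growth)
    k = carrying_capacity(taus, demo.capacity)
    w = r * traj.N[sl] / k

    def logpdf(mu, s):
        return scipy_beta.logpdf(taus, mu / s, (1.0 - mu) / s)

    mu, s = resident.mu, resident.s
    dlog_dmu = (logpdf(mu + h, s) - logpdf(mu - h, s)) / (2 * h)
    dlog_ds = (logpdf(mu, s + h) - logpdf(mu, s - h)) / (2 * h)
    return float(np.mean(w * dlog_dmu)), float(np.mean(w * dlog_ds))
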