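"""Invasion fitness, selection gradients and the fitness Hessian.

The invasion fitness of a rare mutant with TPC shape ``(mu_M, s_M)`` in a
resident population with shape ``(mu_N, s_N)`` is the long-run average of
its per-capita log growth rate on the resident's attractor:

    lambda_bar = (1/L) * sum_t  r(tau_t) * (1 - alpha_MN(tau_t) N_t / k(tau_t)),

where N_t is the resident trajectory and alpha_MN the TPC density ratio.
The mutant is strictly non-feedback (true rarity limit): it never alters
N_t.  Because the resident's own competition coefficient is identically 1,
the resident trajectory does not depend on the resident's TPC either, so a
single frozen (temperature, N_t) realization per thermal regime serves
*every* fitness, gradient and Hessian evaluation under that regime.  This
is exactly the common-random-numbers scheme: comparative quantities
(finite-difference stencils, nullclines) are smooth deterministic
functions of the traits conditional on one noise realization.

Cached per regime are the window averages

    lambda_bar(resident, mutant)
        = mean(r_t) - mean( w_t * exp(log beta_N(tau_t) - log beta_M(tau_t)) ),
    w_t = r(tau_t) * N_t / k(tau_t),

so each evaluation costs only two log-density sweeps over the averaging
window.

Selection gradients are central finite differences of the invasion fitness
in the mutant traits, evaluated at the resident (step ``fd_step``, default
1e-4); the Hessian uses second-order central stencils at 10x that step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .competition_tpc import TPCShape, log_beta_density
from .demography import DemographyParams, carrying_capacity, growth_rate
from .ricker import simulate_resident
from .thermal_env import ThermalRegime, generate_temperature

__all__ = [
    "InvasionConfig",
    "SelectionGradient",
    "FitnessHessian",
    "ResidentContext",
    "resident_context",
    "invasion_fitness",
    "selection_gradient",
    "fitness_hessian",
]

_LOG_RATIO_CAP = 700.0
_DEFAULT_N0 = 0.5


@dataclass(frozen=True)
class InvasionConfig:
    """Numerical controls for invasion-fitness evaluation.

    ``horizon_L`` is the averaging horizon, ``burn_in`` the number of
    initial steps discarded before averaging, ``fd_step`` the central
    finite-difference step in both traits, and ``noise_seed`` the frozen
    noise stream shared by all comparative evaluations.
    """

    horizon_L: int = 100_000
    burn_in: int = 1000
    fd_step: float = 1e-4
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burn_in < self.horizon_L:
            raise ValueError(
                f"need 0 < burn_in < horizon_L, got {self.burn_in}, {self.horizon_L}"
            )
        if not self.fd_step > 0.0:
            raise ValueError(f"fd_step must be positive, got {self.fd_step}")


@dataclass(frozen=True)
class SelectionGradient:
    """The pair (g_mu, g_s) of selection gradients at a resident."""

    g_mu: float
    g_s: float
    config: InvasionConfig

    def as_array(self) -> np.ndarray:
        return np.array([self.g_mu, self.g_s])


@dataclass(frozen=True)
class FitnessHessian:
    """Symmetric 2x2 Hessian of mutant fitness at the resident."""

    entries: np.ndarray  # shape (2, 2)
    eigenvalues: np.ndarray  # ascending

    @property
    def negative_definite(self) -> bool:
        return bool(np.all(self.eigenvalues < 0.0))


class ResidentContext:
    """Frozen resident environment for fast repeated fitness evaluation.

    Holds the averaging-window temperatures, the weights ``w_t`` and the
    mean growth rate for one (regime, demography, config) triple.  The
    regime's own seed is replaced by ``cfg.noise_seed`` so that stencil
    evaluations share a single noise realization.
    """

    def __init__(
        self,
        regime: ThermalRegime,
        params: DemographyParams,
        cfg: InvasionConfig,
        N0: float = _DEFAULT_N0,
    ):
        self.regime = dataclasses.replace(regime, seed=cfg.noise_seed)
        self.params = params
        self.cfg = cfg
        series = generate_temperature(self.regime, cfg.horizon_L)
        traj = simulate_resident(N0, series, params)
        sl = slice(cfg.burn_in, cfg.horizon_L)
        self.tau_w = series.values[sl]
        r_w = growth_rate(self.tau_w, params.growth)
        k_w = carrying_capacity(self.tau_w, params.capacity)
        self.N_w = traj.N[sl]
        self.weight = r_w * self.N_w / k_w
        self.mean_r = float(np.mean(r_w))
        self.effective_popsize = float(np.mean(self.N_w))

    def fitness(self, resident: TPCShape, mutant: TPCShape) -> float:
        """Invasion fitness of *mutant* against *resident* on this context."""
        log_ratio = log_beta_density(self.tau_w, resident) - log_beta_density(
            self.tau_w, mutant
        )
        np.clip(log_ratio, -_LOG_RATIO_CAP, _LOG_RATIO_CAP, out=log_ratio)
        return self.mean_r - float(np.mean(self.weight * np.exp(log_ratio)))

    def gradient(self, resident: TPCShape) -> SelectionGradient:
        """Central-FD selection gradients in the mutant traits at *resident*."""
        h = self.cfg.fd_step
        mu, s = resident.mu, resident.s
        if not (h < mu < 1.0 - h and s > h):
            raise ValueError(
                f"fd_step {h} violates trait bounds at resident ({mu}, {s})"
            )
        g_mu = (
            self.fitness(resident, TPCShape(mu + h, s))
            - self.fitness(resident, TPCShape(mu - h, s))
        ) / (2.0 * h)
        g_s = (
            self.fitness(resident, TPCShape(mu, s + h))
            - self.fitness(resident, TPCShape(mu, s - h))
        ) / (2.0 * h)
        return SelectionGradient(g_mu=g_mu, g_s=g_s, config=self.cfg)

    def hessian(self, resident: TPCShape) -> FitnessHessian:
        """Central-FD Hessian of mutant fitness at *resident* (step 10*fd_step)."""
        h = 10.0 * self.cfg.fd_step
        mu, s = resident.mu, resident.s
        if not (h < mu < 1.0 - h and s > h):
            raise ValueError(f"Hessian step {h} violates trait bounds at ({mu}, {s})")

        def f(dmu: float, ds: float) -> float:
            return self.fitness(resident, TPCShape(mu + dmu, s + ds))

        f00 = f(0.0, 0.0)
        h11 = (f(h, 0.0) - 2.0 * f00 + f(-h, 0.0)) / h**2
        h22 = (f(0.0, h) - 2.0 * f00 + f(0.0, -h)) / h**2
        h12 = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4.0 * h**2)
        entries = np.array([[h11, h12], [h12, h22]])
        eigs = np.sort(np.linalg.eigvalsh(entries))
        return FitnessHessian(entries=entries, eigenvalues=eigs)


@lru_cache(maxsize=16)
def resident_context(
    regime: ThermalRegime, params: DemographyParams, cfg: InvasionConfig
) -> ResidentContext:
    """Memoized :class:`ResidentContext` factory (all keys are frozen)."""
    return ResidentContext(regime, params, cfg)


def invasion_fitness(
    resident: TPCShape,
    mutant: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    cfg: InvasionConfig = InvasionConfig(),
) -> float:
    """Long-run average per-capita growth rate of a rare mutant."""
    return resident_context(regime, params, cfg).fitness(resident, mutant)


def selection_gradient(
    resident: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    cfg: InvasionConfig = InvasionConfig(),
) -> SelectionGradient:
    """Selection gradients (g_mu, g_s) at *resident* under *regime*."""
    return resident_context(regime, params, cfg).gradient(resident)


def fitness_hessian(
    resident: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    cfg: InvasionConfig = InvasionConfig(),
) -> FitnessHessian:
    """FD Hessian of mutant invasion fitness at *resident*."""
    return resident_context(regime, params, cfg).hessian(resident)
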