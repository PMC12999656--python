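"""Stochastic Ricker dynamics driven by a temperature series.

Single-population update:

    N_{t+1} = N_t * exp( r(tau_t) * (1 - N_t / k(tau_t)) )

and the coupled resident-mutant competition system:

    N_{t+1} = N_t * exp( r(tau_t) * (1 - (N_t + alpha_NM(tau_t) M_t) / k(tau_t)) )
    M_{t+1} = M_t * exp( r(tau_t) * (1 - (alpha_MN(tau_t) N_t + M_t) / k(tau_t)) )

where the competition coefficients are the TPC density ratios of
:func:`thermoevo.competition_tpc.competition_coefficients`.  The dynamics
are deterministic conditional on the temperature series: all stochasticity
enters through tau_t.  The exponential map preserves positivity, so a
mutant can only reach zero through floating-point underflow; values below
1e-300 are clamped to exact zero (an absorbing state) and the event is
logged.

Demographic stochasticity is deliberately absent: populations are treated
as large enough that only environmental fluctuation matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .competition_tpc import TPCShape, log_beta_density
from .demography import DemographyParams, carrying_capacity, growth_rate
from .thermal_env import TemperatureSeries

__all__ = [
    "Trajectory",
    "AttractorSummary",
    "SimulationError",
    "simulate_resident",
    "simulate_pair",
    "attractor_summary",
]

logger = logging.getLogger(__name__)

_EXP_CAP = 700.0  # |exponent| beyond this would overflow a double
_EXTINCTION_FLOOR = 1e-300


class SimulationError(RuntimeError):
    """Raised when a trajectory diverges (exponent out of double range)."""


@dataclass(frozen=True)
class Trajectory:
    """Time series of temperature and population sizes.

    ``N[t]`` and (if present) ``M[t]`` are aligned with ``tau.values[t]``;
    the final temperature drives no further update.
    """

    times: np.ndarray
    tau: TemperatureSeries
    N: np.ndarray
    M: Optional[np.ndarray]
    params: DemographyParams
    shapes: Optional[tuple[TPCShape, TPCShape]] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.tau) == n == len(self.N)):
            raise ValueError("times, tau and N must have equal length")
        if self.M is not None and len(self.M) != n:
            raise ValueError("M must match the trajectory length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AttractorSummary:
    """Time-average statistics of the resident on its attractor.

    ``mean_N`` doubles as the effective population size estimate used by
    the canonical equation.
    """

    mean_N: float
    sd_N: float
    burn_in: int
    window: int


def _step_exponents_ok(arg: float, t: int) -> None:
    if not np.isfinite(arg) or abs(arg) > _EXP_CAP:
        raise SimulationError(
            f"Ricker exponent {arg!r} out of range at step {t}; trajectory divergent"
        )


def simulate_resident(
    N0: float, tau: TemperatureSeries, params: DemographyParams = DemographyParams()
) -> Trajectory:
    """Iterate the single-population stochastic Ricker map along *tau*."""
    if not N0 > 0.0:
        raise ValueError(f"N0 must be strictly positive, got {N0}")
    taus = tau.values
    r = growth_rate(taus, params.growth)
    k = carrying_capacity(taus, params.capacity)
    n = len(taus)
    N = np.empty(n)
    N[0] = N0
    x = N0
    for t in range(n - 1):
        arg = r[t] * (1.0 - x / k[t])
        _step_exponents_ok(arg, t)
        x = x * np.exp(arg)
        N[t + 1] = x
    return Trajectory(times=np.arange(n), tau=tau, N=N, M=None, params=params)


def simulate_pair(
    N0: float,
    M0: float,
    tau: TemperatureSeries,
    params: DemographyParams,
    resident: TPCShape,
    mutant: TPCShape,
) -> Trajectory:
    """Iterate the coupled resident-mutant Ricker competition system.

    With ``M0 = 0`` the mutant stays extinct and the resident path equals
    the single-population run bit-for-bit.  Competition coefficients are
    density ratios re-evaluated at every step's temperature (precomputed
    in log space along the whole series).
    """
    if not N0 > 0.0:
        raise ValueError(f"N0 must be strictly positive, got {N0}")
    if M0 < 0.0:
        raise ValueError(f"M0 must be nonnegative, got {M0}")
    taus = tau.values
    r = growth_rate(taus, params.growth)
    k = carrying_capacity(taus, params.capacity)
    # alpha_MN(tau_t) = exp(log beta_N - log beta_M); alpha_NM is its reciprocal
    log_ratio = np.clip(
        log_beta_density(taus, resident) - log_beta_density(taus, mutant),
        -_EXP_CAP,
        _EXP_CAP,
    )
    a_mn = np.exp(log_ratio)
    a_nm = np.exp(-log_ratio)
    n = len(taus)
    N = np.empty(n)
    M = np.empty(n)
    N[0], M[0] = N0, M0
    x, y = N0, M0
    clamped = False
    for t in range(n - 1):
        arg_n = r[t] * (1.0 - (x + a_nm[t] * y) / k[t])
        arg_m = r[t] * (1.0 - (a_mn[t] * x + y) / k[t])
        _step_exponents_ok(arg_n, t)
        _step_exponents_ok(arg_m, t)
        x = x * np.exp(arg_n)
        y = y * np.exp(arg_m)
        if 0.0 < y < _EXTINCTION_FLOOR:
            y = 0.0
            if not clamped:
                logger.info("mutant clamped to extinction at step %d", t + 1)
                clamped = True
        N[t + 1], M[t + 1] = x, y
    return Trajectory(
        times=np.arange(n),
        tau=tau,
        N=N,
        M=M,
        params=params,
        shapes=(resident, mutant),
    )


def attractor_summary(traj: Trajectory, burn_in: int = 1000) -> AttractorSummary:
    """Mean and SD of resident size over steps >= *burn_in*."""
    if not 0 <= burn_in < len(traj):
        raise ValueError(
            f"burn_in must satisfy 0 <= burn_in < {len(traj)}, got {burn_in}"
        )
    window = traj.N[burn_in:]
    return AttractorSummary(
        mean_N=float(np.mean(window)),
        sd_N=float(np.std(window)),
        burn_in=burn_in,
        window=len(window),
    )
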